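"""Built-in progressive multiple alignment of CON1 regions.

A deliberately compact substitute for an external aligner: pairwise global
alignments (BLOSUM62, affine gaps open -10 / extend -1) supply guide
distances, sequences are merged profile-to-profile along a UPGMA guide tree,
and profile columns are scored as expected BLOSUM62 substitution scores
(gap symbols contribute zero).  Deterministic for fixed inputs; externally
computed alignments can always be imported instead (aligned FASTA).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ..motifs import Con1Region

__all__ = [
    "GAP",
    "ALPHABET",
    "Alignment",
    "align_con1",
    "align_to_profile",
    "parse_alignment_fasta",
    "write_alignment_fasta",
]

GAP = "-"
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_CHAR_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_GAP_INDEX = len(ALPHABET)

GAP_OPEN = -10.0
GAP_EXTEND = -1.0


def _blosum62_matrix() -> np.ndarray:
    """BLOSUM62 over ALPHABET plus an all-zero row/column for the gap."""
    bl = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    S = np.zeros((n + 1, n + 1))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            S[i, j] = bl[a][b]
    return S


_BLOSUM = _blosum62_matrix()


@dataclass(frozen=True)
class Alignment:
    """Equal-length aligned rows over the amino-acid alphabet plus gap."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def to_array(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows], dtype="U1")


def _pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    aligner.mode = "global"
    return aligner


def _guide_distances(seqs: Sequence[str]) -> np.ndarray:
    """p-distances from pairwise global alignments, for the guide tree only."""
    aligner = _pairwise_aligner()
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(seqs[i], seqs[j])[0]
            a, b = str(aln[0]), str(aln[1])
            comp = sum(1 for x, y in zip(a, b) if x != GAP and y != GAP)
            diff = sum(1 for x, y in zip(a, b) if x != GAP and y != GAP and x != y)
            D[i, j] = D[j, i] = diff / comp if comp else 1.0
    return D


def _profile_freqs(cols: list[str]) -> np.ndarray:
    """(L, 22) residue/gap frequency matrix of a sub-alignment."""
    arr = np.array([list(c) for c in cols], dtype="U1")  # rows = sequences
    L = arr.shape[1]
    F = np.zeros((L, _GAP_INDEX + 1))
    for k in range(arr.shape[0]):
        idx = np.array([_CHAR_INDEX.get(c, _GAP_INDEX) for c in arr[k]])
        F[np.arange(L), idx] += 1.0
    return F / arr.shape[0]


def _merge_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Affine-gap global profile-profile alignment (Gotoh, three states).

    Returns the two input row blocks padded with gap columns so that they can
    be stacked into one alignment.  Traceback prefers diagonal, then the
    A-gap state, then the B-gap state — a fixed order keeps output
    deterministic.
    """
    Fa = _profile_freqs(rows_a)
    Fb = _profile_freqs(rows_b)
    La, Lb = Fa.shape[0], Fb.shape[0]
    score = Fa @ _BLOSUM @ Fb.T  # (La, Lb) expected column scores

    NEG = -1e30
    M = np.full((La + 1, Lb + 1), NEG)
    X = np.full((La + 1, Lb + 1), NEG)  # gap in B (consume A column)
    Y = np.full((La + 1, Lb + 1), NEG)  # gap in A (consume B column)
    M[0, 0] = 0.0
    for i in range(1, La + 1):
        X[i, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for j in range(1, Lb + 1):
        Y[0, j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    for i in range(1, La + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        si = score[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        # X state depends on row i-1 only: vectorise over j
        np.maximum(Mi1 + GAP_OPEN, np.maximum(Xi1 + GAP_EXTEND, Yi1 + GAP_OPEN), out=Xi)
        Xi[0] = GAP_OPEN + GAP_EXTEND * (i - 1)
        prev_m = np.maximum(Mi1, np.maximum(Xi1, Yi1))  # best arriving diagonally
        for j in range(1, Lb + 1):
            Mi[j] = prev_m[j - 1] + si[j - 1]
            Yi[j] = max(Mi[j - 1] + GAP_OPEN, Yi[j - 1] + GAP_EXTEND, Xi[j - 1] + GAP_OPEN)

    # traceback
    i, j = La, Lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    ops: list[str] = []  # 'D' diagonal, 'A' consume A only, 'B' consume B only
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax(prev))
            ops.append("D")
            i, j = i - 1, j - 1
        elif state == 1 or j == 0:
            cand = [M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND, Y[i - 1, j] + GAP_OPEN]
            state = int(np.argmax(cand)) if i > 1 or j > 0 else 0
            ops.append("A")
            i -= 1
        else:
            cand = [M[i, j - 1] + GAP_OPEN, X[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXTEND]
            state = int(np.argmax(cand)) if j > 1 or i > 0 else 0
            ops.append("B")
            j -= 1
    ops.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("D", "A"):
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += GAP
        if op in ("D", "B"):
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += GAP
    return out_a, out_b


def align_con1(
    regions: Iterable[Con1Region] | Iterable[tuple[str, str]],
    guide: "object | None" = None,
) -> Alignment:
    """Progressively align CON1 regions (or ``(id, sequence)`` pairs).

    Requires at least two sequences.  The merge order follows the UPGMA guide
    tree built from pairwise-alignment p-distances unless a guide
    :class:`~chsfam.io_formats.Tree` is supplied, in which case its topology
    dictates the order.
    """
    items: list[tuple[str, str]] = []
    for r in regions:
        if isinstance(r, Con1Region):
            items.append((r.protein_id, r.sequence))
        else:
            sid, seq = r
            items.append((sid, seq))
    if len(items) < 2:
        raise ValueError("alignment requires at least 2 sequences")
    ids = [sid for sid, _ in items]
    seqs = [seq for _, seq in items]

    merge_order = _merge_order(ids, seqs, guide)

    blocks: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(len(items))
    }
    next_id = len(items)
    for a, b in merge_order:
        idx_a, rows_a = blocks.pop(a)
        idx_b, rows_b = blocks.pop(b)
        out_a, out_b = _merge_profiles(rows_a, rows_b)
        blocks[next_id] = (idx_a + idx_b, out_a + out_b)
        next_id += 1
    (_, (order, rows)), = blocks.items()

    by_input = {orig: row for orig, row in zip(order, rows)}
    return Alignment(ids=tuple(ids), rows=tuple(by_input[i] for i in range(len(items))))


def _merge_order(
    ids: list[str], seqs: list[str], guide: "object | None"
) -> list[tuple[int, int]]:
    if guide is not None:
        return _merge_order_from_tree(ids, guide)
    if len(ids) == 2:
        return [(0, 1)]
    D = _guide_distances(seqs)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    n = len(ids)
    return [(int(Z[k, 0]), int(Z[k, 1])) for k in range(n - 1)]


def _merge_order_from_tree(ids: list[str], guide) -> list[tuple[int, int]]:
    index = {name: i for i, name in enumerate(ids)}
    merges: list[tuple[int, int]] = []
    counter = [len(ids)]

    def visit(node) -> int:
        if node.is_leaf:
            return index[node.label]
        child_ids = [visit(c) for c in node.children]
        acc = child_ids[0]
        for cid in child_ids[1:]:
            merges.append((acc, cid))
            acc = counter[0]
            counter[0] += 1
        return acc

    visit(guide.root)
    return merges


def parse_alignment_fasta(path: str | Path) -> Alignment:
    from Bio import SeqIO

    ids, rows = [], []
    for entry in SeqIO.parse(str(path), "fasta"):
        ids.append(entry.description.split()[0])
        rows.append(str(entry.seq).upper())
    return Alignment(ids=tuple(ids), rows=tuple(rows))


def write_alignment_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")
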