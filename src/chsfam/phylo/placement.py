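"""Placement of a query CON1 region into a labelled reference tree.

The query is aligned to the reference profile, the joint NJ tree is rebuilt
with bootstrap, and the host clade is determined from the joint topology:
candidate clades are the bipartition sides containing the query whose
reference leaves are non-empty and all share one class label; the smallest
such side wins (a size tie between different labels means no placement — the
query sits ambiguously between class clades).  The support reported for a
placement is the bootstrap percentage of the *class clade's* edge — the side
holding the query plus every reference leaf of the host label — falling back
to the chosen candidate's edge when that exact bipartition is absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..motifs import Con1Region
from .align import GAP, Alignment, _merge_profiles
from .tree import bipartition_sets, bootstrap_from_alignment

__all__ = ["ReferenceSet", "Placement", "align_query_to_reference", "place_query"]


@dataclass(frozen=True)
class ReferenceSet:
    """A labelled reference alignment: each leaf carries a class label."""

    alignment: Alignment
    labels: dict[str, str]  # leaf id -> class label

    def __post_init__(self) -> None:
        if not self.alignment.ids:
            raise ValueError("empty reference")
        missing = [i for i in self.alignment.ids if i not in self.labels]
        if missing:
            raise ValueError(f"reference leaves without labels: {missing}")

    @property
    def class_labels(self) -> frozenset[str]:
        return frozenset(self.labels.values())

    def degapped_rows(self) -> dict[str, str]:
        return {i: self.alignment.degapped(i) for i in self.alignment.ids}


@dataclass(frozen=True)
class Placement:
    query_id: str
    host_clade_label: str | None
    support: float | None  # [0, 100]; present iff host label present
    sister_leaves: tuple[str, ...] = ()
    #: True when the query sits at the host clade's own divergence scale:
    #: its mean distance to the host's reference leaves is less than half
    #: its mean distance to all other reference leaves.  A deeply divergent
    #: query that merely attaches to the clade's stem is roughly equidistant
    #: to every clade and fails this.
    proximal: bool = True

    def __post_init__(self) -> None:
        if (self.host_clade_label is None) != (self.support is None):
            raise ValueError("support must be present exactly when host is")


def align_query_to_reference(query_id: str, query_seq: str, reference: ReferenceSet) -> Alignment:
    """Profile-align the query against the reference alignment."""
    ref = reference.alignment
    out_ref, out_q = _merge_profiles(list(ref.rows), [query_seq])
    return Alignment(ids=ref.ids + (query_id,), rows=tuple(out_ref) + (out_q[0],))


def place_query(
    query: Con1Region | tuple[str, str],
    reference: ReferenceSet,
    n_reps: int = 100,
    seed: int | np.random.Generator = 0,
    *,
    site_rule: str = "partial_deletion",
    coverage: float = 0.95,
    correction: str | None = None,
) -> Placement:
    """Place one query into the reference tree and report its host clade."""
    if isinstance(query, Con1Region):
        qid, qseq = query.protein_id, query.sequence
    else:
        qid, qseq = query
    if qid in reference.alignment.ids:
        raise ValueError(f"query id {qid!r} collides with a reference leaf")

    joint = align_query_to_reference(qid, qseq, reference)
    point, supports = bootstrap_from_alignment(
        joint,
        n_reps,
        seed,
        site_rule=site_rule,
        coverage=coverage,
        correction=correction,
    )

    splits = bipartition_sets(point)
    all_leaves = frozenset(joint.ids)
    candidates: list[tuple[int, str, frozenset[str]]] = []
    for split in splits:
        side = split if qid in split else all_leaves - split
        refs = side - {qid}
        if not refs:
            continue
        side_labels = {reference.labels[r] for r in refs}
        if len(side_labels) == 1:
            candidates.append((len(side), side_labels.pop(), side))

    if not candidates:
        return Placement(query_id=qid, host_clade_label=None, support=None)
    min_size = min(c[0] for c in candidates)
    minimal = sorted(c for c in candidates if c[0] == min_size)
    if len({label for _, label, _ in minimal}) > 1:
        return Placement(query_id=qid, host_clade_label=None, support=None)
    _, host, side = minimal[0]

    # support of the class clade's edge: query + all reference leaves of host
    class_side = frozenset(
        [qid] + [r for r in reference.alignment.ids if reference.labels[r] == host]
    )
    anchor = min(all_leaves)
    key = class_side if anchor not in class_side else all_leaves - class_side
    if key in supports:
        support = supports[key]
    else:
        fb = side if anchor not in side else all_leaves - side
        support = supports.get(fb, 0.0)

    return Placement(
        query_id=qid,
        host_clade_label=host,
        support=support,
        sister_leaves=tuple(sorted(side - {qid})),
        proximal=_query_is_proximal(joint, qid, host, reference),
    )


def _query_is_proximal(
    joint: Alignment, qid: str, host: str, reference: ReferenceSet
) -> bool:
    """Mean query-to-host p-distance < 0.5 x mean query-to-other distance."""
    arr = joint.to_array()
    codes = arr.view(np.uint32).reshape(arr.shape[0], -1)
    residue = arr != GAP
    qi = joint.ids.index(qid)
    dists: dict[str, float] = {}
    for i, rid in enumerate(joint.ids):
        if rid == qid:
            continue
        both = residue[qi] & residue[i]
        comp = int(both.sum())
        dists[rid] = (
            float(((codes[qi] != codes[i]) & both).sum()) / comp if comp else 1.0
        )
    host_d = [d for rid, d in dists.items() if reference.labels[rid] == host]
    other_d = [d for rid, d in dists.items() if reference.labels[rid] != host]
    if not other_d:
        return True
    return float(np.mean(host_d)) < 0.5 * float(np.mean(other_d))
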