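"""CON1 motif scanning and motif-anchored region extraction.

All chitin synthases share a conserved catalytic region (CON1) delimited by
three short motifs.  The region is defined operationally: it begins at the
start of a QxxEY occurrence, ends at the end of a QxRRW occurrence, and an
EDRxL occurrence lies strictly between the two.  ``x`` matches any residue;
bracketed alternatives (e.g. ``[ED]``) are allowed in patterns.

Two named pattern sets are provided: the default identification set
(QxxEY / EDRxL / QxRRW) and a more permissive alternate set
(QxxEY / [ED]Dx / Q[RQ]xRW) reflecting looser motif definitions in the older
literature.  The default set is the one used for candidate screening.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .io_formats import ProteinRecord

__all__ = [
    "MotifHit",
    "Con1Region",
    "MotifPatternSet",
    "PRIMARY_MOTIFS",
    "ALTERNATE_MOTIFS",
    "PATTERN_SETS",
    "MIN_CON1_LENGTH",
    "scan_motifs",
    "extract_con1",
]

#: three non-overlapping 5-residue motifs is the floor
MIN_CON1_LENGTH = 15


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int
    end: int
    matched: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.matched):
            raise ValueError("matched substring length disagrees with interval")


@dataclass(frozen=True)
class Con1Region:
    """The motif-anchored conserved catalytic region of one CHS."""

    protein_id: str
    start: int
    end: int
    sequence: str
    motif_hits: tuple[MotifHit, MotifHit, MotifHit]

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("region sequence length disagrees with interval")
        if len(self.sequence) < MIN_CON1_LENGTH:
            raise ValueError(f"CON1 region shorter than {MIN_CON1_LENGTH} residues")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifPatternSet:
    """Named fixed-length wildcard patterns with anchor roles.

    ``start_motif`` anchors the region start, ``end_motif`` the region end and
    ``internal_motif`` must fall strictly between them.
    """

    name: str
    patterns: tuple[tuple[str, str], ...]  # (motif_name, pattern)
    start_motif: str
    internal_motif: str
    end_motif: str

    def pattern_for(self, motif_name: str) -> str:
        for name, pat in self.patterns:
            if name == motif_name:
                return pat
        raise KeyError(motif_name)


PRIMARY_MOTIFS = MotifPatternSet(
    name="primary",
    patterns=(("QxxEY", "QxxEY"), ("EDRxL", "EDRxL"), ("QxRRW", "QxRRW")),
    start_motif="QxxEY",
    internal_motif="EDRxL",
    end_motif="QxRRW",
)

ALTERNATE_MOTIFS = MotifPatternSet(
    name="alternate",
    patterns=(("QxxEY", "QxxEY"), ("EDx", "[ED]Dx"), ("QRQxRW", "Q[RQ]xRW")),
    start_motif="QxxEY",
    internal_motif="EDx",
    end_motif="QRQxRW",
)

PATTERN_SETS: dict[str, MotifPatternSet] = {
    PRIMARY_MOTIFS.name: PRIMARY_MOTIFS,
    ALTERNATE_MOTIFS.name: ALTERNATE_MOTIFS,
}

_TOKEN_RE = re.compile(r"\[([A-Z]+)\]|([A-Zx])")


def compile_pattern(pattern: str) -> tuple[re.Pattern[str], int]:
    """Compile a wildcard pattern into an overlap-reporting regex.

    Returns the compiled regex (a lookahead, so overlapping occurrences are
    all found) and the fixed match length.
    """
    parts: list[str] = []
    length = 0
    pos = 0
    for m in _TOKEN_RE.finditer(pattern):
        if m.start() != pos:
            raise ValueError(f"bad motif pattern {pattern!r}")
        pos = m.end()
        if m.group(1) is not None:
            parts.append(f"[{m.group(1)}]")
        elif m.group(2) == "x":
            parts.append("[A-Z]")
        else:
            parts.append(m.group(2))
        length += 1
    if pos != len(pattern):
        raise ValueError(f"bad motif pattern {pattern!r}")
    return re.compile(f"(?=({''.join(parts)}))"), length


def scan_motifs(
    record: ProteinRecord | str, patterns: MotifPatternSet = PRIMARY_MOTIFS
) -> list[MotifHit]:
    """Report every occurrence (including overlapping ones) of every motif.

    Accepts a :class:`ProteinRecord` or a bare sequence string.  An empty
    result is valid.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    hits: list[MotifHit] = []
    for motif_name, pattern in patterns.patterns:
        regex, length = compile_pattern(pattern)
        for m in regex.finditer(seq):
            hits.append(
                MotifHit(
                    motif_name=motif_name,
                    start=m.start(),
                    end=m.start() + length,
                    matched=m.group(1),
                )
            )
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return hits


def extract_con1(
    record: ProteinRecord | str,
    hits: list[MotifHit] | None = None,
    patterns: MotifPatternSet = PRIMARY_MOTIFS,
    *,
    protein_id: str | None = None,
) -> Con1Region | None:
    """Extract the CON1 region delimited by an ordered motif triple.

    A valid triple is (start-motif, internal-motif, end-motif) occurring in
    that order without overlap; the internal motif lies strictly inside the
    region.  Among all valid triples the minimal-span one is chosen, ties
    broken by leftmost start (then leftmost internal hit).  Returns ``None``
    when no valid triple exists — absence is a legitimate screening outcome,
    not an error.
    """
    if isinstance(record, ProteinRecord):
        seq, pid = record.sequence, record.protein_id
    else:
        seq, pid = record, (protein_id or "")
    if hits is None:
        hits = scan_motifs(seq, patterns)
    starts = [h for h in hits if h.motif_name == patterns.start_motif]
    mids = [h for h in hits if h.motif_name == patterns.internal_motif]
    ends = [h for h in hits if h.motif_name == patterns.end_motif]
    best: tuple[int, int, int, MotifHit, MotifHit, MotifHit] | None = None
    for q in starts:
        for r in ends:
            span = r.end - q.start
            if span < MIN_CON1_LENGTH:
                continue
            for e in mids:
                if q.end <= e.start and e.end <= r.start:
                    key = (span, q.start, e.start)
                    if best is None or key < best[:3]:
                        best = (span, q.start, e.start, q, e, r)
                    break  # mids sorted by start: first valid is leftmost
    if best is None:
        return None
    _, _, _, q, e, r = best
    return Con1Region(
        protein_id=pid,
        start=q.start,
        end=r.end,
        sequence=seq[q.start : r.end],
        motif_hits=(q, e, r),
    )
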