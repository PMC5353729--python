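"""Ordered domain architectures and Group/Type structure labels.

Typing uses six focal accessions (PF08407, PF01644, PF00063, PF00173,
PF03142, PF08766) plus the CON1 token; any other accession is recorded as
auxiliary and never changes the type label.  Group A architectures carry
PF01644 immediately followed by CON1 (the fused remnant of PF03142's
C-terminus); Group B architectures carry an intact PF03142 and no PF01644.

Type table (multisets, order checked only where stated):

====  =======================================  =====
A1    PF01644, CON1                            Group A
A2    PF08407, PF01644, CON1                   Group A
A3    PF08407, PF01644, CON1, PF03142 (last)   Group A
B1    PF03142                                  Group B
B2    PF03142, PF00173                         Group B
B3    PF00063, PF03142, PF08766                Group B
B4    PF00063, PF00173, PF03142, PF08766       Group B
====  =======================================  =====

Anything else is ``other``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .io_formats import DomainHit, ProteinRecord
from .motifs import Con1Region
from .screen import resolve_accession

__all__ = [
    "FOCAL_ACCESSIONS",
    "CON1_TOKEN",
    "Architecture",
    "StructureType",
    "build_architecture",
    "assign_structure_type",
]

FOCAL_ACCESSIONS = ("PF08407", "PF01644", "PF00063", "PF00173", "PF03142", "PF08766")
CON1_TOKEN = "CON1"

GROUP_A_TYPES = frozenset({"A1", "A2", "A3"})
GROUP_B_TYPES = frozenset({"B1", "B2", "B3", "B4"})


@dataclass(frozen=True)
class Architecture:
    """Ordered focal domain content of one protein."""

    protein_id: str
    elements: tuple[str, ...]  # focal accessions / CON1, by start coordinate
    intervals: tuple[tuple[int, int], ...]  # matching 0-based half-open spans
    auxiliary: tuple[DomainHit, ...] = ()

    def __post_init__(self) -> None:
        if len(self.elements) != len(self.intervals):
            raise ValueError("elements and intervals length mismatch")
        prev_end = -1
        for (s, e) in self.intervals:
            if s < prev_end:
                raise ValueError("architecture elements overlap after resolution")
            prev_end = e


@dataclass(frozen=True)
class StructureType:
    group: str  # A, B or none
    type_label: str  # A1..A3, B1..B4 or other

    def __post_init__(self) -> None:
        if self.group == "A" and self.type_label not in GROUP_A_TYPES:
            raise ValueError("group A requires an A-type label")
        if self.group == "B" and self.type_label not in GROUP_B_TYPES:
            raise ValueError("group B requires a B-type label")
        if self.group == "none" and self.type_label != "other":
            raise ValueError("group none requires label other")


def _merge_same_accession(
    spans: list[tuple[int, int, float]]
) -> list[tuple[int, int, float]]:
    """Union overlapping intervals of one accession, keeping the best score."""
    spans.sort()
    merged: list[tuple[int, int, float]] = []
    for s, e, sc in spans:
        if merged and s < merged[-1][1]:
            ps, pe, psc = merged[-1]
            merged[-1] = (ps, max(pe, e), max(psc, sc))
        else:
            merged.append((s, e, sc))
    return merged


def build_architecture(
    protein: ProteinRecord | str,
    hits: Iterable[DomainHit],
    con1: Con1Region | None,
    *,
    aliases: Mapping[str, str] | None = None,
) -> Architecture:
    """Resolve a protein's domain hits into an ordered element list.

    Resolution order: (1) overlapping same-accession hits are merged; (2)
    overlapping different-accession hits are resolved greedily by higher bit
    score; (3) a PF03142 hit contained in (or partially overlapping) the CON1
    region is replaced by the CON1 token — it is the catalytic remnant the
    motifs delimit — whereas a PF03142 hit that itself contains the CON1
    region is kept and the token suppressed (the intact CS2 domain subsumes
    its catalytic core).
    """
    pid = protein.protein_id if isinstance(protein, ProteinRecord) else protein
    focal: dict[str, list[tuple[int, int, float]]] = {}
    auxiliary: list[DomainHit] = []
    for h in hits:
        if h.protein_id != pid:
            continue
        acc = resolve_accession(h.accession, aliases)
        if acc in FOCAL_ACCESSIONS:
            focal.setdefault(acc, []).append((h.start, h.end, h.score))
        else:
            auxiliary.append(h)

    candidates: list[tuple[int, int, float, str]] = []  # (start, end, score, name)
    for acc, spans in focal.items():
        for s, e, sc in _merge_same_accession(spans):
            candidates.append((s, e, sc, acc))

    # cross-accession overlaps: keep higher score, greedily
    kept: list[tuple[int, int, float, str]] = []
    for cand in sorted(candidates, key=lambda c: (-c[2], c[0], c[3])):
        if all(cand[1] <= k[0] or cand[0] >= k[1] for k in kept):
            kept.append(cand)

    elements: list[tuple[int, int, str]] = []
    con1_token = con1 is not None
    if con1 is not None:
        for s, e, sc, acc in list(kept):
            if acc != "PF03142":
                continue
            if s <= con1.start and con1.end <= e:
                con1_token = False  # intact CS2 contains the region
            elif not (e <= con1.start or s >= con1.end):
                kept.remove((s, e, sc, acc))  # remnant/overlap: token wins
    for s, e, sc, acc in kept:
        if con1_token and not (e <= con1.start or s >= con1.end):
            continue  # any other focal hit overlapping CON1 yields to the token
        elements.append((s, e, acc))
    if con1 is not None and con1_token:
        elements.append((con1.start, con1.end, CON1_TOKEN))
    elements.sort()

    return Architecture(
        protein_id=pid,
        elements=tuple(name for _, _, name in elements),
        intervals=tuple((s, e) for s, e, _ in elements),
        auxiliary=tuple(sorted(auxiliary, key=lambda h: (h.start, h.accession))),
    )


_B_RULES: dict[frozenset[str], str] = {
    frozenset({"PF03142"}): "B1",
    frozenset({"PF03142", "PF00173"}): "B2",
    frozenset({"PF00063", "PF03142", "PF08766"}): "B3",
    frozenset({"PF00063", "PF00173", "PF03142", "PF08766"}): "B4",
}


def assign_structure_type(arch: Architecture) -> StructureType:
    """Map the focal-element multiset (plus stated order constraints) to a
    Group/Type label; unknown combinations are ``other``."""
    elems = arch.elements
    counts: dict[str, int] = {}
    for e in elems:
        counts[e] = counts.get(e, 0) + 1
    if any(v > 1 for v in counts.values()):
        return StructureType(group="none", type_label="other")
    content = frozenset(counts)

    if "PF01644" in content and CON1_TOKEN in content:
        # Group A requires PF01644 immediately followed by CON1
        i = elems.index("PF01644")
        if i + 1 < len(elems) and elems[i + 1] == CON1_TOKEN:
            if content == frozenset({"PF01644", CON1_TOKEN}):
                return StructureType(group="A", type_label="A1")
            if content == frozenset({"PF08407", "PF01644", CON1_TOKEN}):
                return StructureType(group="A", type_label="A2")
            if content == frozenset({"PF08407", "PF01644", CON1_TOKEN, "PF03142"}):
                if elems.index("PF03142") > elems.index(CON1_TOKEN):
                    return StructureType(group="A", type_label="A3")
        return StructureType(group="none", type_label="other")

    label = _B_RULES.get(content)
    if label is not None:
        return StructureType(group="B", type_label=label)
    return StructureType(group="none", type_label="other")
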