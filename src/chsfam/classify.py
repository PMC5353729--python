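"""Class assignment: domain-structure type x phylogenetic placement.

A chitin synthase is assigned to one of the seven classes (I-VII), to the
basal group 23b, or left unclassified.  A class call requires three things to
agree: the query's host clade in the species-augmented reference tree, the
bootstrap support of that class clade (strictly above the threshold, default
60%), and a compatible domain-structure type:

    I, II, III, 23b <-> A2      IV <-> B2      V, VII <-> B4      VI <-> B1

Proteins with Type A1, A3 or B3 structures are flagged *noisy* (they scatter
through the tree without phylogenetic coherence), as are Type B1 proteins
that do not sit inside the Division 3 (Class VI) reference clade with
adequate support; noisy proteins are excluded from classification and
reported as unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .architecture import Architecture, StructureType, assign_structure_type
from .io_formats import ProteinRecord
from .motifs import Con1Region
from .phylo import Placement, ReferenceSet, place_query

__all__ = [
    "CLASS_LABELS",
    "TYPE_COMPATIBILITY",
    "CLASS_DIVISION",
    "DEFAULT_SUPPORT_THRESHOLD",
    "ClassAssignment",
    "ClassificationSummary",
    "assign_class",
    "flag_noisy",
    "classify_species_set",
    "summarize_classification",
]

CLASS_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII", "23b")
UNCLASSIFIED = "unclassified"

TYPE_COMPATIBILITY: dict[str, str] = {
    "I": "A2",
    "II": "A2",
    "III": "A2",
    "23b": "A2",
    "IV": "B2",
    "V": "B4",
    "VII": "B4",
    "VI": "B1",
}
CLASS_DIVISION: dict[str, int] = {
    "I": 1,
    "II": 1,
    "III": 1,
    "23b": 1,
    "IV": 2,
    "V": 2,
    "VII": 2,
    "VI": 3,
}
#: types excluded from classification wherever they fall in the tree
ALWAYS_NOISY_TYPES = frozenset({"A1", "A3", "B3"})
DIVISION3_CLASSES = frozenset({"VI"})

DEFAULT_SUPPORT_THRESHOLD = 60.0


@dataclass(frozen=True)
class ClassAssignment:
    protein_id: str
    species_id: str
    class_label: str  # I..VII, 23b or unclassified
    division: int | None  # 1, 2, 3 or None
    support: float | None
    type_label: str
    host_clade_label: str | None
    noisy: bool = False


@dataclass(frozen=True)
class ClassificationSummary:
    counts: dict[str, int]  # per class label, incl. unclassified
    total: int
    excluded_count: int  # noisy proteins
    per_type: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("class counts must sum to total")


def assign_class(
    type_label: StructureType | str,
    placement: Placement,
    threshold: float = DEFAULT_SUPPORT_THRESHOLD,
    *,
    strict: bool = True,
) -> tuple[str, int | None, float | None]:
    """Combine structure type and placement into (class, division, support).

    A class is called iff the host clade label matches a known class, the
    support clears the threshold (strictly by default, matching the published
    ">60%" rule) and the structure type is compatible; otherwise the protein
    is unclassified.
    """
    t = type_label.type_label if isinstance(type_label, StructureType) else type_label
    host, support = placement.host_clade_label, placement.support
    if host is None or support is None or host not in TYPE_COMPATIBILITY:
        return UNCLASSIFIED, None, None
    cleared = support > threshold if strict else support >= threshold
    if not cleared or TYPE_COMPATIBILITY[host] != t:
        return UNCLASSIFIED, None, None
    return host, CLASS_DIVISION[host], support


def flag_noisy(
    type_label: StructureType | str,
    placement: Placement | None,
    threshold: float = DEFAULT_SUPPORT_THRESHOLD,
) -> bool:
    """Deterministic surrogate for "randomly scattered through the tree".

    Types A1, A3 and B3 are always noisy.  Type B1 is noisy unless placed
    inside the Division 3 reference clade with support >= threshold *and*
    at that clade's own divergence scale (``placement.proximal``).  All
    other types are never noisy.  (A deeply divergent B1 copy tends to
    attach to the Division 3 stem because Class VI is the division's only
    clade; the proximity requirement separates such copies from genuine
    Class VI members.)
    """
    t = type_label.type_label if isinstance(type_label, StructureType) else type_label
    if t in ALWAYS_NOISY_TYPES:
        return True
    if t == "B1":
        if (
            placement is not None
            and placement.host_clade_label in DIVISION3_CLASSES
            and placement.support is not None
            and placement.support >= threshold
            and placement.proximal
        ):
            return False
        return True
    return False


def _derived_seed(base_seed: int, protein_id: str) -> np.random.Generator:
    import zlib

    return np.random.default_rng([base_seed, zlib.crc32(protein_id.encode())])


def classify_species_set(
    records: Iterable[ProteinRecord],
    architectures: Mapping[str, Architecture],
    con1: Mapping[str, Con1Region],
    reference: ReferenceSet,
    *,
    threshold: float = DEFAULT_SUPPORT_THRESHOLD,
    strict: bool = True,
    n_reps: int = 100,
    seed: int = 0,
    site_rule: str = "partial_deletion",
    coverage: float = 0.95,
    correction: str | None = None,
) -> list[ClassAssignment]:
    """Classify a species' screened-in proteins against the reference tree.

    The reference must carry every one of the 7 classes.  A query whose CON1
    exactly equals a reference leaf's sequence takes that leaf's class
    directly (support 100) instead of re-building a tree containing a
    duplicate; every other query is placed individually, with a per-protein
    seed derived from the base seed so results are order-independent and
    reproducible.
    """
    missing = {c for c in CLASS_LABELS if c != "23b"} - reference.class_labels
    if missing:
        raise ValueError(
            f"reference tree lacks class labels {sorted(missing)}; the master "
            "tree must carry all 7 classes"
        )
    ref_by_seq: dict[str, str] = {}
    for rid, row in reference.degapped_rows().items():
        ref_by_seq.setdefault(row, rid)

    assignments: list[ClassAssignment] = []
    for rec in sorted(records, key=lambda r: r.protein_id):
        pid = rec.protein_id
        arch = architectures[pid]
        stype = assign_structure_type(arch)
        region = con1.get(pid)
        if region is None:
            raise ValueError(f"protein {pid!r} reached classification without CON1")

        dup_ref = ref_by_seq.get(region.sequence)
        if dup_ref is not None:
            placement = Placement(
                query_id=pid,
                host_clade_label=reference.labels[dup_ref],
                support=100.0,
                sister_leaves=(dup_ref,),
            )
        else:
            placement = place_query(
                (pid, region.sequence),
                reference,
                n_reps=n_reps,
                seed=_derived_seed(seed, pid),
                site_rule=site_rule,
                coverage=coverage,
                correction=correction,
            )

        noisy = flag_noisy(stype, placement, threshold)
        if noisy:
            label, division, support = UNCLASSIFIED, None, None
        else:
            label, division, support = assign_class(
                stype, placement, threshold, strict=strict
            )
        assignments.append(
            ClassAssignment(
                protein_id=pid,
                species_id=rec.species_id,
                class_label=label,
                division=division,
                support=support,
                type_label=stype.type_label,
                host_clade_label=placement.host_clade_label,
                noisy=noisy,
            )
        )
    return assignments


def summarize_classification(
    assignments: Iterable[ClassAssignment],
) -> ClassificationSummary:
    """Per-class tallies plus bookkeeping identities (counts sum to total)."""
    counts = {label: 0 for label in CLASS_LABELS + (UNCLASSIFIED,)}
    per_type: dict[str, int] = {}
    total = 0
    excluded = 0
    for a in assignments:
        counts[a.class_label] += 1
        per_type[a.type_label] = per_type.get(a.type_label, 0) + 1
        total += 1
        if a.noisy:
            excluded += 1
    return ClassificationSummary(
        counts=counts, total=total, excluded_count=excluded, per_type=per_type
    )
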