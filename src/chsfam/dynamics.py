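"""Per-species and per-taxon CHS repertoire profiles (expansion/contraction).

The profile is a species x class count matrix (including the unclassified
column); a taxon summary reports the mean CHS count per species (half-up to
one decimal, the reporting precision used for such surveys) and, per class,
the fractions of species with multiple / one / no members.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import pandas as pd

from .classify import CLASS_LABELS, UNCLASSIFIED, ClassAssignment
from .io_formats import TaxonomyTable

__all__ = ["FamilyProfile", "TaxonSummary", "profile_counts", "taxon_summary"]

PROFILE_COLUMNS = CLASS_LABELS + (UNCLASSIFIED,)


@dataclass(frozen=True)
class FamilyProfile:
    """Species x class count matrix; row sum = accepted CHS count."""

    table: pd.DataFrame  # index species_id, columns PROFILE_COLUMNS

    def counts(self, species_id: str) -> pd.Series:
        return self.table.loc[species_id]

    def total(self, species_id: str) -> int:
        return int(self.table.loc[species_id].sum())


@dataclass(frozen=True)
class TaxonSummary:
    taxon: str
    n_species: int
    mean_chs: float  # per species, half-up to 1 decimal
    presence: dict[str, dict[str, float]]  # class -> {multiple, one, none}

    def __post_init__(self) -> None:
        for cls, frac in self.presence.items():
            if abs(sum(frac.values()) - 1.0) > 1e-9:
                raise ValueError(f"presence fractions for {cls} do not sum to 1")


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def profile_counts(
    assignments: Iterable[ClassAssignment], taxonomy: TaxonomyTable
) -> FamilyProfile:
    """Count assignments per species and class; species known to the taxonomy
    but absent from the assignments get all-zero rows."""
    table = pd.DataFrame(
        0, index=list(taxonomy.species_ids), columns=list(PROFILE_COLUMNS), dtype=int
    )
    for a in assignments:
        if a.species_id not in taxonomy:
            raise KeyError(f"species {a.species_id!r} absent from taxonomy")
        table.loc[a.species_id, a.class_label] += 1
    return FamilyProfile(table=table)


def taxon_summary(
    profile: FamilyProfile, taxonomy: TaxonomyTable, taxon: str
) -> TaxonSummary:
    """Summarise the repertoire of one taxon (a lineage name or tag)."""
    members = [sp for sp in taxonomy.members(taxon) if sp in profile.table.index]
    if not members:
        raise ValueError(f"taxon {taxon!r} has no species in the profile")
    sub = profile.table.loc[members]
    mean = round_half_up(float(sub.sum().sum()) / len(members), 1)
    presence: dict[str, dict[str, float]] = {}
    n = len(members)
    for cls in PROFILE_COLUMNS:
        col = sub[cls]
        presence[cls] = {
            "multiple": float((col >= 2).sum()) / n,
            "one": float((col == 1).sum()) / n,
            "none": float((col == 0).sum()) / n,
        }
    return TaxonSummary(
        taxon=taxon, n_species=n, mean_chs=mean, presence=presence
    )
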