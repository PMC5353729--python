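"""Candidate screening: the three false-positive removal criteria.

A candidate protein is accepted when it (1) carries at least one hit to a
characteristic chitin-synthase domain at or below the configured E-value,
(2) has an extractable CON1 region, and (3) is not an exact within-species
duplicate of another protein that already passed (1) and (2).

The characteristic-domain set defaults to {PF03142, PF01644} with cd04190
treated as an alias of PF03142.  PF01644 is included deliberately: Division 1
chitin synthases carry only the CON1 remnant of PF03142 (the CS2 N-terminus
was lost by recombination), so demanding an intact PF03142 hit would discard
the entire division.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .io_formats import DomainHit, ProteinRecord
from .motifs import Con1Region

__all__ = [
    "CHARACTERISTIC_DOMAINS",
    "ACCESSION_ALIASES",
    "DEFAULT_EVALUE_MAX",
    "IncompleteInputError",
    "ScreenResult",
    "filter_candidates",
]

CHARACTERISTIC_DOMAINS = frozenset({"PF03142", "PF01644"})
#: cd04190 (CDD) describes the same catalytic domain as Pfam's PF03142
ACCESSION_ALIASES: dict[str, str] = {"cd04190": "PF03142"}
DEFAULT_EVALUE_MAX = 1e-5


class IncompleteInputError(ValueError):
    """A record has neither a domain-hit entry nor a CON1 entry."""


@dataclass(frozen=True)
class ScreenResult:
    protein_id: str
    accepted: bool
    reasons: tuple[str, ...]  # subset of the three failure reasons

    def __post_init__(self) -> None:
        if self.accepted != (not self.reasons):
            raise ValueError("accepted must hold exactly when reasons is empty")


def resolve_accession(accession: str, aliases: Mapping[str, str] | None = None) -> str:
    aliases = ACCESSION_ALIASES if aliases is None else aliases
    return aliases.get(accession, accession)


def filter_candidates(
    records: Iterable[ProteinRecord],
    hits: Iterable[DomainHit],
    con1: Mapping[str, Con1Region | None],
    *,
    characteristic: frozenset[str] = CHARACTERISTIC_DOMAINS,
    aliases: Mapping[str, str] | None = None,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> list[ScreenResult]:
    """Apply the three selection criteria; returns one result per record.

    Duplicate collapse (criterion 3) runs within species over proteins that
    passed criteria 1 and 2: identical full-length sequences are collapsed to
    the lexicographically smallest protein id.  A record covered by neither
    the hit table nor the CON1 map is a hard error (incomplete inputs).
    """
    records = list(records)
    hits_by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        hits_by_protein.setdefault(h.protein_id, []).append(h)

    reasons_by_id: dict[str, list[str]] = {}
    passed_12: list[ProteinRecord] = []
    for rec in records:
        pid = rec.protein_id
        if pid not in hits_by_protein and pid not in con1:
            raise IncompleteInputError(
                f"protein {pid!r} has neither domain hits nor a CON1 entry; "
                "screening inputs are incomplete"
            )
        reasons: list[str] = []
        ok_domain = any(
            resolve_accession(h.accession, aliases) in characteristic
            and h.evalue <= evalue_max
            for h in hits_by_protein.get(pid, ())
        )
        if not ok_domain:
            reasons.append("no_characteristic_domain")
        if con1.get(pid) is None:
            reasons.append("missing_motifs")
        reasons_by_id[pid] = reasons
        if not reasons:
            passed_12.append(rec)

    # criterion 3: within-species exact-sequence duplicates
    keeper: dict[tuple[str, str], str] = {}
    for rec in sorted(passed_12, key=lambda r: r.protein_id):
        key = (rec.species_id, rec.sequence)
        if key in keeper:
            reasons_by_id[rec.protein_id].append("duplicate")
        else:
            keeper[key] = rec.protein_id

    return [
        ScreenResult(
            protein_id=rec.protein_id,
            accepted=not reasons_by_id[rec.protein_id],
            reasons=tuple(reasons_by_id[rec.protein_id]),
        )
        for rec in records
    ]
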