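"""Head-to-head ChsV/ChsVII gene-pair detection and intron status.

Two genes are head-to-head when they sit on the same contig on opposite
strands with their 5' ends facing each other across the intergenic interval
(divergent transcription) and at most ``max_intervening`` annotated genes
strictly between them (default 1 — tandem duplicates are occasionally
separated by one predicted hypothetical gene).  No distance cap is applied
by default; one can be configured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .classify import ClassAssignment
from .io_formats import GeneModel

__all__ = [
    "ARRANGEMENTS",
    "SyntenyCall",
    "detect_head_to_head",
    "intron_status",
]

ARRANGEMENTS = ("head_to_head", "same_strand", "tail_to_tail", "different_contig", "distant")
DEFAULT_MAX_INTERVENING = 1


@dataclass(frozen=True)
class SyntenyCall:
    species_id: str
    gene_v: str
    gene_vii: str
    arrangement: str
    intervening_gene_count: int | None  # None when genes share no contig
    both_have_introns: bool | None  # None = unknown
    ambiguous: bool = False  # species had multiple V or VII genes

    def __post_init__(self) -> None:
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(f"unknown arrangement {self.arrangement!r}")


def intron_status(model: GeneModel) -> bool | None:
    """True iff the gene model has >= 2 exons, False iff exactly 1, None when
    the exon count is unknown."""
    if model.exon_count is None:
        return None
    return model.exon_count >= 2


def _both_introns(a: GeneModel, b: GeneModel) -> bool | None:
    sa, sb = intron_status(a), intron_status(b)
    if sa is False or sb is False:
        return False
    if sa is None or sb is None:
        return None
    return True


def _count_intervening(
    left: GeneModel, right: GeneModel, contig_genes: list[GeneModel]
) -> int:
    gap_start, gap_end = left.end, right.start
    return sum(
        1
        for g in contig_genes
        if g.gene_id not in (left.gene_id, right.gene_id)
        and g.start > gap_start
        and g.end < gap_end
    )


def _pair_call(
    species: str,
    gv: GeneModel,
    gvii: GeneModel,
    contig_genes: Mapping[str, list[GeneModel]],
    max_intervening: int,
    max_distance: int | None,
    ambiguous: bool,
) -> SyntenyCall:
    introns = _both_introns(gv, gvii)
    if gv.contig != gvii.contig:
        return SyntenyCall(
            species_id=species,
            gene_v=gv.gene_id,
            gene_vii=gvii.gene_id,
            arrangement="different_contig",
            intervening_gene_count=None,
            both_have_introns=introns,
            ambiguous=ambiguous,
        )
    left, right = (gv, gvii) if gv.start <= gvii.start else (gvii, gv)
    n_between = _count_intervening(left, right, contig_genes[gv.contig])
    distance = max(0, right.start - left.end)

    if left.strand == right.strand:
        arrangement = "same_strand"
    elif left.strand == "-" and right.strand == "+":
        # 5' ends face each other across the gap: divergent / head-to-head
        too_far = max_distance is not None and distance > max_distance
        arrangement = (
            "head_to_head" if n_between <= max_intervening and not too_far else "distant"
        )
    else:
        arrangement = "tail_to_tail"
    return SyntenyCall(
        species_id=species,
        gene_v=gv.gene_id,
        gene_vii=gvii.gene_id,
        arrangement=arrangement,
        intervening_gene_count=n_between,
        both_have_introns=introns,
        ambiguous=ambiguous,
    )


def detect_head_to_head(
    models: Iterable[GeneModel],
    assignments: Iterable[ClassAssignment],
    max_intervening: int = DEFAULT_MAX_INTERVENING,
    *,
    max_distance: int | None = None,
) -> list[SyntenyCall]:
    """Call the V/VII arrangement for every species carrying both classes.

    Species with exactly one V and one VII gene yield one call; species with
    multiple V or VII genes yield one call per V x VII pair, flagged
    ambiguous.  The call is symmetric in which gene carries which label.
    """
    models = list(models)
    by_protein = {m.protein_id: m for m in models if m.protein_id}
    contig_genes: dict[str, list[GeneModel]] = {}
    for m in models:
        contig_genes.setdefault(m.contig, []).append(m)

    v_genes: dict[str, list[GeneModel]] = {}
    vii_genes: dict[str, list[GeneModel]] = {}
    for a in assignments:
        if a.class_label not in ("V", "VII"):
            continue
        gene = by_protein.get(a.protein_id)
        if gene is None:
            continue
        (v_genes if a.class_label == "V" else vii_genes).setdefault(
            a.species_id, []
        ).append(gene)

    calls: list[SyntenyCall] = []
    for species in sorted(set(v_genes) & set(vii_genes)):
        vs = sorted(v_genes[species], key=lambda g: g.gene_id)
        viis = sorted(vii_genes[species], key=lambda g: g.gene_id)
        ambiguous = len(vs) > 1 or len(viis) > 1
        for gv in vs:
            for gvii in viis:
                calls.append(
                    _pair_call(
                        species, gv, gvii, contig_genes, max_intervening,
                        max_distance, ambiguous,
                    )
                )
    return calls
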