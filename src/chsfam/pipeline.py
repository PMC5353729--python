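"""Stage orchestration: in-memory analysis core plus file-based stages.

``analyze_dataset`` runs the whole chain on in-memory domain objects (used by
the tests, the acceptance experiments and the numbered analysis drivers);
the ``stage_*`` functions wrap it for the CLI, reading and writing the
documented TSV/JSON artifacts in a working directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .architecture import Architecture, build_architecture
from .classify import (
    ClassAssignment,
    ClassificationSummary,
    classify_species_set,
    summarize_classification,
)
from .dynamics import FamilyProfile, TaxonSummary, profile_counts, taxon_summary
from .io_formats import (
    DomainHit,
    GeneModel,
    ProteinRecord,
    TaxonomyTable,
    parse_domain_hits,
    parse_gene_models,
    parse_sequences,
    parse_taxonomy,
)
from .motifs import PATTERN_SETS, Con1Region, MotifPatternSet, extract_con1, scan_motifs
from .phylo import Alignment, ReferenceSet, align_con1
from .screen import DEFAULT_EVALUE_MAX, ScreenResult, filter_candidates
from .synteny import SyntenyCall, detect_head_to_head

__all__ = [
    "AnalysisParams",
    "AnalysisResult",
    "extract_all_con1",
    "reference_from_labeled",
    "load_reference",
    "analyze_dataset",
    "write_screen_tsv",
    "write_con1_tsv",
    "read_con1_tsv",
    "write_architecture_tsv",
    "write_assignments_tsv",
    "read_assignments_tsv",
    "write_synteny_tsv",
]


@dataclass(frozen=True)
class AnalysisParams:
    pattern_set: str = "primary"
    evalue_max: float = DEFAULT_EVALUE_MAX
    site_rule: str = "partial_deletion"
    coverage: float = 0.95
    correction: str | None = None
    n_reps: int = 100
    support_threshold: float = 60.0
    strict_support: bool = True
    max_intervening: int = 1
    max_distance: int | None = None
    seed: int = 0

    @property
    def motifs(self) -> MotifPatternSet:
        return PATTERN_SETS[self.pattern_set]


@dataclass
class AnalysisResult:
    screen_results: list[ScreenResult]
    con1: dict[str, Con1Region | None]
    architectures: dict[str, Architecture]
    assignments: list[ClassAssignment]
    summary: ClassificationSummary
    profile: FamilyProfile | None
    taxon_summaries: dict[str, TaxonSummary] = field(default_factory=dict)
    synteny_calls: list[SyntenyCall] = field(default_factory=list)

    @property
    def accepted_ids(self) -> set[str]:
        return {r.protein_id for r in self.screen_results if r.accepted}


def extract_all_con1(
    records: Iterable[ProteinRecord], patterns: MotifPatternSet | None = None
) -> dict[str, Con1Region | None]:
    pats = patterns or PATTERN_SETS["primary"]
    out: dict[str, Con1Region | None] = {}
    for rec in records:
        hits = scan_motifs(rec, pats)
        out[rec.protein_id] = extract_con1(rec, hits, pats)
    return out


def reference_from_labeled(
    labeled: Sequence[tuple[str, str, str]]
) -> ReferenceSet:
    """Build a :class:`ReferenceSet` from (id, class_label, sequence) rows.

    Equal-length region sets (e.g. the indel-free synthetic reference) are
    used column-for-column; otherwise the built-in progressive aligner runs.
    """
    ids = tuple(rid for rid, _, _ in labeled)
    seqs = [seq for _, _, seq in labeled]
    labels = {rid: lab for rid, lab, _ in labeled}
    if len({len(s) for s in seqs}) == 1:
        aln = Alignment(ids=ids, rows=tuple(seqs))
    else:
        aln = align_con1(list(zip(ids, seqs)))
    return ReferenceSet(alignment=aln, labels=labels)


def load_reference(path: str | Path) -> ReferenceSet:
    """Read a labelled reference CON1 FASTA (``>id class=LABEL`` headers)."""
    from Bio import SeqIO

    labeled: list[tuple[str, str, str]] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.description.split()[0]
        label = None
        for tok in entry.description.split()[1:]:
            if tok.startswith("class="):
                label = tok[len("class="):]
        if label is None:
            raise ValueError(f"reference entry {rid!r} lacks a class= label")
        labeled.append((rid, label, str(entry.seq).upper()))
    if not labeled:
        raise ValueError(f"empty reference file {path}")
    return reference_from_labeled(labeled)


def analyze_dataset(
    records: Iterable[ProteinRecord],
    hits: Iterable[DomainHit],
    gene_models: Iterable[GeneModel],
    taxonomy: TaxonomyTable | None,
    reference: ReferenceSet,
    params: AnalysisParams = AnalysisParams(),
) -> AnalysisResult:
    """Screen, type, classify, profile and call synteny on one dataset."""
    records = list(records)
    hits = list(hits)
    con1 = extract_all_con1(records, params.motifs)
    screen_results = filter_candidates(
        records, hits, con1, evalue_max=params.evalue_max
    )
    accepted = {r.protein_id for r in screen_results if r.accepted}
    accepted_records = [r for r in records if r.protein_id in accepted]

    architectures = {
        rec.protein_id: build_architecture(rec, hits, con1[rec.protein_id])
        for rec in accepted_records
    }

    assignments: list[ClassAssignment] = []
    by_species: dict[str, list[ProteinRecord]] = {}
    for rec in accepted_records:
        by_species.setdefault(rec.species_id, []).append(rec)
    for species in sorted(by_species):
        assignments.extend(
            classify_species_set(
                by_species[species],
                architectures,
                {p: r for p, r in con1.items() if r is not None},
                reference,
                threshold=params.support_threshold,
                strict=params.strict_support,
                n_reps=params.n_reps,
                seed=params.seed,
                site_rule=params.site_rule,
                coverage=params.coverage,
                correction=params.correction,
            )
        )

    summary = summarize_classification(assignments)
    profile = None
    taxon_summaries: dict[str, TaxonSummary] = {}
    if taxonomy is not None:
        profile = profile_counts(assignments, taxonomy)
        taxa: list[str] = []
        for sp in taxonomy.species_ids:
            for name in taxonomy.lineage(sp) + taxonomy.tags(sp):
                if name not in taxa:
                    taxa.append(name)
        for taxon in taxa:
            taxon_summaries[taxon] = taxon_summary(profile, taxonomy, taxon)

    synteny_calls = detect_head_to_head(
        gene_models,
        assignments,
        params.max_intervening,
        max_distance=params.max_distance,
    )
    return AnalysisResult(
        screen_results=screen_results,
        con1=con1,
        architectures=architectures,
        assignments=assignments,
        summary=summary,
        profile=profile,
        taxon_summaries=taxon_summaries,
        synteny_calls=synteny_calls,
    )


# ---------------------------------------------------------------------------
# TSV artifacts (file-based stage boundaries)


def write_screen_tsv(results: Iterable[ScreenResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\taccepted\treasons\n")
        for r in results:
            fh.write(f"{r.protein_id}\t{int(r.accepted)}\t{','.join(r.reasons)}\n")


def write_con1_tsv(con1: Mapping[str, Con1Region | None], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\tsequence\n")
        for pid in sorted(con1):
            region = con1[pid]
            if region is None:
                fh.write(f"{pid}\t.\t.\t.\n")
            else:
                fh.write(f"{pid}\t{region.start}\t{region.end}\t{region.sequence}\n")


def read_con1_tsv(path: str | Path) -> dict[str, tuple[int, int, str] | None]:
    out: dict[str, tuple[int, int, str] | None] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            pid, start, end, seq = line.rstrip("\n").split("\t")
            out[pid] = None if start == "." else (int(start), int(end), seq)
    return out


def write_architecture_tsv(
    architectures: Mapping[str, Architecture],
    types: Mapping[str, str],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\telements\ttype_label\n")
        for pid in sorted(architectures):
            arch = architectures[pid]
            fh.write(f"{pid}\t{'-'.join(arch.elements)}\t{types[pid]}\n")


def write_assignments_tsv(
    assignments: Iterable[ClassAssignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "protein_id\tspecies_id\tclass\tdivision\tsupport\ttype\thost\tnoisy\n"
        )
        for a in assignments:
            fh.write(
                f"{a.protein_id}\t{a.species_id}\t{a.class_label}\t"
                f"{a.division if a.division is not None else '.'}\t"
                f"{a.support if a.support is not None else '.'}\t"
                f"{a.type_label}\t{a.host_clade_label or '.'}\t{int(a.noisy)}\n"
            )


def read_assignments_tsv(path: str | Path) -> list[ClassAssignment]:
    out: list[ClassAssignment] = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            pid, sp, cls, div, sup, typ, host, noisy = line.rstrip("\n").split("\t")
            out.append(
                ClassAssignment(
                    protein_id=pid,
                    species_id=sp,
                    class_label=cls,
                    division=None if div == "." else int(div),
                    support=None if sup == "." else float(sup),
                    type_label=typ,
                    host_clade_label=None if host == "." else host,
                    noisy=bool(int(noisy)),
                )
            )
    return out


def write_synteny_tsv(calls: Iterable[SyntenyCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "species_id\tgene_v\tgene_vii\tarrangement\tintervening\t"
            "both_have_introns\tambiguous\n"
        )
        for c in calls:
            introns = "." if c.both_have_introns is None else int(c.both_have_introns)
            inter = "." if c.intervening_gene_count is None else c.intervening_gene_count
            fh.write(
                f"{c.species_id}\t{c.gene_v}\t{c.gene_vii}\t{c.arrangement}\t"
                f"{inter}\t{introns}\t{int(c.ambiguous)}\n"
            )


def load_dataset_dir(data_dir: str | Path):
    """Parse an emitted dataset directory back into domain objects."""
    data_dir = Path(data_dir)
    taxonomy = parse_taxonomy(data_dir / "taxonomy.tsv")
    records = parse_sequences(data_dir / "proteins.fasta", taxonomy=taxonomy)
    hits = parse_domain_hits(data_dir / "domain_hits.tsv", "tsv", sequences=records)
    models = parse_gene_models(data_dir / "genes.gff3")
    reference = load_reference(data_dir / "reference_con1.fasta")
    truth = None
    truth_path = data_dir / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
    return records, hits, models, taxonomy, reference, truth
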