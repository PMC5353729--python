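"""Synthetic proteome generator with planted ground truth.

Emulates the statistical structure the analysis assumes — class-structured
CON1 divergence, class-specific domain architectures, decoy proteins,
phylogenetically incoherent Type B1 copies, and head-to-head ChsV/ChsVII
gene pairs — so that every pipeline stage is testable without any genome
download.

Sequence model
--------------
A root CON1 sequence (default 141 aa, the mean catalytic-region size in
large fungal surveys) carries the three anchor motifs: QxxEY at the start,
EDRxL at the centre, QxRRW at the end.  It evolves along a fixed two-level
tree (root -> 3 divisions -> 8 class lineages, with 23b a sister lineage of
II+III inside Division 1); each branch substitutes a Bernoulli-sampled set
of sites uniformly over the 19 alternative residues, and the fixed letters
of the three motifs are frozen so motifs survive.  Per-branch substitution
rates are calibrated numerically so that the *expected pairwise p-distance
over the whole region* between two class members equals the configured
within-class divergence, and between two sibling-class consensuses equals
the configured between-class divergence (p-distance is then an unbiased
estimate of the configured divergence).  No indels are simulated, so all
regions share one length and the emitted reference alignment is gap-free.

Every emitted protein is assembled as flank + class-appropriate domain
segments + CON1 + flank, and the domain-hit table is emitted to match the
planted architecture exactly.  A rejection loop re-draws any protein whose
full sequence happens to contain a spurious motif triple that would change
the minimal-span CON1 extraction, so extractor output always matches the
planted coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .io_formats import (
    DomainHit,
    GeneModel,
    ProteinRecord,
    TaxonomyTable,
    write_domain_hits,
    write_sequences,
    write_taxonomy,
)
from .motifs import extract_con1

__all__ = [
    "SpeciesSpec",
    "SimConfig",
    "SyntheticTruth",
    "SimulatedDataset",
    "simulate_family",
    "emit_dataset",
    "default_species_table",
    "ALL_CLASSES",
]

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
ALL_CLASSES = ("I", "II", "III", "IV", "V", "VI", "VII", "23b")

CLASS_TYPE = {
    "I": "A2", "II": "A2", "III": "A2", "23b": "A2",
    "IV": "B2", "V": "B4", "VI": "B1", "VII": "B4",
}
CLASS_DIVISION_LINEAGE = {
    "I": "D1", "II": "D1", "III": "D1", "23b": "D1",
    "IV": "D2", "V": "D2", "VII": "D2", "VI": "D3",
}

SEGMENT_LENGTHS = {
    "PF08407": 50, "PF01644": 60, "PF00063": 80,
    "PF00173": 45, "PF08766": 40,
}
CS2_PAD = 20  # residues of intact PF03142 on each side of CON1
LINKER = 8


@dataclass(frozen=True)
class SpeciesSpec:
    """Planted repertoire of one synthetic species."""

    species_id: str
    lineage: tuple[str, ...]
    tags: tuple[str, ...] = ()
    class_counts: dict[str, int] = field(default_factory=dict)
    n_noisy_b1: int = 0
    n_decoy_no_motif: int = 1
    n_decoy_no_domain: int = 1
    tandem_vii_v: bool = False  # eligible for the head-to-head arrangement


def default_species_table() -> tuple[SpeciesSpec, ...]:
    """Twelve species emulating the survey's taxon structure: filamentous
    Pezizomycotina-like (full 7-class repertoires, head-to-head V/VII),
    contracted yeasts, Basidiomycota-like species without Class VI, and
    early-diverging-like species expanded by unclassifiable Type B1 copies.
    """
    full = {c: 1 for c in ("I", "II", "III", "IV", "V", "VI", "VII")}
    species: list[SpeciesSpec] = []
    for i in range(1, 6):
        counts = dict(full)
        if i <= 2:
            counts["23b"] = 1
        species.append(
            SpeciesSpec(
                species_id=f"sp{i:02d}",
                lineage=("Ascomycota", "Pezizomycotina", "Sordariomycetes"),
                class_counts=counts,
                tandem_vii_v=True,
            )
        )
    for i in (6, 7):
        species.append(
            SpeciesSpec(
                species_id=f"sp{i:02d}",
                lineage=("Ascomycota", "Saccharomycotina", "Saccharomycetes"),
                tags=("yeast",),
                class_counts={"I": 1, "II": 1, "IV": 1},
            )
        )
    for i in (8, 9, 10):
        species.append(
            SpeciesSpec(
                species_id=f"sp{i:02d}",
                lineage=("Basidiomycota", "Agaricomycotina", "Agaricomycetes"),
                class_counts={c: 1 for c in ("I", "II", "III", "IV", "V", "VII")},
            )
        )
    for i in (11, 12):
        species.append(
            SpeciesSpec(
                species_id=f"sp{i:02d}",
                lineage=("Chytridiomycota",),
                tags=("early_diverging",),
                class_counts={"III": 2, "IV": 2, "V": 1, "VI": 1, "VII": 1},
                n_noisy_b1=8,
            )
        )
    return tuple(species)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    species: tuple[SpeciesSpec, ...] = field(default_factory=default_species_table)
    within_class_divergence: float = 0.05
    between_class_divergence: float = 0.5
    con1_length: int = 141
    flank_length: int = 25
    n_reference_per_class: int = 3
    head_to_head_fraction: float = 0.95
    intervening_gene_probability: float = 17.0 / 95.0

    def __post_init__(self) -> None:
        if self.within_class_divergence < 0 or self.between_class_divergence < 0:
            raise ValueError("divergences must be non-negative")
        if self.within_class_divergence > self.between_class_divergence:
            import warnings

            warnings.warn(
                "within-class divergence exceeds between-class divergence; "
                "classes will not be identifiable",
                stacklevel=2,
            )
        if self.con1_length < 20:
            raise ValueError("con1_length too short to host the three motifs")
        for spec in self.species:
            for cls in spec.class_counts:
                if cls not in ALL_CLASSES:
                    raise ValueError(
                        f"{spec.species_id}: unknown class {cls!r} in repertoire"
                    )


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted per-protein and per-species ground truth."""

    proteins: dict[str, dict]  # pid -> {species, role, class, type, con1}
    species: dict[str, dict]  # sp -> {head_to_head, intervening, gene_v, gene_vii}

    def role(self, protein_id: str) -> str:
        return self.proteins[protein_id]["role"]


@dataclass(frozen=True)
class SimulatedDataset:
    records: list[ProteinRecord]
    domain_hits: list[DomainHit]
    gene_models: list[GeneModel]
    taxonomy: TaxonomyTable
    reference: list[tuple[str, str, str]]  # (ref_id, class_label, sequence)
    truth: SyntheticTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# substitution machinery


def _motif_layout(L: int) -> tuple[dict[str, int], frozenset[int]]:
    """Anchor positions and the frozen (fixed-letter) site set."""
    mid = L // 2 - 2
    anchors = {"QxxEY": 0, "EDRxL": mid, "QxRRW": L - 5}
    frozen = {0, 3, 4, mid, mid + 1, mid + 2, mid + 4, L - 5, L - 3, L - 2, L - 1}
    return anchors, frozenset(frozen)


def _plant_motifs(seq: list[str], L: int) -> None:
    anchors, _ = _motif_layout(L)
    q, e, r = anchors["QxxEY"], anchors["EDRxL"], anchors["QxRRW"]
    seq[q], seq[q + 3], seq[q + 4] = "Q", "E", "Y"
    seq[e], seq[e + 1], seq[e + 2], seq[e + 4] = "E", "D", "R", "L"
    seq[r], seq[r + 2], seq[r + 3] = "Q", "R", "R"
    seq[r + 4] = "W"


def _pairwise_p(rate: float) -> float:
    """Expected mismatch probability at a mutable site between two lineages
    that each substituted with probability *rate* (uniform over the 19
    alternatives) since their common ancestor."""
    return 2 * rate * (1 - rate) + rate * rate * (18.0 / 19.0)


def _rate_for_divergence(target: float, L: int, n_frozen: int) -> float:
    """Per-branch substitution probability whose expected pairwise p-distance
    over the whole region (frozen motif sites included) equals *target*."""
    if target <= 0:
        return 0.0
    dilution = (L - n_frozen) / L
    limit = _pairwise_p(0.999) * dilution
    if target >= limit:
        raise ValueError(
            f"divergence {target} unreachable (saturation limit ~{limit:.3f})"
        )
    return float(brentq(lambda r: _pairwise_p(r) * dilution - target, 0.0, 0.999))


def _mutate(
    seq: str, rate: float, frozen: frozenset[int], rng: np.random.Generator
) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        if int(i) in frozen:
            continue
        old = chars[i]
        alternatives = RESIDUES.replace(old, "")
        chars[i] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(chars)


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(RESIDUES[i] for i in rng.integers(0, len(RESIDUES), size=length))


class _Con1Factory:
    """Root + class consensus sequences and member drawing."""

    def __init__(self, config: SimConfig, rng: np.random.Generator) -> None:
        L = config.con1_length
        self.L = L
        _, self.frozen = _motif_layout(L)
        root = list(_random_seq(L, rng))
        _plant_motifs(root, L)
        self.root = "".join(root)

        n_frozen = len(self.frozen)
        self.member_rate = _rate_for_divergence(
            config.within_class_divergence, L, n_frozen
        )
        class_rate = _rate_for_divergence(
            config.between_class_divergence, L, n_frozen
        )
        division_rate = _rate_for_divergence(
            config.between_class_divergence / 2.0, L, n_frozen
        )
        self.noisy_rate = class_rate

        divisions = {
            name: _mutate(self.root, division_rate, self.frozen, rng)
            for name in ("D1", "D2", "D3")
        }
        # 23b branches with II+III from a shared sub-ancestor inside Division 1
        d1_sub = _mutate(divisions["D1"], division_rate / 2.0, self.frozen, rng)
        parents = {cls: divisions[CLASS_DIVISION_LINEAGE[cls]] for cls in ALL_CLASSES}
        for cls in ("II", "III", "23b"):
            parents[cls] = d1_sub
        self.consensus = {
            cls: _mutate(parents[cls], class_rate, self.frozen, rng)
            for cls in ALL_CLASSES
        }

    def member(self, cls: str, rng: np.random.Generator) -> str:
        return _mutate(self.consensus[cls], self.member_rate, self.frozen, rng)

    def noisy(self, rng: np.random.Generator) -> str:
        return _mutate(self.root, self.noisy_rate, self.frozen, rng)

    def broken_motif(self, rng: np.random.Generator) -> str:
        """A CON1-like region whose internal EDRxL motif is destroyed."""
        seq = list(self.noisy(rng))
        mid = self.L // 2 - 2
        for off in (0, 1, 2, 4):
            seq[mid + off] = "G"
        return "".join(seq)


# ---------------------------------------------------------------------------
# protein assembly


def _hit(pid: str, acc: str, start: int, end: int, rng: np.random.Generator) -> DomainHit:
    return DomainHit(
        protein_id=pid,
        accession=acc,
        start=start,
        end=end,
        score=round(float(rng.uniform(60, 400)), 1),
        evalue=float(10.0 ** -rng.uniform(10, 50)),
    )


def _assemble(
    pid: str,
    type_label: str,
    con1_seq: str,
    flank: int,
    rng: np.random.Generator,
    *,
    emit_cd04190: bool = False,
    characteristic: bool = True,
) -> tuple[str, list[DomainHit], tuple[int, int]]:
    """Build the full protein for one architecture; returns (sequence, hits,
    planted CON1 interval)."""
    parts: list[str] = [_random_seq(flank, rng)]
    hits: list[DomainHit] = []
    pos = flank

    def add_segment(acc: str) -> None:
        nonlocal pos
        seg = _random_seq(SEGMENT_LENGTHS[acc], rng)
        hits.append(_hit(pid, acc, pos, pos + len(seg), rng))
        parts.append(seg)
        pos += len(seg)
        parts.append(_random_seq(LINKER, rng))
        pos += LINKER

    def add_cs2_con1() -> tuple[int, int]:
        nonlocal pos
        pre, post = _random_seq(CS2_PAD, rng), _random_seq(CS2_PAD, rng)
        cs2_start = pos
        parts.extend([pre, con1_seq, post])
        con1_span = (pos + CS2_PAD, pos + CS2_PAD + len(con1_seq))
        pos += CS2_PAD + len(con1_seq) + CS2_PAD
        hits.append(_hit(pid, "PF03142", cs2_start, pos, rng))
        if emit_cd04190:
            hits.append(_hit(pid, "cd04190", cs2_start, pos, rng))
        return con1_span

    def add_bare_con1() -> tuple[int, int]:
        nonlocal pos
        parts.append(con1_seq)
        span = (pos, pos + len(con1_seq))
        pos += len(con1_seq)
        return span

    if type_label == "A2":
        add_segment("PF08407")
        seg = _random_seq(SEGMENT_LENGTHS["PF01644"], rng)
        hits.append(_hit(pid, "PF01644", pos, pos + len(seg), rng))
        parts.append(seg)
        pos += len(seg)
        con1_span = add_bare_con1()  # PF01644 immediately followed by CON1
    elif type_label == "B2":
        add_segment("PF00173")
        con1_span = add_cs2_con1()
    elif type_label == "B4":
        add_segment("PF00063")
        add_segment("PF00173")
        con1_span = add_cs2_con1()
        parts.append(_random_seq(LINKER, rng))
        pos += LINKER
        add_segment("PF08766")
    elif type_label == "B1":
        con1_span = add_cs2_con1()
    elif type_label == "bare":
        con1_span = add_bare_con1()
    else:
        raise ValueError(f"no assembly rule for type {type_label!r}")

    parts.append(_random_seq(flank, rng))
    if not characteristic:
        hits = [h for h in hits if h.accession not in ("PF03142", "PF01644", "cd04190")]
    return "".join(parts), hits, con1_span


def _draw_protein(
    pid: str,
    type_label: str,
    con1_drawer: Callable[[np.random.Generator], str],
    flank: int,
    rng: np.random.Generator,
    *,
    expect_con1: bool = True,
    emit_cd04190: bool = False,
    characteristic: bool = True,
    max_tries: int = 100,
) -> tuple[str, list[DomainHit], tuple[int, int] | None]:
    """Assembly with a rejection loop: the minimal-span extraction on the
    full sequence must reproduce exactly the planted CON1 interval (or find
    no region at all for motif-broken decoys)."""
    for _ in range(max_tries):
        con1_seq = con1_drawer(rng)
        seq, hits, span = _assemble(
            pid, type_label, con1_seq, flank, rng,
            emit_cd04190=emit_cd04190, characteristic=characteristic,
        )
        region = extract_con1(seq, protein_id=pid)
        if expect_con1:
            if region is not None and (region.start, region.end) == span:
                return seq, hits, span
        else:
            if region is None:
                return seq, hits, None
    raise RuntimeError(f"could not draw a valid sequence for {pid} in {max_tries} tries")


# ---------------------------------------------------------------------------
# gene models


def _exon_lines_and_models(
    genes: list[tuple[str, str, int, int, str, str | None, int | None]],
) -> list[GeneModel]:
    return [
        GeneModel(
            gene_id=gid, contig=contig, start=start, end=end, strand=strand,
            protein_id=pid, exon_count=exons,
        )
        for gid, contig, start, end, strand, pid, exons in genes
    ]


def _place_genes(
    spec: SpeciesSpec,
    protein_ids: list[str],
    roles: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[GeneModel], dict]:
    """Lay the species' genes on one contig; plant the V/VII arrangement."""
    contig = f"{spec.species_id}_c1"
    v_pid = next((p for p in protein_ids if roles[p] == "class:V"), None)
    vii_pid = next((p for p in protein_ids if roles[p] == "class:VII"), None)
    pair = v_pid is not None and vii_pid is not None
    head_to_head = bool(
        pair and spec.tandem_vii_v and rng.random() < config.head_to_head_fraction
    )
    intervening = int(
        head_to_head and rng.random() < config.intervening_gene_probability
    )

    genes: list[tuple[str, str, int, int, str, str | None, int | None]] = []
    pos = 1001
    gene_len = 2500
    spacing = 8000

    def add(pid: str | None, strand: str, exons: int | None, length: int = gene_len) -> str:
        nonlocal pos
        gid = f"{pid}_g" if pid else f"{spec.species_id}_hyp{pos}"
        genes.append((gid, contig, pos, pos + length - 1, strand, pid, exons))
        pos += length + spacing
        return gid

    gene_v = gene_vii = None
    ordinary = [p for p in protein_ids if not (head_to_head and p in (v_pid, vii_pid))]
    for pid in ordinary:
        exons = 3 if roles[pid] in ("class:V", "class:VII") else 2
        add(pid, "+", exons)
    if head_to_head:
        # divergent pair: V on '-' (5' end facing right), VII on '+' downstream
        gid_v = f"{v_pid}_g"
        genes.append((gid_v, contig, pos, pos + gene_len - 1, "-", v_pid, 3))
        gap_start = pos + gene_len
        pos = gap_start + 2200
        if intervening:
            genes.append(
                (f"{spec.species_id}_hyp1", contig, gap_start + 400,
                 gap_start + 1400, "+", None, 1)
            )
        gid_vii = f"{vii_pid}_g"
        genes.append((gid_vii, contig, pos, pos + gene_len - 1, "+", vii_pid, 3))
        pos += gene_len + spacing
        gene_v, gene_vii = gid_v, gid_vii
    elif pair:
        gene_v, gene_vii = f"{v_pid}_g", f"{vii_pid}_g"

    truth = {
        "has_pair": pair,
        "head_to_head": head_to_head,
        "intervening": intervening if head_to_head else 0,
        "gene_v": gene_v,
        "gene_vii": gene_vii,
    }
    return _exon_lines_and_models(genes), truth


# ---------------------------------------------------------------------------
# top level


def simulate_family(config: SimConfig) -> SimulatedDataset:
    """Generate a full synthetic dataset plus its planted truth.

    Deterministic for a fixed config (byte-identical emitted files).
    """
    rng = np.random.default_rng(config.seed)
    factory = _Con1Factory(config, rng)

    reference: list[tuple[str, str, str]] = []
    for cls in ALL_CLASSES:
        for k in range(1, config.n_reference_per_class + 1):
            reference.append((f"ref_{cls}_{k}", cls, factory.member(cls, rng)))

    records: list[ProteinRecord] = []
    all_hits: list[DomainHit] = []
    gene_models: list[GeneModel] = []
    truth_proteins: dict[str, dict] = {}
    truth_species: dict[str, dict] = {}
    lineages: dict[str, tuple[str, ...]] = {}
    tags: dict[str, tuple[str, ...]] = {}

    for spec in config.species:
        lineages[spec.species_id] = spec.lineage
        tags[spec.species_id] = spec.tags
        protein_ids: list[str] = []
        roles: dict[str, str] = {}
        counter = 0

        def next_pid() -> str:
            nonlocal counter
            counter += 1
            return f"{spec.species_id}_p{counter:02d}"

        for cls in ALL_CLASSES:
            for _ in range(spec.class_counts.get(cls, 0)):
                pid = next_pid()
                tlab = CLASS_TYPE[cls]
                emit_cd = tlab in ("B1", "B2", "B4") and rng.random() < 0.3
                seq, hits, span = _draw_protein(
                    pid, tlab, lambda g, c=cls: factory.member(c, g),
                    config.flank_length, rng, emit_cd04190=emit_cd,
                )
                records.append(
                    ProteinRecord(pid, spec.species_id, seq, spec.lineage)
                )
                all_hits.extend(hits)
                protein_ids.append(pid)
                roles[pid] = f"class:{cls}"
                truth_proteins[pid] = {
                    "species": spec.species_id, "role": f"class:{cls}",
                    "class": cls, "type": tlab, "con1": list(span),
                }
        for _ in range(spec.n_noisy_b1):
            pid = next_pid()
            seq, hits, span = _draw_protein(
                pid, "B1", factory.noisy, config.flank_length, rng,
            )
            records.append(ProteinRecord(pid, spec.species_id, seq, spec.lineage))
            all_hits.extend(hits)
            protein_ids.append(pid)
            roles[pid] = "noisy_b1"
            truth_proteins[pid] = {
                "species": spec.species_id, "role": "noisy_b1",
                "class": None, "type": "B1", "con1": list(span),
            }
        for _ in range(spec.n_decoy_no_motif):
            pid = next_pid()
            seq, hits, _ = _draw_protein(
                pid, "B1", factory.broken_motif, config.flank_length, rng,
                expect_con1=False,
            )
            records.append(ProteinRecord(pid, spec.species_id, seq, spec.lineage))
            all_hits.extend(hits)
            protein_ids.append(pid)
            roles[pid] = "decoy_no_motif"
            truth_proteins[pid] = {
                "species": spec.species_id, "role": "decoy_no_motif",
                "class": None, "type": None, "con1": None,
            }
        for _ in range(spec.n_decoy_no_domain):
            pid = next_pid()
            seq, hits, span = _draw_protein(
                pid, "bare", factory.noisy, config.flank_length, rng,
                characteristic=False,
            )
            records.append(ProteinRecord(pid, spec.species_id, seq, spec.lineage))
            all_hits.extend(hits)
            protein_ids.append(pid)
            roles[pid] = "decoy_no_domain"
            truth_proteins[pid] = {
                "species": spec.species_id, "role": "decoy_no_domain",
                "class": None, "type": None, "con1": list(span),
            }

        models, sp_truth = _place_genes(spec, protein_ids, roles, config, rng)
        gene_models.extend(models)
        truth_species[spec.species_id] = sp_truth

    return SimulatedDataset(
        records=records,
        domain_hits=all_hits,
        gene_models=gene_models,
        taxonomy=TaxonomyTable(lineages, tags),
        reference=reference,
        truth=SyntheticTruth(proteins=truth_proteins, species=truth_species),
        config=config,
    )


# ---------------------------------------------------------------------------
# emission


def _write_gff3(models: list[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            attrs = f"ID={m.gene_id}"
            if m.protein_id:
                attrs += f";protein_id={m.protein_id}"
            fh.write(
                f"{m.contig}\tchsfam_sim\tgene\t{m.start}\t{m.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            if m.exon_count is None:
                continue
            tid = f"{m.gene_id}.t1"
            fh.write(
                f"{m.contig}\tchsfam_sim\tmRNA\t{m.start}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={tid};Parent={m.gene_id}\n"
            )
            span = m.end - m.start + 1
            n = m.exon_count
            exon_len = max(1, (span - 50 * (n - 1)) // n)
            s = m.start
            for k in range(n):
                e = m.end if k == n - 1 else min(m.end, s + exon_len - 1)
                fh.write(
                    f"{m.contig}\tchsfam_sim\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={tid}.e{k + 1};Parent={tid}\n"
                )
                s = e + 51
    # exon layout is cosmetic; only the exon count is consumed downstream


def emit_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as FASTA / TSV / GFF3 / JSON; re-parsing the files
    reproduces the in-memory dataset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": out / "proteins.fasta",
        "domain_hits": out / "domain_hits.tsv",
        "genes": out / "genes.gff3",
        "taxonomy": out / "taxonomy.tsv",
        "reference": out / "reference_con1.fasta",
        "truth": out / "truth.json",
    }
    write_sequences(dataset.records, paths["proteins"])
    write_domain_hits(dataset.domain_hits, paths["domain_hits"])
    _write_gff3(dataset.gene_models, paths["genes"])
    write_taxonomy(dataset.taxonomy, paths["taxonomy"])
    with open(paths["reference"], "w") as fh:
        for rid, label, seq in dataset.reference:
            fh.write(f">{rid} class={label}\n{seq}\n")
    truth_doc = {
        "proteins": dataset.truth.proteins,
        "species": dataset.truth.species,
        "config": {
            "seed": dataset.config.seed,
            "within_class_divergence": dataset.config.within_class_divergence,
            "between_class_divergence": dataset.config.between_class_divergence,
            "con1_length": dataset.config.con1_length,
        },
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
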