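"""Synthetic generator: determinism, planted structure, calibration."""

import itertools

import numpy as np
import pytest

from chsfam.motifs import extract_con1, scan_motifs
from chsfam.pipeline import load_dataset_dir
from chsfam.simulate import (
    SimConfig,
    SpeciesSpec,
    emit_dataset,
    simulate_family,
)


def _small_config(seed=0, **kw):
    species = (
        SpeciesSpec(
            species_id="spA",
            lineage=("Ascomycota", "Pezizomycotina", "X"),
            class_counts={c: 1 for c in ("I", "II", "III", "IV", "V", "VI", "VII")},
            tandem_vii_v=True,
        ),
        SpeciesSpec(
            species_id="spB",
            lineage=("Chytridiomycota",),
            tags=("early_diverging",),
            class_counts={"IV": 1},
            n_noisy_b1=2,
        ),
    )
    return SimConfig(seed=seed, species=species, **kw)


class TestDeterminism:
    def test_same_seed_same_dataset(self):
        d1 = simulate_family(_small_config(3))
        d2 = simulate_family(_small_config(3))
        assert [r.sequence for r in d1.records] == [r.sequence for r in d2.records]
        assert d1.truth.proteins == d2.truth.proteins
        assert d1.reference == d2.reference

    def test_different_seed_differs(self):
        d1 = simulate_family(_small_config(3))
        d2 = simulate_family(_small_config(4))
        assert [r.sequence for r in d1.records] != [r.sequence for r in d2.records]

    def test_emitted_files_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a", tmp_path / "b"
        emit_dataset(simulate_family(_small_config(5)), p1)
        emit_dataset(simulate_family(_small_config(5)), p2)
        for f in sorted(p1.iterdir()):
            assert f.read_bytes() == (p2 / f.name).read_bytes()


class TestPlantedStructure:
    def test_zero_within_divergence_gives_identical_members(self):
        cfg = _small_config(1, within_class_divergence=0.0)
        ds = simulate_family(cfg)
        seqs = {}
        for pid, info in ds.truth.proteins.items():
            if info["role"].startswith("class:"):
                s, e = info["con1"]
                rec = next(r for r in ds.records if r.protein_id == pid)
                seqs.setdefault(info["class"], set()).add(rec.sequence[s:e])
        for cls, members in seqs.items():
            assert len(members) == 1, cls

    def test_extractor_matches_planted_coordinates(self, default_dataset):
        for rec in default_dataset.records:
            info = default_dataset.truth.proteins[rec.protein_id]
            region = extract_con1(rec)
            if info["con1"] is None:
                assert region is None
            else:
                assert region is not None
                assert [region.start, region.end] == info["con1"]

    def test_decoys_lack_a_motif_type(self, default_dataset):
        for rec in default_dataset.records:
            info = default_dataset.truth.proteins[rec.protein_id]
            if info["role"] != "decoy_no_motif":
                continue
            names = {h.motif_name for h in scan_motifs(rec)}
            assert extract_con1(rec) is None
            assert len(names) < 3 or extract_con1(rec) is None

    def test_truth_ids_equal_fasta_ids(self, default_dataset):
        assert set(default_dataset.truth.proteins) == {
            r.protein_id for r in default_dataset.records
        }

    def test_con1_lengths_within_surveyed_range(self, default_dataset):
        """Generated regions fall in the empirically observed 97-1200 aa
        span (the default sits at the observed mean, 141)."""
        for info in default_dataset.truth.proteins.values():
            if info["con1"] is None:
                continue
            s, e = info["con1"]
            assert 97 <= e - s <= 1200

    def test_head_to_head_pairs_planted_with_exon_counts(self, default_dataset):
        by_id = {m.gene_id: m for m in default_dataset.gene_models}
        n_pairs = 0
        for sp, info in default_dataset.truth.species.items():
            if not info["head_to_head"]:
                continue
            n_pairs += 1
            gv, gw = by_id[info["gene_v"]], by_id[info["gene_vii"]]
            assert gv.contig == gw.contig
            assert {gv.strand, gw.strand} == {"+", "-"}
            assert gv.exon_count >= 2 and gw.exon_count >= 2
        assert n_pairs >= 1

    def test_inconsistent_repertoire_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            SimConfig(
                species=(
                    SpeciesSpec("s", ("P",), class_counts={"VIII": 1}),
                )
            )

    def test_within_above_between_warns(self):
        with pytest.warns(UserWarning, match="identifiable"):
            _small_config(0, within_class_divergence=0.6,
                          between_class_divergence=0.5)


class TestRoundTrip:
    def test_emit_then_parse_reproduces_dataset(self, tmp_path):
        ds = simulate_family(_small_config(2))
        emit_dataset(ds, tmp_path)
        records, hits, models, taxonomy, reference, truth = load_dataset_dir(tmp_path)
        assert [(r.protein_id, r.species_id, r.sequence) for r in records] == [
            (r.protein_id, r.species_id, r.sequence) for r in ds.records
        ]
        key = lambda hs: sorted(
            (h.protein_id, h.accession, h.start, h.end) for h in hs
        )
        assert key(hits) == key(ds.domain_hits)
        gkey = lambda ms: sorted(
            (m.gene_id, m.contig, m.start, m.end, m.strand, m.protein_id,
             m.exon_count)
            for m in ms
        )
        assert gkey(models) == gkey(ds.gene_models)
        assert truth["proteins"] == ds.truth.proteins
        assert set(reference.labels.values()) == {
            "I", "II", "III", "IV", "V", "VI", "VII", "23b"
        }


class TestDivergenceCalibration:
    def test_within_class_pairwise_divergence_matches_expectation(self):
        """Mean pairwise p-distance among class members tracks the
        configured within-class divergence to within 3 standard errors
        (>= 50 pairs)."""
        species = tuple(
            SpeciesSpec(
                species_id=f"s{i}",
                lineage=("Ascomycota", "Pezizomycotina", "X"),
                class_counts={"II": 4},
                n_decoy_no_motif=0,
                n_decoy_no_domain=0,
            )
            for i in range(6)
        )
        cfg = SimConfig(seed=9, species=species, within_class_divergence=0.05)
        ds = simulate_family(cfg)
        regions = []
        for pid, info in sorted(ds.truth.proteins.items()):
            s, e = info["con1"]
            rec = next(r for r in ds.records if r.protein_id == pid)
            regions.append(rec.sequence[s:e])
        pairs = list(itertools.combinations(regions, 2))
        assert len(pairs) >= 50
        dists = [
            sum(a != b for a, b in zip(x, y)) / len(x) for x, y in pairs
        ]
        mean = float(np.mean(dists))
        se = float(np.std(dists, ddof=1) / np.sqrt(len(dists)))
        assert abs(mean - 0.05) <= 3 * max(se, 1e-4)
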