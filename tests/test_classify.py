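"""Class calls, the noisy-exclusion rule and classification summaries."""

import pytest

from chsfam.classify import (
    ClassAssignment,
    assign_class,
    classify_species_set,
    flag_noisy,
    summarize_classification,
)
from chsfam.phylo import Placement
from chsfam.pipeline import AnalysisParams, analyze_dataset, reference_from_labeled


def _placement(host, support):
    return Placement(query_id="q", host_clade_label=host, support=support)


class TestAssignClass:
    @pytest.mark.parametrize(
        "type_label,host,support,expected",
        [
            ("B4", "V", 85.0, ("V", 2)),
            ("A2", "23b", 70.0, ("23b", 1)),
            ("B2", "IV", 99.0, ("IV", 2)),
            ("B1", "VI", 61.0, ("VI", 3)),
            ("B2", "V", 90.0, ("unclassified", None)),  # type/class conflict
            ("B4", "V", 60.0, ("unclassified", None)),  # strict > 60
            ("B4", "V", 12.0, ("unclassified", None)),  # weak support
            ("A2", None, None, ("unclassified", None)),  # unplaced
        ],
    )
    def test_rule_table(self, type_label, host, support, expected):
        label, division, _ = assign_class(type_label, _placement(host, support))
        assert (label, division) == expected

    def test_threshold_inclusive_mode(self):
        label, _, support = assign_class(
            "B4", _placement("V", 60.0), strict=False
        )
        assert label == "V" and support == 60.0


class TestFlagNoisy:
    @pytest.mark.parametrize("t", ["A1", "A3", "B3"])
    def test_scattered_types_always_noisy(self, t):
        assert flag_noisy(t, _placement("V", 100.0))
        assert flag_noisy(t, None)

    def test_b1_inside_division3_clade_exempt(self):
        assert not flag_noisy("B1", _placement("VI", 80.0))

    def test_b1_outside_division_clades_noisy(self):
        assert flag_noisy("B1", _placement(None, None))
        assert flag_noisy("B1", _placement("II", 95.0))

    def test_b1_weakly_supported_noisy(self):
        assert flag_noisy("B1", _placement("VI", 30.0))

    @pytest.mark.parametrize("t", ["A2", "B2", "B4"])
    def test_core_types_never_noisy(self, t):
        assert not flag_noisy(t, _placement(None, None))


class TestClassifySpeciesSet:
    def test_reference_must_carry_all_seven_classes(self, default_dataset):
        partial = [r for r in default_dataset.reference if r[1] in ("I", "II")]
        with pytest.raises(ValueError, match="master"):
            classify_species_set(
                [], {}, {}, reference_from_labeled(partial)
            )

    def test_species_with_no_proteins_yields_empty(self, default_reference):
        assert classify_species_set([], {}, {}, default_reference) == []

    def test_low_divergence_species_recovers_planted_classes(
        self, default_dataset, default_con1, default_reference
    ):
        from chsfam.architecture import build_architecture

        sp = "sp01"
        records = [
            r
            for r in default_dataset.records
            if r.species_id == sp
            and default_dataset.truth.proteins[r.protein_id]["role"].startswith("class:")
        ]
        archs = {
            r.protein_id: build_architecture(
                r, default_dataset.domain_hits, default_con1[r.protein_id]
            )
            for r in records
        }
        con1 = {r.protein_id: default_con1[r.protein_id] for r in records}
        got = classify_species_set(
            records, archs, con1, default_reference, n_reps=50, seed=0
        )
        for a in got:
            planted = default_dataset.truth.proteins[a.protein_id]["class"]
            assert a.class_label == planted

    def test_rerun_same_seed_identical(
        self, default_dataset, default_con1, default_reference
    ):
        from chsfam.architecture import build_architecture

        records = [
            r for r in default_dataset.records if r.species_id == "sp06"
        ]
        accepted = [
            r
            for r in records
            if not default_dataset.truth.proteins[r.protein_id]["role"].startswith(
                "decoy"
            )
        ]
        archs = {
            r.protein_id: build_architecture(
                r, default_dataset.domain_hits, default_con1[r.protein_id]
            )
            for r in accepted
        }
        con1 = {r.protein_id: default_con1[r.protein_id] for r in accepted}
        a1 = classify_species_set(
            accepted, archs, con1, default_reference, n_reps=25, seed=5
        )
        a2 = classify_species_set(
            accepted, archs, con1, default_reference, n_reps=25, seed=5
        )
        assert a1 == a2


def _assignment(pid, label, *, noisy=False, type_label="A2", species="sp1"):
    return ClassAssignment(
        protein_id=pid,
        species_id=species,
        class_label=label,
        division=None,
        support=None,
        type_label=type_label,
        host_clade_label=None,
        noisy=noisy,
    )


class TestSummary:
    def test_counts_sum_to_total(self):
        assignments = [
            _assignment("p1", "I"),
            _assignment("p2", "V", type_label="B4"),
            _assignment("p3", "unclassified", noisy=True, type_label="B1"),
        ]
        s = summarize_classification(assignments)
        assert s.total == 3
        assert sum(s.counts.values()) == 3
        assert s.excluded_count == 1
        assert s.per_type == {"A2": 1, "B4": 1, "B1": 1}

    def test_empty_input_all_zero(self):
        s = summarize_classification([])
        assert s.total == 0 and s.excluded_count == 0
        assert all(v == 0 for v in s.counts.values())

    def test_partition_property_full_pipeline(
        self, default_dataset, default_reference
    ):
        """Every screened-in protein receives exactly one class label."""
        result = analyze_dataset(
            default_dataset.records,
            default_dataset.domain_hits,
            default_dataset.gene_models,
            default_dataset.taxonomy,
            default_reference,
            AnalysisParams(n_reps=25, seed=0),
        )
        assert len(result.assignments) == len(result.accepted_ids)
        assert {a.protein_id for a in result.assignments} == result.accepted_ids
        assert sum(result.summary.counts.values()) == result.summary.total


def test_recovery_degrades_monotonically_with_divergence():
    """Class recovery is non-increasing as within-class divergence rises
    toward the between-class level (3 levels, small query sets)."""
    from chsfam.evaluate import class_recovery

    rates = [
        class_recovery(w, 0.5, n_queries=16, n_reps=25, seed=3).rate
        for w in (0.0, 0.15, 0.45)
    ]
    assert rates[0] == 100.0
    assert rates[0] >= rates[1] >= rates[2]
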