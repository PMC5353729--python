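"""Head-to-head V/VII detection and intron status."""

import pytest

from chsfam.classify import ClassAssignment
from chsfam.io_formats import GeneModel
from chsfam.synteny import detect_head_to_head, intron_status


def _gene(gid, start, end, strand, pid=None, contig="c1", exons=3):
    return GeneModel(
        gene_id=gid, contig=contig, start=start, end=end, strand=strand,
        protein_id=pid, exon_count=exons,
    )


def _assignment(pid, label, species="sp1"):
    return ClassAssignment(
        protein_id=pid,
        species_id=species,
        class_label=label,
        division=2,
        support=90.0,
        type_label="B4",
        host_clade_label=label,
    )


ASSIGN = [_assignment("pv", "V"), _assignment("pw", "VII")]


class TestArrangements:
    def test_divergent_adjacent_pair_is_head_to_head(self):
        models = [
            _gene("gv", 1000, 3000, "-", "pv"),
            _gene("gw", 3500, 6000, "+", "pw"),
        ]
        (call,) = detect_head_to_head(models, ASSIGN)
        assert call.arrangement == "head_to_head"
        assert call.intervening_gene_count == 0
        assert call.both_have_introns is True

    def test_same_strand_pair(self):
        models = [
            _gene("gv", 1000, 3000, "+", "pv"),
            _gene("gw", 3500, 6000, "+", "pw"),
        ]
        (call,) = detect_head_to_head(models, ASSIGN)
        assert call.arrangement == "same_strand"

    def test_convergent_pair_is_tail_to_tail(self):
        models = [
            _gene("gv", 1000, 3000, "+", "pv"),
            _gene("gw", 3500, 6000, "-", "pw"),
        ]
        (call,) = detect_head_to_head(models, ASSIGN)
        assert call.arrangement == "tail_to_tail"

    def test_one_intervening_hypothetical_gene_allowed(self):
        models = [
            _gene("gv", 1000, 3000, "-", "pv"),
            _gene("hyp", 3200, 3400, "+", None, exons=1),
            _gene("gw", 3500, 6000, "+", "pw"),
        ]
        (call,) = detect_head_to_head(models, ASSIGN)
        assert call.arrangement == "head_to_head"
        assert call.intervening_gene_count == 1

    def test_two_intervening_genes_break_the_call(self):
        models = [
            _gene("gv", 1000, 3000, "-", "pv"),
            _gene("h1", 3100, 3200, "+", None, exons=1),
            _gene("h2", 3250, 3350, "+", None, exons=1),
            _gene("gw", 3500, 6000, "+", "pw"),
        ]
        (call,) = detect_head_to_head(models, ASSIGN)
        assert call.arrangement == "distant"
        assert call.intervening_gene_count == 2

    def test_different_contigs(self):
        models = [
            _gene("gv", 1000, 3000, "-", "pv", contig="c1"),
            _gene("gw", 3500, 6000, "+", "pw", contig="c2"),
        ]
        (call,) = detect_head_to_head(models, ASSIGN)
        assert call.arrangement == "different_contig"
        assert call.intervening_gene_count is None

    def test_distance_cap_configurable(self):
        models = [
            _gene("gv", 1000, 3000, "-", "pv"),
            _gene("gw", 90000, 93000, "+", "pw"),
        ]
        (call,) = detect_head_to_head(models, ASSIGN, max_distance=10000)
        assert call.arrangement == "distant"

    def test_call_invariant_under_label_swap(self):
        models = [
            _gene("gv", 1000, 3000, "-", "pv"),
            _gene("gw", 3500, 6000, "+", "pw"),
        ]
        swapped = [_assignment("pv", "VII"), _assignment("pw", "V")]
        (c1,) = detect_head_to_head(models, ASSIGN)
        (c2,) = detect_head_to_head(models, swapped)
        assert c1.arrangement == c2.arrangement == "head_to_head"

    def test_multiple_copies_flagged_ambiguous(self):
        models = [
            _gene("gv1", 1000, 3000, "-", "pv"),
            _gene("gv2", 10000, 12000, "+", "pv2"),
            _gene("gw", 3500, 6000, "+", "pw"),
        ]
        assigns = ASSIGN + [_assignment("pv2", "V")]
        calls = detect_head_to_head(models, assigns)
        assert len(calls) == 2
        assert all(c.ambiguous for c in calls)

    def test_species_without_both_classes_skipped(self):
        models = [_gene("gv", 1000, 3000, "-", "pv")]
        assert detect_head_to_head(models, [_assignment("pv", "V")]) == []


class TestIntrons:
    @pytest.mark.parametrize("exons,expected", [(3, True), (2, True), (1, False), (None, None)])
    def test_intron_status(self, exons, expected):
        g = _gene("g", 1, 100, "+", exons=exons)
        assert intron_status(g) is expected

    def test_unknown_exons_propagate_to_pair_status(self):
        models = [
            _gene("gv", 1000, 3000, "-", "pv", exons=None),
            _gene("gw", 3500, 6000, "+", "pw"),
        ]
        (call,) = detect_head_to_head(models, ASSIGN)
        assert call.both_have_introns is None

    def test_single_exon_member_makes_pair_false(self):
        models = [
            _gene("gv", 1000, 3000, "-", "pv", exons=1),
            _gene("gw", 3500, 6000, "+", "pw", exons=None),
        ]
        (call,) = detect_head_to_head(models, ASSIGN)
        assert call.both_have_introns is False


def test_planted_genomes_recall_and_false_positives(default_dataset):
    """Detector recall 1.0, false positives 0 at zero annotation noise."""
    from chsfam.evaluate import synteny_performance

    recall, fp = synteny_performance(seed=1)
    assert recall.rate == 100.0
    assert fp.rate == 0.0


def test_planted_pairs_have_introns(default_dataset):
    by_id = {m.gene_id: m for m in default_dataset.gene_models}
    for sp, info in default_dataset.truth.species.items():
        if info["head_to_head"]:
            assert intron_status(by_id[info["gene_v"]]) is True
            assert intron_status(by_id[info["gene_vii"]]) is True
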