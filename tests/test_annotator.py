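"""Gene selection, template strand, feature flags, warnings and the table split."""

import numpy as np
import pytest

from rlanno.annotator import (
    AnnotationParams,
    annotate,
    assign_features,
    select_gene,
    split_tables,
    template_strand,
    warn_flag,
)
from rlanno.bed_io import ExpressionTable
from rlanno.genome_model import (
    FEATURE_NAMES,
    GeneModel,
    GenomicInterval,
    features_with_flanks,
)
from rlanno.overlap_engine import OverlapHit


def _gene(start, end, strand="+", name="g", chrom="chr1"):
    return GeneModel(GenomicInterval(chrom, start, end, name=name, strand=strand),
                     start, start, (0,), (end - start,))


def _hit(peak, gene, ovl, body=None):
    return OverlapHit(peak=peak, gene=gene, overlap_bp=ovl,
                      body_overlap_bp=ovl if body is None else body)


PEAK = GenomicInterval("chr1", 1000, 2000, name="p")


class TestTemplateStrand:
    def test_complement(self):
        assert template_strand("+") == "-"
        assert template_strand("-") == "+"

    def test_unstranded_rejected(self):
        with pytest.raises(ValueError):
            template_strand(".")


class TestSelectGene:
    params = AnnotationParams(expression_threshold=0.5)

    def test_single_hit_wins_outright(self):
        hits = [_hit(PEAK, _gene(0, 5000, name="A"), 100)]
        chosen, reason, expressed = select_gene(PEAK, hits, ExpressionTable({"A": 0.0}), self.params)
        assert chosen.gene.name == "A" and reason == "single_gene"
        assert expressed is False

    def test_highest_expression_beats_larger_overlap(self):
        hits = [_hit(PEAK, _gene(0, 5000, name="A"), 100),
                _hit(PEAK, _gene(0, 9000, name="B"), 900)]
        expr = ExpressionTable({"A": 10.0, "B": 3.0})
        chosen, reason, expressed = select_gene(PEAK, hits, expr, self.params)
        assert chosen.gene.name == "A" and reason == "highest_expression"
        assert expressed is True

    def test_all_below_threshold_falls_back_to_overlap(self):
        hits = [_hit(PEAK, _gene(0, 5000, name="A"), 100),
                _hit(PEAK, _gene(0, 9000, name="B"), 900)]
        expr = ExpressionTable({"A": 0.0, "B": 0.0})
        chosen, reason, expressed = select_gene(PEAK, hits, expr, self.params)
        assert chosen.gene.name == "B" and reason == "largest_overlap"
        assert expressed is False

    def test_equal_expression_falls_back_to_overlap_then_name(self):
        hits = [_hit(PEAK, _gene(0, 5000, name="B"), 500),
                _hit(PEAK, _gene(0, 9000, name="A"), 500)]
        expr = ExpressionTable({"A": 7.0, "B": 7.0})
        chosen, reason, _ = select_gene(PEAK, hits, expr, self.params)
        # equal expression and equal overlap: lexicographically smaller name
        assert chosen.gene.name == "A" and reason == "largest_overlap"

    def test_no_expression_table_means_largest_overlap(self):
        hits = [_hit(PEAK, _gene(0, 5000, name="A"), 100),
                _hit(PEAK, _gene(0, 9000, name="B"), 900)]
        chosen, reason, expressed = select_gene(PEAK, hits, ExpressionTable(), self.params)
        assert chosen.gene.name == "B" and reason == "largest_overlap"
        assert expressed is False

    def test_empty_hits_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            select_gene(PEAK, [], ExpressionTable(), self.params)


class TestAssignFeatures:
    def test_peak_over_whole_gene_lights_all_six(self, two_exon_gene, default_params):
        fs = features_with_flanks(two_exon_gene, 5000, 5000, 1_000_000)
        peak = GenomicInterval("chr1", 0, 7000, name="p")
        flags = assign_features(peak, two_exon_gene, fs, default_params)
        assert all(flags)

    def test_peak_inside_intron_lights_intron_only(self, two_exon_gene, default_params):
        fs = features_with_flanks(two_exon_gene, 5000, 5000, 1_000_000)
        peak = GenomicInterval("chr1", 400, 600, name="p")
        flags = assign_features(peak, two_exon_gene, fs, default_params)
        assert dict(zip(FEATURE_NAMES, flags)) == {
            "Upstream": False, "5UTR": False, "Exon": False,
            "Intron": True, "3UTR": False, "Downstream": False}

    def test_peak_over_gene_end_lights_exon_utr3_downstream(self, two_exon_gene, default_params):
        fs = features_with_flanks(two_exon_gene, 5000, 5000, 1_000_000)
        peak = GenomicInterval("chr1", 950, 1100, name="p")
        flags = dict(zip(FEATURE_NAMES, assign_features(peak, two_exon_gene, fs, default_params)))
        assert flags == {"Upstream": False, "5UTR": False, "Exon": True,
                         "Intron": False, "3UTR": True, "Downstream": True}


class TestWarnFlag:
    params = AnnotationParams(expression_threshold=0.5)

    def test_flank_only_peak_is_warned(self):
        gene = _gene(10_000, 20_000, name="A")
        hits = [_hit(PEAK, gene, 300, body=0)]
        flags = (True, False, False, False, False, False)
        assert warn_flag(flags, hits, ExpressionTable({"A": 50.0}), self.params) is True

    def test_body_peak_single_expressed_gene_not_warned(self):
        gene = _gene(0, 5000, name="A")
        hits = [_hit(PEAK, gene, 1000)]
        flags = (False, False, True, False, False, False)
        assert warn_flag(flags, hits, ExpressionTable({"A": 50.0}), self.params) is False

    def test_two_expressed_genes_warned(self):
        a, b = _gene(0, 5000, name="A"), _gene(1500, 9000, name="B", strand="-")
        hits = [_hit(PEAK, a, 1000), _hit(PEAK, b, 500)]
        flags = (False, False, True, False, False, False)
        assert warn_flag(flags, hits, ExpressionTable({"A": 5.0, "B": 3.0}), self.params) is True

    def test_one_expressed_one_silent_not_warned(self):
        a, b = _gene(0, 5000, name="A"), _gene(1500, 9000, name="B", strand="-")
        hits = [_hit(PEAK, a, 1000), _hit(PEAK, b, 500)]
        flags = (False, False, True, False, False, False)
        assert warn_flag(flags, hits, ExpressionTable({"A": 5.0, "B": 0.0}), self.params) is False


class TestAnnotateEndToEnd:
    def test_empty_peak_list(self, default_fixture, default_expr, default_params):
        records, intergenic = annotate([], default_fixture.genes, default_expr,
                                       default_params, default_fixture.chrom_sizes)
        assert records == [] and intergenic == []

    def test_matches_fixture_ground_truth(self, default_fixture, default_expr, default_params):
        from rlanno.fixtures import score_against_truth
        records, intergenic = annotate(default_fixture.peaks, default_fixture.genes,
                                       default_expr, default_params,
                                       default_fixture.chrom_sizes)
        frac, breakdown = score_against_truth(records, intergenic, default_fixture.truth)
        assert frac == 1.0
        assert (breakdown["warning_accuracy"] == 1.0).all()

    def test_every_genic_record_has_a_feature(self, default_fixture, default_expr,
                                              default_params):
        records, _ = annotate(default_fixture.peaks, default_fixture.genes, default_expr,
                              default_params, default_fixture.chrom_sizes)
        assert all(any(r.features) for r in records)
        assert all(r.template_strand != r.gene_strand for r in records)

    def test_determinism_identical_runs(self, default_fixture, default_expr, default_params):
        run = lambda: annotate(default_fixture.peaks, default_fixture.genes, default_expr,
                               default_params, default_fixture.chrom_sizes)
        r1, i1 = run()
        r2, i2 = run()
        assert r1 == r2 and i1 == i2

    def test_metric_invariance_under_monotone_transform(self, default_fixture, default_params):
        """Any strictly monotone, threshold-class-preserving rescaling of the
        expression values leaves every gene assignment unchanged."""
        expr = ExpressionTable(dict(default_fixture.expression))
        # x -> x^3 * 7: strictly monotone on [0, inf), preserves which values are > 0
        transformed = ExpressionTable({k: 7.0 * v ** 3 for k, v in
                                       default_fixture.expression.items()})
        r1, _ = annotate(default_fixture.peaks, default_fixture.genes, expr,
                         default_params, default_fixture.chrom_sizes)
        r2, _ = annotate(default_fixture.peaks, default_fixture.genes, transformed,
                         default_params, default_fixture.chrom_sizes)
        assert [r.gene_name for r in r1] == [r.gene_name for r in r2]
        assert [r.expressed for r in r1] == [r.expressed for r in r2]

    def test_expression_monotonicity(self, default_fixture, default_params):
        """Raising one candidate's expression above all rivals makes it win
        every peak it overlaps."""
        from rlanno.overlap_engine import find_overlaps
        hits, _ = find_overlaps(default_fixture.peaks, default_fixture.genes,
                                5000, 5000, default_fixture.chrom_sizes)
        # pick a gene that loses at least one multi-candidate peak
        target = None
        for peak, peak_hits in hits.items():
            if len(peak_hits) >= 2:
                target = peak_hits[-1].gene.name
                break
        assert target is not None
        boosted = dict(default_fixture.expression)
        boosted[target] = max(boosted.values()) + 1000.0
        records, _ = annotate(default_fixture.peaks, default_fixture.genes,
                              ExpressionTable(boosted), default_params,
                              default_fixture.chrom_sizes)
        for rec in records:
            peak_hits = hits.get(rec.peak, [])
            if any(h.gene.name == target for h in peak_hits):
                assert rec.gene_name == target


class TestSplitTables:
    def test_partition_sizes(self, default_fixture, default_expr, default_params):
        records, _ = annotate(default_fixture.peaks, default_fixture.genes, default_expr,
                              default_params, default_fixture.chrom_sizes)
        expressed, unexpressed, merged = split_tables(records)
        assert len(expressed) + len(unexpressed) == len(merged) == len(records)
        assert all(r.expressed for r in expressed)
        assert not any(r.expressed for r in unexpressed)
        assert merged == list(records)

    def test_no_expression_table_all_unexpressed(self, default_fixture, default_params):
        params = AnnotationParams(expression_mode=False)
        records, _ = annotate(default_fixture.peaks, default_fixture.genes,
                              ExpressionTable(), params, default_fixture.chrom_sizes)
        expressed, unexpressed, merged = split_tables(records)
        assert expressed == [] and len(unexpressed) == len(records)
        assert all(r.expression_value is None for r in records)
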