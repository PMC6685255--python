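"""Peak shuffling, feature counting, fold enrichment and the chi-squared test."""

import math

import numpy as np
import pytest
from scipy import stats

from rlanno.annotator import annotate
from rlanno.enrichment import (
    ENRICHMENT_FEATURES,
    chi2_feature_test,
    count_features,
    fold_enrichment,
    run_enrichment,
    shuffle_peaks,
)
from rlanno.genome_model import GenomicInterval


class TestShufflePeaks:
    def test_forced_placement_single_chromosome(self):
        peak = GenomicInterval("chr1", 40, 140, name="p")
        (out,) = shuffle_peaks([peak], {"chrA": 100}, seed=0)
        assert (out.chrom, out.start, out.end) == ("chrA", 0, 100)

    def test_seed_reproducibility(self):
        peaks = [GenomicInterval("chr1", i * 100, i * 100 + 50, name=f"p{i}") for i in range(20)]
        sizes = {"chr1": 100_000, "chr2": 50_000}
        assert shuffle_peaks(peaks, sizes, seed=42) == shuffle_peaks(peaks, sizes, seed=42)
        assert shuffle_peaks(peaks, sizes, seed=42) != shuffle_peaks(peaks, sizes, seed=43)

    def test_length_multiset_conserved(self):
        rng = np.random.default_rng(5)
        peaks = [GenomicInterval("chr1", int(s), int(s) + int(l), name=f"p{i}")
                 for i, (s, l) in enumerate(zip(rng.integers(0, 10_000, 50),
                                                rng.integers(1, 5000, 50)))]
        out = shuffle_peaks(peaks, {"c1": 50_000, "c2": 20_000}, seed=1)
        assert sorted(p.length for p in out) == sorted(p.length for p in peaks)
        for p in out:
            assert 0 <= p.start and p.end <= {"c1": 50_000, "c2": 20_000}[p.chrom]

    def test_chromosome_choice_proportional_to_length(self):
        """10,000 placements of a 100 bp peak over 900 kb + 100 kb chromosomes:
        the small chromosome receives ~10% of them (binomial 3-sigma band)."""
        peak = GenomicInterval("chr1", 0, 100, name="p")
        out = shuffle_peaks([peak] * 10_000, {"big": 900_000, "small": 100_000}, seed=7)
        frac = sum(1 for p in out if p.chrom == "small") / 10_000
        sd = math.sqrt(0.1 * 0.9 / 10_000)
        assert abs(frac - 0.1) <= 3 * sd

    def test_unplaceable_peak_raises_with_name(self):
        peak = GenomicInterval("chr1", 0, 500, name="huge_peak")
        with pytest.raises(ValueError, match="huge_peak"):
            shuffle_peaks([peak], {"c1": 100, "c2": 400}, seed=0)


class TestCountFeatures:
    def test_multi_feature_peak_counts_in_each(self, default_fixture, default_expr,
                                               default_params):
        records, intergenic = annotate(default_fixture.peaks, default_fixture.genes,
                                       default_expr, default_params,
                                       default_fixture.chrom_sizes)
        counts = count_features(records, intergenic)
        assert counts["Intergenic"] == len(intergenic)
        # independent tally per feature
        for i, feat in enumerate(("Upstream", "5UTR", "Exon", "Intron", "3UTR", "Downstream")):
            assert counts[feat] == sum(1 for r in records if r.features[i])

    def test_empty_inputs_all_zero(self):
        assert all(v == 0 for v in count_features([], []).values())


class TestChi2:
    def test_perfect_independence_gives_zero_statistic(self):
        stat, p, degenerate = chi2_feature_test(10, 10, 10, 10)
        assert stat == 0.0 and p == 1.0 and not degenerate

    def test_diagonal_table_statistic_forty(self):
        # closed form: n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 40*(400)^2/(20*20*20*20)
        stat, p, degenerate = chi2_feature_test(20, 0, 0, 20)
        assert stat == pytest.approx(40.0, abs=1e-12)
        assert not degenerate

    def test_zero_marginal_is_degenerate(self):
        stat, p, degenerate = chi2_feature_test(0, 10, 0, 10)
        assert degenerate and p == 1.0

    def test_matches_closed_form_on_random_tables(self):
        """Pearson statistic and df=1 p-value agree with the closed-form
        2x2 formula to 1e-10 over random tables."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(0, 500, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            stat, p, degenerate = chi2_feature_test(a, b, c, d)
            n = a + b + c + d
            expected_stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert not degenerate
            assert abs(stat - expected_stat) < 1e-10
            assert abs(p - stats.chi2.sf(expected_stat, df=1)) < 1e-10


class TestFoldEnrichment:
    def test_fold_two(self):
        observed = {f: 0 for f in ENRICHMENT_FEATURES}
        observed["Exon"] = 50
        reps = [{**{f: 0 for f in ENRICHMENT_FEATURES}, "Exon": v} for v in (20, 25, 30)]
        res = {r.feature: r for r in fold_enrichment(observed, reps, total_peaks=100)}
        assert res["Exon"].fold == pytest.approx(2.0)
        assert res["Exon"].rand_mean == pytest.approx(25.0)
        assert res["Exon"].rand_sd == pytest.approx(5.0)

    def test_identity_when_observed_equals_every_replicate(self):
        counts = {f: 3 for f in ENRICHMENT_FEATURES}
        res = fold_enrichment(counts, [dict(counts), dict(counts)], total_peaks=10)
        for r in res:
            assert r.fold == pytest.approx(1.0) and r.rand_sd == 0.0

    def test_no_signal_conventions(self):
        zeros = {f: 0 for f in ENRICHMENT_FEATURES}
        res = {r.feature: r for r in fold_enrichment(zeros, [dict(zeros), dict(zeros)],
                                                     total_peaks=10)}
        assert all(r.fold == 1.0 for r in res.values())
        observed = dict(zeros, Exon=5)
        res = {r.feature: r for r in fold_enrichment(observed, [dict(zeros), dict(zeros)],
                                                     total_peaks=10)}
        assert math.isinf(res["Exon"].fold)

    def test_requires_two_replicates(self):
        zeros = {f: 0 for f in ENRICHMENT_FEATURES}
        with pytest.raises(ValueError):
            fold_enrichment(zeros, [zeros])


class TestRunEnrichment:
    def test_bitwise_reproducible(self, default_fixture, default_expr, default_params):
        kwargs = dict(
            peaks=default_fixture.peaks[:60], genes=default_fixture.genes,
            expr=default_expr, params=default_params,
            chrom_sizes=default_fixture.chrom_sizes, n_shuffles=4, seed=9,
        )
        r1 = run_enrichment(**kwargs)
        r2 = run_enrichment(**kwargs)
        assert r1 == r2

    def test_genic_query_enriched_in_gene_body_features(self, default_fixture, default_expr,
                                                        default_params):
        """The fixture's peaks are mostly placed in gene bodies; exonic/intronic
        folds must exceed 1 while the intergenic fold falls below 1."""
        res = {r.feature: r for r in run_enrichment(
            default_fixture.peaks, default_fixture.genes, default_expr, default_params,
            default_fixture.chrom_sizes, n_shuffles=10, seed=3)}
        assert res["Exon"].fold > 1.5
        assert res["Intron"].fold > 1.5
        assert res["Intergenic"].fold < 1.0
        assert res["Exon"].p_value < 1e-6
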