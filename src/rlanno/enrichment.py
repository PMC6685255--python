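"""Shuffle-based feature enrichment for peak sets.

The observed per-feature peak counts are compared against the same
counts for randomly re-placed peaks.  Shuffling preserves each peak's
length and drops it uniformly on the genome: the destination chromosome
is drawn with probability proportional to chromosome length (among
chromosomes long enough to hold the peak) and the start uniformly within
it.  Shuffled peaks may overlap each other; there are no exclusion
regions.  Each shuffle replicate is annotated with exactly the same
parameters (and expression table) as the query, so the comparison is
like for like.

Per feature the summary is: observed count, mean and sample SD of the
shuffled counts, fold enrichment = observed / mean, and the p-value of a
Pearson chi-squared test (df=1, no continuity correction) on the 2x2
table of in/out-of-feature counts, observed vs (rounded) random mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .annotator import AnnotationParams, AnnotationRecord, annotate
from .bed_io import ExpressionTable
from .genome_model import FEATURE_NAMES, ChromSizes, GeneModel, GenomicInterval

__all__ = [
    "ENRICHMENT_FEATURES",
    "FeatureCounts",
    "EnrichmentResult",
    "shuffle_peaks",
    "count_features",
    "fold_enrichment",
    "chi2_feature_test",
    "run_enrichment",
]

ENRICHMENT_FEATURES = FEATURE_NAMES + ("Intergenic",)

# feature name -> count of peaks whose flag is true (a peak may hit several)
FeatureCounts = Dict[str, int]


@dataclass
class EnrichmentResult:
    """Per-feature enrichment summary.

    ``fold`` is observed/rand_mean; ``math.inf`` when the random mean is
    zero but peaks were observed, and 1.0 when both are zero (no signal
    either way).  ``degenerate`` marks a chi-squared table with a zero
    marginal, where the test is undefined and the p-value is reported
    as 1.
    """

    feature: str
    observed: int
    rand_mean: float
    rand_sd: float
    fold: float
    p_value: float
    degenerate: bool = False


def shuffle_peaks(
    peaks: Sequence[GenomicInterval],
    chrom_sizes: ChromSizes,
    seed,
) -> List[GenomicInterval]:
    """Length-preserving random re-placement of every peak on the genome.

    ``seed`` is anything :func:`numpy.random.default_rng` accepts;
    identical seeds give identical output.  A peak longer than every
    chromosome cannot be placed and raises ``ValueError``.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    shuffled: List[GenomicInterval] = []
    for peak in peaks:
        plen = peak.length
        fits = lengths >= plen
        if not fits.any():
            raise ValueError(
                f"peak {peak.name} ({plen} bp) is longer than every chromosome; cannot shuffle"
            )
        weights = np.where(fits, lengths, 0.0)
        idx = rng.choice(len(chroms), p=weights / weights.sum())
        chrom = chroms[idx]
        start = int(rng.integers(0, chrom_sizes[chrom] - plen + 1))
        shuffled.append(GenomicInterval(chrom, start, start + plen,
                                        name=peak.name, strand=peak.strand))
    return shuffled


def count_features(
    records: Sequence[AnnotationRecord],
    intergenic: Sequence[GenomicInterval],
) -> FeatureCounts:
    """Tally, per feature, how many peaks carry a true flag.

    A multi-feature peak contributes to every feature it overlaps;
    ``Intergenic`` is simply the number of intergenic peaks.
    """
    counts: FeatureCounts = {name: 0 for name in ENRICHMENT_FEATURES}
    for rec in records:
        for name, flag in zip(FEATURE_NAMES, rec.features):
            if flag:
                counts[name] += 1
    counts["Intergenic"] = len(intergenic)
    return counts


def chi2_feature_test(
    observed_in: int, observed_out: int, rand_in: float, rand_out: float
) -> Tuple[float, float, bool]:
    """Pearson chi-squared (df=1, no continuity correction) on a 2x2 table.

    Rows: observed vs random (random entries rounded to integers).
    Returns ``(statistic, p_value, degenerate)``; a zero marginal makes
    the test undefined — the table is flagged degenerate with p = 1.
    """
    table = np.array(
        [[observed_in, observed_out],
         [round(rand_in), round(rand_out)]],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0, True
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p), False


def fold_enrichment(
    observed: FeatureCounts,
    shuffled_counts: Sequence[FeatureCounts],
    total_peaks: Optional[int] = None,
) -> List[EnrichmentResult]:
    """Per-feature fold enrichment against shuffle replicates.

    Requires at least 2 replicates so the sample SD (n-1 denominator) is
    defined.  ``total_peaks`` (the common peak-set size) sizes the 2x2
    chi-squared tables; it defaults to the observed Intergenic count
    plus nothing better, so pass it explicitly when records are at hand.
    """
    if len(shuffled_counts) < 2:
        raise ValueError("fold_enrichment needs >= 2 shuffle replicates for an SD")
    if total_peaks is None:
        total_peaks = max(
            max(observed.values(), default=0),
            max((max(c.values(), default=0) for c in shuffled_counts), default=0),
        )
    results: List[EnrichmentResult] = []
    for feat in ENRICHMENT_FEATURES:
        obs = observed.get(feat, 0)
        rand = np.array([c.get(feat, 0) for c in shuffled_counts], dtype=float)
        mean = float(rand.mean())
        sd = float(rand.std(ddof=1))
        if mean > 0:
            fold = obs / mean
        elif obs > 0:
            fold = math.inf
        else:
            fold = 1.0
        _, p, degenerate = chi2_feature_test(obs, total_peaks - obs, mean, total_peaks - mean)
        results.append(EnrichmentResult(
            feature=feat, observed=obs, rand_mean=mean, rand_sd=sd,
            fold=fold, p_value=p, degenerate=degenerate,
        ))
    return results


def run_enrichment(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    expr: ExpressionTable,
    params: AnnotationParams,
    chrom_sizes: ChromSizes,
    n_shuffles: int = 10,
    seed: int = 0,
    feature_beds=None,
    keep_shuffles: bool = False,
):
    """Annotate the query, then ``n_shuffles`` shuffled replicas, and summarize.

    Replicate ``i`` is shuffled with rng seed ``[seed, i]`` so the whole
    analysis is reproducible bit-for-bit from ``(inputs, seed,
    n_shuffles)``.  Returns a list of :class:`EnrichmentResult` (one per
    feature, Intergenic included); with ``keep_shuffles=True`` also the
    shuffled peak sets.
    """
    if n_shuffles < 2:
        raise ValueError("enrichment needs >= 2 shuffle replicates")
    records, intergenic = annotate(peaks, genes, expr, params, chrom_sizes, feature_beds)
    observed = count_features(records, intergenic)
    shuffled_counts: List[FeatureCounts] = []
    shuffles: List[List[GenomicInterval]] = []
    for i in range(n_shuffles):
        shuf = shuffle_peaks(peaks, chrom_sizes, seed=[seed, i])
        recs, inter = annotate(shuf, genes, expr, params, chrom_sizes, feature_beds)
        shuffled_counts.append(count_features(recs, inter))
        if keep_shuffles:
            shuffles.append(shuf)
    results = fold_enrichment(observed, shuffled_counts, total_peaks=len(peaks))
    if keep_shuffles:
        return results, shuffles
    return results
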