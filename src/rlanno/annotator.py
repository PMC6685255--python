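"""Expression-guided gene selection, feature assignment and the annotation table.

This is the heart of the tool.  DRIP-seq peaks are long and strand-blind:
an R-loop forms co-transcriptionally, so the DNA strand the hybrid RNA
anneals to is the *template* strand — the complement of the annotated
strand of whichever gene is actually transcribed through the peak.
Picking the right gene therefore decides the template strand.

Selection rule (per peak, over all genes overlapping its flank-extended
spans):

1. a single overlapping gene is assigned outright (``single_gene``);
2. with an expression table, when the candidates' values are not all
   equal and the maximum exceeds the threshold, the highest-expressed
   gene wins (``highest_expression``);
3. otherwise — all values at or below threshold, all values equal, or no
   expression table at all — the gene with the largest overlap with the
   peak wins (``largest_overlap``).

Ties are broken deterministically: equal expression at the top falls
back to overlap, and equal overlap to the lexicographically smallest
gene name, so identical inputs always yield byte-identical tables.

A *warning* marks peaks whose assignment is intrinsically ambiguous
because antisense R-loops can form there: peaks touching only the
upstream/downstream flanks of their gene (no gene-body feature), and
peaks overlapping two or more genes that are all expressed above
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .bed_io import ExpressionTable
from .genome_model import (
    FEATURE_NAMES,
    ChromSizes,
    FeatureSet,
    GeneModel,
    GenomicInterval,
    features_with_flanks,
)
from .overlap_engine import OverlapHit, find_overlaps, overlap_length

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationParams",
    "AnnotationRecord",
    "select_gene",
    "template_strand",
    "assign_features",
    "warn_flag",
    "annotate",
    "split_tables",
]


@dataclass(frozen=True)
class AnnotationParams:
    """Knobs of the annotation run.

    up_size / down_size : int, bp (default 5000)
        Sizes of the strand-aware flanks added to each gene span for the
        genic test and the Upstream/Downstream features.
    expression_threshold : float (default 0)
        A gene is "expressed" when its value is strictly greater than
        this.
    expression_mode : bool
        Whether an expression table was provided; without one, all
        records are classed unexpressed and selection is purely
        largest-overlap.
    """

    up_size: int = 5000
    down_size: int = 5000
    expression_threshold: float = 0.0
    expression_mode: bool = True

    def __post_init__(self) -> None:
        if self.up_size < 0 or self.down_size < 0:
            raise ValueError("flank sizes must be non-negative")
        if self.expression_threshold < 0:
            raise ValueError("expression threshold must be non-negative")


@dataclass
class AnnotationRecord:
    """One row of the annotation table (one genic peak)."""

    peak: GenomicInterval
    gene_name: str
    gene_strand: str
    template_strand: str
    expression_value: Optional[float]
    expressed: bool
    features: Tuple[bool, bool, bool, bool, bool, bool]  # Upstream,5UTR,Exon,Intron,3UTR,Downstream
    warning: bool
    selection_reason: str
    rival_genes: List[str] = field(default_factory=list)

    def feature_dict(self) -> Dict[str, bool]:
        return dict(zip(FEATURE_NAMES, self.features))


def template_strand(gene_strand: str) -> str:
    """The DNA strand the nascent RNA hybridizes to: the gene's complement."""
    if gene_strand == "+":
        return "-"
    if gene_strand == "-":
        return "+"
    raise ValueError(f"cannot derive a template strand from strand {gene_strand!r}")


def select_gene(
    peak: GenomicInterval,
    hits: Sequence[OverlapHit],
    expr: ExpressionTable,
    params: AnnotationParams,
) -> Tuple[OverlapHit, str, bool]:
    """Pick one gene for a genic peak; returns (hit, reason, expressed).

    ``expressed`` reports whether the chosen gene's value exceeds the
    threshold (always False without an expression table).
    """
    if not hits:
        raise ValueError(f"peak {peak.name}: select_gene requires at least one overlap hit")

    use_expression = params.expression_mode and not expr.is_empty

    def gene_expr(hit: OverlapHit) -> float:
        return expr.get(hit.gene.name)

    if len(hits) == 1:
        chosen, reason = hits[0], "single_gene"
    else:
        values = [gene_expr(h) for h in hits]
        distinct = len(set(values)) > 1
        if use_expression and distinct and max(values) > params.expression_threshold:
            top = max(values)
            pool = [h for h, v in zip(hits, values) if v == top]
            reason = "highest_expression"
        else:
            pool = list(hits)
            reason = "largest_overlap"
        # overlap (extended span) first, then lexicographic gene name
        pool.sort(key=lambda h: (-h.overlap_bp, h.gene.name))
        chosen = pool[0]

    expressed = use_expression and gene_expr(chosen) > params.expression_threshold
    return chosen, reason, expressed


def assign_features(
    peak: GenomicInterval,
    gene: GeneModel,
    features: FeatureSet,
    params: AnnotationParams,
) -> Tuple[bool, bool, bool, bool, bool, bool]:
    """Six flags (Upstream, 5'UTR, Exon, Intron, 3'UTR, Downstream).

    A flag is true iff the peak overlaps >= 1 bp of that feature of the
    assigned gene.  Long peaks routinely light several flags at once —
    multi-feature annotation is deliberate, not an error state.
    """
    by_feature = features.by_feature()
    return tuple(
        any(overlap_length(peak, iv) >= 1 for iv in by_feature[name])
        for name in FEATURE_NAMES
    )  # type: ignore[return-value]


def warn_flag(
    features: Sequence[bool],
    all_hits: Sequence[OverlapHit],
    expr: ExpressionTable,
    params: AnnotationParams,
) -> bool:
    """Ambiguity warning: flank-only peaks, or peaks over >=2 expressed genes.

    Rule (a): the peak overlaps ONLY the Upstream/Downstream flanks of
    its assigned gene — antisense transcripts are common at gene ends.
    Rule (b): the peak overlaps two or more distinct genes whose
    expression exceeds the threshold — either could host the R-loop.
    """
    upstream, utr5, exon, intron, utr3, downstream = features
    flank_only = (upstream or downstream) and not (utr5 or exon or intron or utr3)
    if flank_only:
        return True
    if params.expression_mode and not expr.is_empty:
        expressed_genes = {
            h.gene.name for h in all_hits
            if expr.get(h.gene.name) > params.expression_threshold
        }
        if len(expressed_genes) >= 2:
            return True
    return False


def _feature_set(
    gene: GeneModel,
    params: AnnotationParams,
    chrom_len: int,
    feature_beds: Optional[Dict[str, List[GenomicInterval]]] = None,
) -> FeatureSet:
    """Feature set for a gene: shipped feature BEDs win over derivation."""
    if feature_beds:
        fs = features_with_flanks(gene, params.up_size, params.down_size, chrom_len)
        mapping = {"5UTR": "utr5", "3UTR": "utr3", "Exon": "exons", "Intron": "introns"}
        for feat, attr in mapping.items():
            if feat in feature_beds:
                setattr(fs, attr, [iv for iv in feature_beds[feat] if iv.name == gene.name])
        return fs
    return features_with_flanks(gene, params.up_size, params.down_size, chrom_len)


def annotate(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    expr: ExpressionTable,
    params: AnnotationParams,
    chrom_sizes: ChromSizes,
    feature_beds: Optional[Dict[str, List[GenomicInterval]]] = None,
) -> Tuple[List[AnnotationRecord], List[GenomicInterval]]:
    """Full annotation: overlap -> gene selection -> features -> warnings.

    Returns ``(records, intergenic)``; every input peak appears in
    exactly one of the two, in input order, and the result is
    deterministic given identical inputs.
    """
    hits, _ = find_overlaps(peaks, genes, params.up_size, params.down_size, chrom_sizes)

    # pre-index feature BEDs by gene name so lookups stay linear
    beds_by_gene: Optional[Dict[str, Dict[str, List[GenomicInterval]]]] = None
    if feature_beds:
        beds_by_gene = {}
        for feat, ivs in feature_beds.items():
            for iv in ivs:
                if iv.name is None:
                    continue
                beds_by_gene.setdefault(iv.name, {}).setdefault(feat, []).append(iv)

    fs_cache: Dict[int, FeatureSet] = {}
    records: List[AnnotationRecord] = []
    intergenic: List[GenomicInterval] = []
    for peak in peaks:
        peak_hits = hits.get(peak)
        if not peak_hits:
            intergenic.append(peak)
            continue
        chosen, reason, expressed = select_gene(peak, peak_hits, expr, params)
        gene = chosen.gene
        key = id(gene)
        if key not in fs_cache:
            per_gene_beds = beds_by_gene.get(gene.name) if beds_by_gene else None
            fs_cache[key] = _feature_set(gene, params, chrom_sizes[gene.chrom], per_gene_beds)
        flags = assign_features(peak, gene, fs_cache[key], params)
        warning = warn_flag(flags, peak_hits, expr, params)
        expr_value = expr.get(gene.name) if (params.expression_mode and not expr.is_empty) else None
        rivals = sorted({h.gene.name for h in peak_hits} - {gene.name})
        records.append(AnnotationRecord(
            peak=peak,
            gene_name=gene.name,
            gene_strand=gene.strand,
            template_strand=template_strand(gene.strand),
            expression_value=expr_value,
            expressed=expressed,
            features=flags,
            warning=warning,
            selection_reason=reason,
            rival_genes=rivals,
        ))
    return records, intergenic


def split_tables(
    records: Sequence[AnnotationRecord],
) -> Tuple[List[AnnotationRecord], List[AnnotationRecord], List[AnnotationRecord]]:
    """Partition records into (expressed, unexpressed, merged), order-preserving."""
    expressed = [r for r in records if r.expressed]
    unexpressed = [r for r in records if not r.expressed]
    return expressed, unexpressed, list(records)
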