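"""Summary tables and figures for an annotation run.

Four figure types are produced: (a) a per-feature percentage histogram
with counts in the legend, (b) a pie chart of peak proportions, (c) an
upset-style plot of feature-combination counts, and (d) the fold-
enrichment histogram with shuffle-SD error bars and chi-squared p-value
annotations.  Every number shown in a figure is also written to a TSV
under ``summary/`` — the TSVs are canonical, the figures decorative.

The pie chart needs one label per peak, so multi-feature peaks are
collapsed by the priority 5'UTR > 3'UTR > Exon > Intron > Upstream >
Downstream > Intergenic (transcribed gene-body features first).
"""

from __future__ import annotations

import logging
import math
import os
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence

import pandas as pd

from .annotator import AnnotationRecord, split_tables
from .bed_io import write_annotation_table, write_bed
from .enrichment import EnrichmentResult, count_features
from .genome_model import FEATURE_NAMES, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = ["combo_counts", "pie_counts", "render_reports", "PIE_PRIORITY"]

PIE_PRIORITY = ("5UTR", "3UTR", "Exon", "Intron", "Upstream", "Downstream", "Intergenic")

# mapping: exact feature-flag subset -> number of genic peaks showing it
FeatureComboCounts = Dict[FrozenSet[str], int]


def combo_counts(records: Sequence[AnnotationRecord]) -> FeatureComboCounts:
    """Exact-combination tally of the six feature flags over genic peaks."""
    combos: FeatureComboCounts = {}
    for rec in records:
        combo = frozenset(n for n, f in zip(FEATURE_NAMES, rec.features) if f)
        combos[combo] = combos.get(combo, 0) + 1
    return combos


def pie_counts(
    records: Sequence[AnnotationRecord], intergenic: Sequence[GenomicInterval]
) -> Dict[str, int]:
    """One label per peak via the pie priority rule; counts sum to all peaks."""
    counts = {name: 0 for name in PIE_PRIORITY}
    for rec in records:
        flags = rec.feature_dict()
        for name in PIE_PRIORITY[:-1]:
            if flags[name]:
                counts[name] += 1
                break
    counts["Intergenic"] = len(intergenic)
    return counts


def _feature_table(records, intergenic) -> pd.DataFrame:
    counts = count_features(records, intergenic)
    total = len(records) + len(intergenic)
    rows = [
        {"feature": feat, "count": counts[feat],
         "percent": (100.0 * counts[feat] / total) if total else 0.0}
        for feat in counts
    ]
    return pd.DataFrame(rows)


def _combo_table(records) -> pd.DataFrame:
    combos = combo_counts(records)
    rows = [
        {"combination": "+".join(sorted(c, key=FEATURE_NAMES.index)), "count": n}
        for c, n in sorted(combos.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    ]
    return pd.DataFrame(rows, columns=["combination", "count"])


def _enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"feature": r.feature, "observed": r.observed, "rand_mean": r.rand_mean,
         "rand_sd": r.rand_sd, "fold": r.fold, "p_value": r.p_value,
         "degenerate": int(r.degenerate)}
        for r in results
    ])


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _save(fig, base: Path) -> None:
    # Date metadata stripped so repeated seeded runs are byte-identical
    fig.savefig(base.with_name(base.name + ".png"), dpi=150, metadata={"Software": None})
    fig.savefig(base.with_name(base.name + ".svg"), metadata={"Date": None})


def render_reports(
    records: Sequence[AnnotationRecord],
    intergenic: Sequence[GenomicInterval],
    enrichment: Optional[Sequence[EnrichmentResult]],
    out_dir,
    figures: bool = True,
) -> None:
    """Write annotation tables, summary TSVs and (optionally) figures.

    Layout under ``out_dir``: ``annotation.{expressed,unexpressed,merged}.tsv``,
    ``intergenic.bed``, ``warned_peaks.tsv``, ``enrichment.tsv``,
    ``summary/*.tsv``, ``figures/*.{png,svg}``.  If the plotting backend
    fails, the TSVs are still written and a warning is logged.
    """
    out_dir = Path(out_dir)
    summary_dir = out_dir / "summary"
    out_dir.mkdir(parents=True, exist_ok=True)

    expressed, unexpressed, merged = split_tables(records)
    variants = {"expressed": expressed, "unexpressed": unexpressed, "merged": merged}
    for label, recs in variants.items():
        write_annotation_table(recs, out_dir / f"annotation.{label}.tsv")
    write_bed(intergenic, out_dir / "intergenic.bed")
    _write_warned(records, out_dir / "warned_peaks.tsv")

    for label, recs in variants.items():
        inter = intergenic if label == "merged" else []
        _write_tsv(_feature_table(recs, inter), summary_dir / f"feature_counts.{label}.tsv")
        _write_tsv(_combo_table(recs), summary_dir / f"feature_combinations.{label}.tsv")
    pie = pie_counts(merged, intergenic)
    _write_tsv(pd.DataFrame([{"feature": k, "count": v} for k, v in pie.items()]),
               summary_dir / "pie_counts.merged.tsv")
    if enrichment is not None:
        _write_tsv(_enrichment_table(enrichment), out_dir / "enrichment.tsv")

    if not figures:
        return
    try:
        _render_figures(variants, intergenic, pie, enrichment, out_dir / "figures")
    except Exception:  # pragma: no cover - backend-dependent
        logger.warning("figure rendering failed; summary TSVs were still written", exc_info=True)


def _write_warned(records: Sequence[AnnotationRecord], path: Path) -> None:
    rows = []
    for rec in records:
        if not rec.warning:
            continue
        rows.append({
            "chrom": rec.peak.chrom, "start": rec.peak.start, "end": rec.peak.end,
            "peak_name": rec.peak.name, "gene_name": rec.gene_name,
            "gene_strand": rec.gene_strand,
            "rival_genes": ",".join(rec.rival_genes) or ".",
        })
    _write_tsv(pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_name",
                                           "gene_name", "gene_strand", "rival_genes"]), path)


def _render_figures(variants, intergenic, pie, enrichment, fig_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    # fixed hash salt keeps SVG element ids stable across identical runs
    matplotlib.rcParams["svg.hashsalt"] = "rlanno"
    import matplotlib.pyplot as plt

    fig_dir.mkdir(parents=True, exist_ok=True)

    for label, recs in variants.items():
        if not recs and label != "merged":
            continue
        inter = intergenic if label == "merged" else []
        table = _feature_table(recs, inter)
        fig, ax = plt.subplots(figsize=(7, 4.5))
        bars = ax.bar(table["feature"], table["percent"], color="#4878d0")
        ax.set_ylabel("% of peaks")
        ax.set_title(f"Peaks per feature ({label})")
        ax.legend(bars[:1], [", ".join(f"{f}: {c}" for f, c in
                                       zip(table["feature"], table["count"]))],
                  fontsize=6, loc="upper right")
        ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        _save(fig, fig_dir / f"feature_percent.{label}")
        plt.close(fig)

        combos = _combo_table(recs)
        if len(combos):
            _upset_plot(plt, combos, fig_dir / f"feature_combinations.{label}")

    # pie chart (merged only; one label per peak)
    nonzero = {k: v for k, v in pie.items() if v > 0}
    if nonzero:
        fig, ax = plt.subplots(figsize=(5.5, 5.5))
        ax.pie(list(nonzero.values()), labels=list(nonzero.keys()),
               autopct="%1.1f%%", startangle=90, counterclock=False)
        ax.set_title("Peak proportions by feature (priority-collapsed)")
        fig.tight_layout()
        _save(fig, fig_dir / "feature_pie.merged")
        plt.close(fig)

    if enrichment is not None:
        table = _enrichment_table(enrichment)
        plot = table[table["rand_mean"] > 0].reset_index(drop=True)
        fig, ax = plt.subplots(figsize=(7, 4.5))
        folds = plot["fold"].to_numpy()
        # error bars: SD of the shuffled counts propagated onto the fold
        errs = plot["rand_sd"].to_numpy() * folds / plot["rand_mean"].to_numpy()
        ax.bar(plot["feature"], folds, yerr=errs, capsize=3, color="#d65f5f")
        ax.axhline(1.0, ls="--", lw=0.8, color="grey")
        for i, row in plot.iterrows():
            txt = "p<1e-99" if row["p_value"] < 1e-99 else f"p={row['p_value']:.2g}"
            ax.annotate(txt, (i, row["fold"]), textcoords="offset points",
                        xytext=(0, 12), ha="center", fontsize=6)
        ax.set_ylabel("fold enrichment (observed / shuffled mean)")
        ax.set_title("Feature enrichment vs shuffled peaks")
        ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        _save(fig, fig_dir / "enrichment.merged")
        plt.close(fig)


def _upset_plot(plt, combos: pd.DataFrame, base: Path, max_combos: int = 20) -> None:
    """Minimal upset-style plot: count bars over a membership dot matrix."""
    combos = combos.head(max_combos)
    names = list(FEATURE_NAMES)
    n = len(combos)
    fig, (ax_bar, ax_dot) = plt.subplots(
        2, 1, figsize=(max(4.0, 0.45 * n + 2), 5),
        sharex=True, gridspec_kw={"height_ratios": [2, 1]})
    ax_bar.bar(range(n), combos["count"], color="#333333")
    ax_bar.set_ylabel("peaks")
    ax_bar.set_title("Feature combinations")
    for x, combo in enumerate(combos["combination"]):
        members = set(combo.split("+"))
        for y, feat in enumerate(names):
            present = feat in members
            ax_dot.plot(x, y, "o", ms=6,
                        color="#333333" if present else "#dddddd")
    ax_dot.set_yticks(range(len(names)))
    ax_dot.set_yticklabels(names, fontsize=7)
    ax_dot.set_xticks(range(n))
    ax_dot.set_xticklabels([], visible=False)
    ax_dot.set_xlim(-0.5, n - 0.5)
    ax_dot.invert_yaxis()
    fig.tight_layout()
    _save(fig, base)
    plt.close(fig)
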