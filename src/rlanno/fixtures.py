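"""Synthetic genomes, genes, expression tables and peaks with known truth.

Real DRIP-seq validation needs stranded (DRIPc-style) data; this module
stands in for it at desk scale: it lays out non-overlapping genes on
small chromosomes, draws expression values, and drops peaks of four
placement classes with a recorded ground-truth annotation for each:

* ``gene_body`` — wholly inside the span of one isolated gene; the
  unambiguous case, where the template strand is simply the complement
  of that gene's strand;
* ``flank_only`` — wholly inside the upstream or downstream flank of an
  isolated gene; assigned to that gene but warned (antisense R-loops
  concentrate at gene ends);
* ``two_gene_overlap`` — spanning the shared body of two overlapping
  genes, both expressed with distinct values; the higher-expressed gene
  is the truth, and the peak is warned;
* ``intergenic`` — farther than one flank size from every gene.

Truth flags are computed here by straight-line interval arithmetic on
the raw gene tuples, independently of the annotation code paths, so
end-to-end scoring is a genuine cross-check.  The layout assumes the
default 5 kb flanks; generation is deterministic given the seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotator import AnnotationRecord
from .genome_model import FEATURE_NAMES, GeneModel, GenomicInterval

__all__ = ["FixtureSpec", "Fixture", "generate", "score_against_truth"]

TRUTH_COLUMNS = [
    "peak_name", "placement_class", "chrom", "start", "end",
    "gene", "template_strand",
    *FEATURE_NAMES,
    "warning", "expressed",
]

_FLANK = 5000      # layout designed for the default flank size
_CLEARANCE = 1500  # extra spacing beyond flanks between slot contents


class FixtureError(ValueError):
    """The requested fixture cannot be laid out on the given genome."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults emulate a small two-chromosome genome with kilobase-scale
    genes and a 70% expressed fraction; expression values for expressed
    genes are log-uniform over [0.1, 1000] (a realistic TPM dynamic
    range) and exactly 0 for silent genes, so the default threshold of 0
    separates them.
    """

    n_chroms: int = 2
    chrom_len: int = 1_000_000
    n_genes: int = 40
    gene_len_range: Tuple[int, int] = (2_000, 20_000)
    exon_count_range: Tuple[int, int] = (1, 6)
    expressed_fraction: float = 0.7
    expression_law: Tuple[float, float] = (0.1, 1000.0)
    peak_len_range: Tuple[int, int] = (300, 3_000)
    peak_classes: Dict[str, int] = field(default_factory=lambda: {
        "gene_body": 120, "flank_only": 30, "two_gene_overlap": 20, "intergenic": 30,
    })
    seed: int = 1

    def total_peaks(self) -> int:
        return sum(self.peak_classes.values())


@dataclass
class Fixture:
    """A generated study: inputs plus the ground-truth annotation table."""

    spec: FixtureSpec
    peaks: List[GenomicInterval]
    genes: List[GeneModel]
    expression: Dict[str, float]
    chrom_sizes: Dict[str, int]
    truth: pd.DataFrame

    def write(self, out_dir) -> None:
        """Write peaks.bed, genes.bed12, expression.tsv, chrom.sizes, truth.tsv."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "peaks.bed", "w") as fh:
            for p in self.peaks:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\n")
        with open(out_dir / "genes.bed12", "w") as fh:
            for g in self.genes:
                sizes = ",".join(map(str, g.block_sizes)) + ","
                starts = ",".join(map(str, g.block_starts)) + ","
                fh.write("\t".join([
                    g.chrom, str(g.start), str(g.end), g.name, "0", g.strand,
                    str(g.thick_start), str(g.thick_end), "0",
                    str(len(g.block_sizes)), sizes, starts,
                ]) + "\n")
        with open(out_dir / "expression.tsv", "w") as fh:
            for name in sorted(self.expression):
                fh.write(f"{name}\t{self.expression[name]:g}\n")
        with open(out_dir / "chrom.sizes", "w") as fh:
            for chrom in sorted(self.chrom_sizes):
                fh.write(f"{chrom}\t{self.chrom_sizes[chrom]}\n")
        self.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene construction

def _make_blocks(rng: np.random.Generator, length: int, n_exons: int) -> Tuple[List[int], List[int]]:
    """Split ``length`` into n_exons exons separated by n_exons-1 introns."""
    parts = 2 * n_exons - 1
    if parts == 1:
        return [0], [length]
    cuts = np.sort(rng.choice(np.arange(1, length), size=parts - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    sizes = np.diff(bounds)
    starts, block_sizes, pos = [], [], 0
    for i, size in enumerate(sizes):
        if i % 2 == 0:  # exon
            starts.append(pos)
            block_sizes.append(int(size))
        pos += int(size)
    return starts, block_sizes


def _make_gene(rng: np.random.Generator, chrom: str, start: int,
               length: int, name: str, spec: FixtureSpec) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    lo, hi = spec.exon_count_range
    max_exons = max(1, min(hi, length // 4))
    n_exons = int(rng.integers(max(1, lo), max_exons + 1))
    block_starts, block_sizes = _make_blocks(rng, length, n_exons)
    end = start + length
    if rng.random() < 0.2:  # non-coding
        thick_start = thick_end = start
    else:
        a, b = sorted(rng.integers(start + 1, end, size=2).tolist())
        if a == b:
            b = min(end, a + 1)
        thick_start, thick_end = a, b
    return GeneModel(
        GenomicInterval(chrom, start, end, name=name, strand=strand),
        thick_start, thick_end, tuple(block_starts), tuple(block_sizes),
    )


# ---------------------------------------------------------------------------
# independent truth-flag arithmetic (deliberately not via genome_model)

def _truth_feature_intervals(g: GeneModel) -> Dict[str, List[Tuple[int, int]]]:
    exons = [(g.start + off, g.start + off + size)
             for off, size in zip(g.block_starts, g.block_sizes)]
    introns = [(a_end, b_start) for (_, a_end), (b_start, _) in zip(exons, exons[1:])
               if a_end < b_start]
    def clip(ivs, lo, hi):
        return [(max(s, lo), min(e, hi)) for s, e in ivs if max(s, lo) < min(e, hi)]
    if g.thick_end > g.thick_start:
        left = clip(exons, g.start, g.thick_start)
        right = clip(exons, g.thick_end, g.end)
    else:
        left, right = [], []
    utr5, utr3 = (left, right) if g.strand == "+" else (right, left)
    if g.strand == "+":
        up = [(g.start - _FLANK, g.start)]
        down = [(g.end, g.end + _FLANK)]
    else:
        up = [(g.end, g.end + _FLANK)]
        down = [(g.start - _FLANK, g.start)]
    return {"Upstream": [(max(0, s), e) for s, e in up], "5UTR": utr5, "Exon": exons,
            "Intron": introns, "3UTR": utr3, "Downstream": [(max(0, s), e) for s, e in down]}


def _truth_flags(peak: GenomicInterval, gene: GeneModel) -> Dict[str, bool]:
    feats = _truth_feature_intervals(gene)
    return {
        name: any(min(peak.end, e) - max(peak.start, s) >= 1 for s, e in ivs)
        for name, ivs in feats.items()
    }


# ---------------------------------------------------------------------------
# generation

def generate(spec: FixtureSpec, out_dir=None) -> Fixture:
    """Generate a fixture study; optionally write its five files to ``out_dir``.

    Raises :class:`FixtureError` before writing anything if the gene and
    flank footprint cannot fit on the requested chromosomes.
    """
    rng = np.random.default_rng(spec.seed)
    min_len, max_len = spec.gene_len_range
    if min_len < 800 or min_len > max_len:
        raise FixtureError(f"gene_len_range {spec.gene_len_range} unusable (need 800 <= min <= max)")

    n_pair_peaks = spec.peak_classes.get("two_gene_overlap", 0)
    n_pairs = 0 if n_pair_peaks == 0 else max(1, min(spec.n_genes // 10, n_pair_peaks))
    n_iso = spec.n_genes - 2 * n_pairs
    if n_iso < 1 and (spec.peak_classes.get("gene_body", 0) or spec.peak_classes.get("flank_only", 0)):
        raise FixtureError("not enough genes for isolated-gene peak classes")

    n_slots = n_iso + n_pairs
    slots_per_chrom = math.ceil(n_slots / spec.n_chroms)
    slot_width = spec.chrom_len // max(1, slots_per_chrom)
    pair_footprint = 2 * max_len + 2 * _FLANK + 2 * _CLEARANCE
    iso_footprint = max_len + 2 * _FLANK + 2 * _CLEARANCE
    need = pair_footprint if n_pairs else iso_footprint
    if slot_width < need:
        raise FixtureError(
            f"unsatisfiable layout: slot width {slot_width} bp < required footprint {need} bp; "
            "enlarge chrom_len or reduce n_genes / gene_len_range"
        )

    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    chrom_sizes = {c: spec.chrom_len for c in chroms}

    # slot k -> (chrom, window start); pairs fill the first n_pairs slots
    genes: List[GeneModel] = []
    iso_genes: List[GeneModel] = []
    pairs: List[Tuple[GeneModel, GeneModel]] = []
    free_zones: List[Tuple[str, int, int]] = []  # gaps safe for intergenic peaks
    gene_idx = 0
    for k in range(n_slots):
        chrom = chroms[k // slots_per_chrom]
        slot_start = (k % slots_per_chrom) * slot_width
        content_start = slot_start + _CLEARANCE + _FLANK
        if k < n_pairs:
            len_a = int(rng.integers(max(min_len, 1000), max_len + 1))
            len_b = int(rng.integers(max(min_len, 1000), max_len + 1))
            a = _make_gene(rng, chrom, content_start, len_a, f"gene_{gene_idx:04d}", spec)
            gene_idx += 1
            b_start = a.start + len_a // 2  # guaranteed body overlap of len_a//2 bp or more
            b = _make_gene(rng, chrom, b_start, len_b, f"gene_{gene_idx:04d}", spec)
            gene_idx += 1
            genes += [a, b]
            pairs.append((a, b))
            content_end = max(a.end, b.end)
        else:
            length = int(rng.integers(min_len, max_len + 1))
            g = _make_gene(rng, chrom, content_start, length, f"gene_{gene_idx:04d}", spec)
            gene_idx += 1
            genes.append(g)
            iso_genes.append(g)
            content_end = g.end
        free_lo = content_end + _FLANK + _CLEARANCE
        free_hi = slot_start + slot_width - _CLEARANCE
        if free_hi - free_lo >= spec.peak_len_range[1] + 2:
            free_zones.append((chrom, free_lo, free_hi))

    # expression: expressed_fraction of isolated genes; pair genes always
    # expressed with distinct values so their truth is decided by expression
    expression: Dict[str, float] = {}
    n_expr = int(round(spec.expressed_fraction * len(iso_genes)))
    order = rng.permutation(len(iso_genes))
    lo_e, hi_e = spec.expression_law
    for rank, idx in enumerate(order):
        g = iso_genes[idx]
        if rank < n_expr:
            expression[g.name] = float(np.exp(rng.uniform(np.log(lo_e), np.log(hi_e))))
        else:
            expression[g.name] = 0.0
    for a, b in pairs:
        va = float(np.exp(rng.uniform(np.log(lo_e), np.log(hi_e))))
        vb = float(np.exp(rng.uniform(np.log(lo_e), np.log(hi_e))))
        while vb == va:  # pragma: no cover - measure-zero
            vb = float(np.exp(rng.uniform(np.log(lo_e), np.log(hi_e))))
        expression[a.name], expression[b.name] = va, vb

    peaks: List[GenomicInterval] = []
    truth_rows: List[dict] = []
    peak_idx = 0

    def add_peak(chrom: str, start: int, end: int, placement: str,
                 gene: Optional[GeneModel], warning: bool) -> None:
        nonlocal peak_idx
        name = f"peak_{peak_idx:05d}"
        peak_idx += 1
        peak = GenomicInterval(chrom, start, end, name=name)
        peaks.append(peak)
        if gene is None:
            flags = {f: False for f in FEATURE_NAMES}
            row = dict(peak_name=name, placement_class=placement, chrom=chrom,
                       start=start, end=end, gene="NA", template_strand="NA",
                       warning=False, expressed=False, **flags)
        else:
            flags = _truth_flags(peak, gene)
            row = dict(peak_name=name, placement_class=placement, chrom=chrom,
                       start=start, end=end, gene=gene.name,
                       template_strand="-" if gene.strand == "+" else "+",
                       warning=warning,
                       expressed=expression.get(gene.name, 0.0) > 0.0,
                       **flags)
        truth_rows.append(row)

    p_lo, p_hi = spec.peak_len_range

    # gene_body: wholly inside one isolated gene's span
    n_body = spec.peak_classes.get("gene_body", 0)
    if n_body and not iso_genes:
        raise FixtureError("gene_body peaks requested but no isolated genes available")
    for i in range(n_body):
        g = iso_genes[i % len(iso_genes)]
        max_here = min(p_hi, g.end - g.start)
        length = int(rng.integers(min(p_lo, max_here), max_here + 1))
        start = int(rng.integers(g.start, g.end - length + 1))
        add_peak(g.chrom, start, start + length, "gene_body", g, warning=False)

    # flank_only: wholly inside one flank, touching no gene body
    n_flank = spec.peak_classes.get("flank_only", 0)
    if n_flank and not iso_genes:
        raise FixtureError("flank_only peaks requested but no isolated genes available")
    for i in range(n_flank):
        g = iso_genes[i % len(iso_genes)]
        side_left = bool(rng.random() < 0.5)
        length = int(rng.integers(p_lo, min(p_hi, _FLANK - 2) + 1))
        if side_left:
            lo, hi = g.start - _FLANK, g.start
        else:
            lo, hi = g.end, g.end + _FLANK
        start = int(rng.integers(lo, hi - length))  # strictly inside, 1bp off the body
        if not side_left:
            start = max(start, lo + 1)
        add_peak(g.chrom, start, start + length, "flank_only", g, warning=True)

    # two_gene_overlap: inside the shared body of an overlapping pair
    for i in range(n_pair_peaks):
        a, b = pairs[i % len(pairs)]
        ov_lo, ov_hi = b.start, min(a.end, b.end)
        width = ov_hi - ov_lo
        length = int(rng.integers(min(p_lo, max(2, width // 2)), max(3, min(p_hi, width)) + 1))
        length = min(length, width)
        start = int(rng.integers(ov_lo, ov_hi - length + 1))
        winner = a if expression[a.name] > expression[b.name] else b
        add_peak(a.chrom, start, start + length, "two_gene_overlap", winner, warning=True)

    # intergenic: in the free zone of a slot, > flank away from every gene
    n_inter = spec.peak_classes.get("intergenic", 0)
    if n_inter and not free_zones:
        raise FixtureError("intergenic peaks requested but no free zones in the layout")
    for i in range(n_inter):
        chrom, lo, hi = free_zones[i % len(free_zones)]
        length = int(rng.integers(p_lo, min(p_hi, hi - lo - 1) + 1))
        start = int(rng.integers(lo, hi - length + 1))
        add_peak(chrom, start, start + length, "intergenic", None, warning=False)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    fixture = Fixture(spec=spec, peaks=peaks, genes=genes, expression=expression,
                      chrom_sizes=chrom_sizes, truth=truth)
    if out_dir is not None:
        fixture.write(out_dir)
    return fixture


# ---------------------------------------------------------------------------
# scoring

def score_against_truth(
    records: Sequence[AnnotationRecord],
    intergenic: Sequence[GenomicInterval],
    truth: pd.DataFrame,
) -> Tuple[float, pd.DataFrame]:
    """Score annotation output against a fixture's ground truth.

    A genic peak is *correct* when assigned gene, template strand and
    all six feature flags match the truth row; an intergenic peak when
    it was annotated intergenic.  Returns the overall correct fraction
    and a per-placement-class breakdown (gene / strand / flags / warning
    accuracies).
    """
    by_name = {r.peak.name: r for r in records}
    inter_names = {p.name for p in intergenic}
    unknown = set(truth["peak_name"]) ^ (set(by_name) | inter_names)
    if unknown:
        raise ValueError(f"peak names do not align with truth table: {sorted(unknown)[:5]} ...")

    rows = []
    for _, t in truth.iterrows():
        cls = t["placement_class"]
        rec = by_name.get(t["peak_name"])
        if t["gene"] == "NA":
            ok = t["peak_name"] in inter_names
            rows.append({"class": cls, "gene_ok": ok, "strand_ok": ok,
                         "flags_ok": ok, "warning_ok": ok, "correct": ok})
            continue
        if rec is None:  # truth genic but annotated intergenic
            rows.append({"class": cls, "gene_ok": False, "strand_ok": False,
                         "flags_ok": False, "warning_ok": False, "correct": False})
            continue
        gene_ok = rec.gene_name == t["gene"]
        strand_ok = rec.template_strand == t["template_strand"]
        flags_ok = all(bool(t[f]) == flag for f, flag in zip(FEATURE_NAMES, rec.features))
        warning_ok = bool(t["warning"]) == rec.warning
        rows.append({"class": cls, "gene_ok": gene_ok, "strand_ok": strand_ok,
                     "flags_ok": flags_ok, "warning_ok": warning_ok,
                     "correct": gene_ok and strand_ok and flags_ok})
    df = pd.DataFrame(rows)
    breakdown = df.groupby("class").agg(
        n=("correct", "size"),
        correct_fraction=("correct", "mean"),
        gene_accuracy=("gene_ok", "mean"),
        strand_accuracy=("strand_ok", "mean"),
        flags_accuracy=("flags_ok", "mean"),
        warning_accuracy=("warning_ok", "mean"),
    ).reset_index()
    return float(df["correct"].mean()), breakdown
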