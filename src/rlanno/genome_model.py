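"""Gene models and per-gene feature decomposition.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  A gene is a BED12 record — a stranded span with a
*thick* (CDS) sub-interval and a list of exon blocks — from which the
transcribed features (5'UTR, exon, intron, 3'UTR) are derived, plus
strand-aware upstream/downstream flanks of configurable size.

Feature definitions
-------------------
* exons are the BED12 blocks; introns are the gaps between consecutive
  blocks, so exons and introns tile the gene span exactly;
* the 5'UTR is the exonic sequence strictly 5' of the CDS (before
  ``thick_start`` on the + strand, after ``thick_end`` on the − strand);
  the 3'UTR is the symmetric exonic complement on the 3' side;
* non-coding genes (``thick_start == thick_end``) have no UTRs — every
  transcribed base counts as exon or intron only;
* the upstream flank abuts the 5' gene boundary and the downstream flank
  the 3' boundary, clamped to ``[0, chrom_len)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "FeatureSet",
    "ChromSizes",
    "ReferenceFormatError",
    "derive_features",
    "flank_regions",
    "extended_span",
    "validate_chrom_sizes",
]

FEATURE_NAMES = ("Upstream", "5UTR", "Exon", "Intron", "3UTR", "Downstream")


class ReferenceFormatError(ValueError):
    """A gene reference record violates the gene-model contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored half-open span ``[start, end)``.

    Parameters
    ----------
    chrom : str
        Chromosome identifier (matched as an exact string, no
        normalisation).
    start, end : int
        0-based half-open bounds, ``0 <= start < end``.
    name : str, optional
        Label (peak name, gene name, ...).
    strand : str, optional
        One of ``+``, ``-``, ``.`` or ``None``.
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chromosome must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


# Chromosome name -> length (bp).  Plain mapping; validated on load.
ChromSizes = Dict[str, int]


def validate_chrom_sizes(sizes: ChromSizes) -> ChromSizes:
    for chrom, length in sizes.items():
        if not chrom:
            raise ValueError("empty chromosome name in sizes table")
        if int(length) <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
    return sizes


@dataclass(frozen=True)
class GeneModel:
    """A BED12 gene record: stranded span, CDS bounds, exon blocks."""

    interval: GenomicInterval
    thick_start: int
    thick_end: int
    block_starts: Tuple[int, ...]
    block_sizes: Tuple[int, ...]

    def __post_init__(self) -> None:
        iv = self.interval
        name = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
        if iv.strand not in ("+", "-"):
            raise ReferenceFormatError(
                f"gene {name}: strand must be '+' or '-', got {iv.strand!r}"
            )
        object.__setattr__(self, "block_starts", tuple(self.block_starts))
        object.__setattr__(self, "block_sizes", tuple(self.block_sizes))
        if len(self.block_starts) != len(self.block_sizes) or not self.block_starts:
            raise ReferenceFormatError(
                f"gene {name}: blockStarts and blockSizes must be equal-length, non-empty"
            )
        if any(s <= 0 for s in self.block_sizes):
            raise ReferenceFormatError(f"gene {name}: block sizes must be positive")
        if self.block_starts[0] != 0:
            raise ReferenceFormatError(f"gene {name}: first block must start at offset 0")
        prev_end = -1
        for off, size in zip(self.block_starts, self.block_sizes):
            if off <= prev_end and prev_end >= 0:
                raise ReferenceFormatError(
                    f"gene {name}: blocks must be sorted and non-overlapping"
                )
            prev_end = off + size - 1
        if iv.start + self.block_starts[-1] + self.block_sizes[-1] != iv.end:
            raise ReferenceFormatError(
                f"gene {name}: last block must end at the gene end "
                f"({iv.start}+{self.block_starts[-1]}+{self.block_sizes[-1]} != {iv.end})"
            )
        if not (iv.start <= self.thick_start <= self.thick_end <= iv.end):
            raise ReferenceFormatError(
                f"gene {name}: thick region [{self.thick_start},{self.thick_end}) "
                f"must lie within [{iv.start},{iv.end})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def name(self) -> str:
        return self.interval.name or f"{self.chrom}:{self.start}-{self.end}"

    @property
    def strand(self) -> str:
        return self.interval.strand  # type: ignore[return-value]

    @property
    def is_coding(self) -> bool:
        return self.thick_end > self.thick_start

    def exon_intervals(self) -> List[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, self.start + off, self.start + off + size,
                            name=self.name, strand=self.strand)
            for off, size in zip(self.block_starts, self.block_sizes)
        ]


@dataclass
class FeatureSet:
    """Per-gene decomposition into transcribed features and flanks.

    ``exons`` and ``introns`` tile the gene span; ``utr5``/``utr3`` are
    subsets of the exonic bases; ``upstream``/``downstream`` abut the 5'
    and 3' gene boundaries (strand-aware) and are filled by
    :func:`flank_regions`, not by :func:`derive_features`.
    """

    gene_name: str
    utr5: List[GenomicInterval] = field(default_factory=list)
    utr3: List[GenomicInterval] = field(default_factory=list)
    exons: List[GenomicInterval] = field(default_factory=list)
    introns: List[GenomicInterval] = field(default_factory=list)
    upstream: List[GenomicInterval] = field(default_factory=list)
    downstream: List[GenomicInterval] = field(default_factory=list)

    def by_feature(self) -> Dict[str, List[GenomicInterval]]:
        return {
            "Upstream": self.upstream,
            "5UTR": self.utr5,
            "Exon": self.exons,
            "Intron": self.introns,
            "3UTR": self.utr3,
            "Downstream": self.downstream,
        }


def _clip(intervals: List[GenomicInterval], lo: int, hi: int) -> List[GenomicInterval]:
    """Intersect each interval with [lo, hi), dropping empty results."""
    out = []
    for iv in intervals:
        s, e = max(iv.start, lo), min(iv.end, hi)
        if s < e:
            out.append(replace(iv, start=s, end=e))
    return out


def derive_features(gene: GeneModel) -> FeatureSet:
    """Decompose a gene model into 5'UTR / exon / intron / 3'UTR intervals.

    Upstream/downstream flanks are left empty here; fill them with
    :func:`flank_regions` once flank sizes and the chromosome length are
    known.
    """
    exons = gene.exon_intervals()
    introns: List[GenomicInterval] = []
    for prev, nxt in zip(exons, exons[1:]):
        if prev.end < nxt.start:
            introns.append(GenomicInterval(gene.chrom, prev.end, nxt.start,
                                           name=gene.name, strand=gene.strand))

    fs = FeatureSet(gene_name=gene.name, exons=exons, introns=introns)
    if gene.is_coding:
        left = _clip(exons, gene.start, gene.thick_start)   # exonic, 5' of CDS in genome coords
        right = _clip(exons, gene.thick_end, gene.end)      # exonic, 3' of CDS in genome coords
        if gene.strand == "+":
            fs.utr5, fs.utr3 = left, right
        else:
            fs.utr5, fs.utr3 = right, left
    return fs


def flank_regions(
    gene: GeneModel, up_size: int, down_size: int, chrom_len: int
) -> Tuple[Optional[GenomicInterval], Optional[GenomicInterval]]:
    """Strand-aware upstream/downstream flanks, clamped to the chromosome.

    Returns ``(upstream, downstream)``; a flank that ends up empty (size
    0 or squeezed out at a chromosome edge) is returned as ``None``.
    """
    if up_size < 0 or down_size < 0:
        raise ValueError("flank sizes must be non-negative")

    def _mk(lo: int, hi: int) -> Optional[GenomicInterval]:
        lo, hi = max(0, lo), min(chrom_len, hi)
        if lo >= hi:
            return None
        return GenomicInterval(gene.chrom, lo, hi, name=gene.name, strand=gene.strand)

    if gene.strand == "+":
        up = _mk(gene.start - up_size, gene.start)
        down = _mk(gene.end, gene.end + down_size)
    else:
        up = _mk(gene.end, gene.end + up_size)
        down = _mk(gene.start - down_size, gene.start)
    return up, down


def extended_span(gene: GeneModel, up_size: int, down_size: int, chrom_len: int) -> GenomicInterval:
    """The gene span extended by its strand-aware flanks (the genic test window)."""
    if gene.strand == "+":
        lo = max(0, gene.start - up_size)
        hi = min(chrom_len, gene.end + down_size)
    else:
        lo = max(0, gene.start - down_size)
        hi = min(chrom_len, gene.end + up_size)
    return GenomicInterval(gene.chrom, lo, hi, name=gene.name, strand=gene.strand)


def features_with_flanks(
    gene: GeneModel, up_size: int, down_size: int, chrom_len: int
) -> FeatureSet:
    """Convenience: :func:`derive_features` plus filled flanks."""
    fs = derive_features(gene)
    up, down = flank_regions(gene, up_size, down_size, chrom_len)
    fs.upstream = [up] if up else []
    fs.downstream = [down] if down else []
    return fs
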