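"""Readers and writers for the plain-text formats the tool touches.

Supported formats: BED3/4/6 (query peaks, features, intergenic output),
BED12 (gene reference), 2-column expression tables (gene name +
normalized value, TPM/FPKM/other), 2-column ``chrom.sizes`` tables, and
the tab-separated annotation table the annotator emits.

All parsers are strict: malformed lines raise :class:`BedParseError`
with the offending file and line number rather than being silently
skipped.  ``track``/``browser`` lines and ``#`` comments are tolerated.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

from .genome_model import (
    ChromSizes,
    GeneModel,
    GenomicInterval,
    ReferenceFormatError,
    validate_chrom_sizes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BedParseError",
    "ExpressionTable",
    "ReferenceSet",
    "read_bed",
    "read_bed12",
    "read_expression_table",
    "read_chrom_sizes",
    "load_reference",
    "write_bed",
    "write_annotation_table",
    "ANNOTATION_COLUMNS",
]

ANNOTATION_COLUMNS = [
    "chrom", "start", "end", "peak_name",
    "gene_name", "gene_strand", "expression_value",
    "Upstream", "5UTR", "Exon", "Intron", "3UTR", "Downstream",
    "warning",
]


class BedParseError(ValueError):
    """A data line could not be parsed; carries file path and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _data_lines(path):
    """Yield (lineno, fields) for data lines, skipping headers/comments."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(path) -> List[GenomicInterval]:
    """Read a BED3/4/6 file into a list of intervals, in file order.

    Column 4 is used as the interval name when present; otherwise the
    interval is auto-named ``peak_<lineno>``.  Column 6 is taken as the
    strand when present.
    """
    intervals: List[GenomicInterval] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise BedParseError(path, lineno, f"expected >=3 tab-separated columns, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise BedParseError(path, lineno, f"non-integer coordinates {fields[1]!r}/{fields[2]!r}") from None
        if start >= end or start < 0:
            raise BedParseError(path, lineno, f"invalid interval [{start},{end}): require 0 <= start < end")
        name = fields[3] if len(fields) >= 4 and fields[3] != "" else f"peak_{lineno}"
        strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-", ".") else None
        intervals.append(GenomicInterval(chrom, start, end, name=name, strand=strand))
    return intervals


def _int_list(text: str) -> List[int]:
    return [int(tok) for tok in text.rstrip(",").split(",") if tok != ""]


def read_bed12(path) -> List[GeneModel]:
    """Read a 12-column BED gene reference into gene models.

    Gene strand is mandatory (annotation needs it to orient features);
    block arithmetic must be self-consistent with chromStart/chromEnd.
    Trailing commas in the block lists are tolerated.
    """
    genes: List[GeneModel] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 12:
            raise BedParseError(path, lineno, f"expected 12 columns for BED12, got {len(fields)}")
        chrom, name, strand = fields[0], fields[3], fields[5]
        try:
            start, end = int(fields[1]), int(fields[2])
            thick_start, thick_end = int(fields[6]), int(fields[7])
            block_count = int(fields[9])
            block_sizes = _int_list(fields[10])
            block_starts = _int_list(fields[11])
        except ValueError:
            raise BedParseError(path, lineno, f"malformed numeric field in record {name!r}") from None
        if strand not in ("+", "-"):
            raise BedParseError(path, lineno, f"gene {name!r}: strand must be '+' or '-', got {strand!r}")
        if len(block_sizes) != block_count or len(block_starts) != block_count:
            raise BedParseError(
                path, lineno,
                f"gene {name!r}: blockCount={block_count} but {len(block_sizes)} sizes / "
                f"{len(block_starts)} starts listed",
            )
        try:
            interval = GenomicInterval(chrom, start, end, name=name, strand=strand)
            genes.append(GeneModel(interval, thick_start, thick_end,
                                   tuple(block_starts), tuple(block_sizes)))
        except (ValueError, ReferenceFormatError) as exc:
            raise BedParseError(path, lineno, str(exc)) from None
    return genes


@dataclass
class ExpressionTable:
    """Gene name -> normalized expression value (TPM/FPKM/other, unit-agnostic).

    Values are used exactly as provided — never rescaled or
    log-transformed — so any normalized metric works as long as it is
    consistent across genes.  An empty table means "no expression mode":
    every gene is treated as unexpressed and gene selection falls back
    to largest overlap.
    """

    values: Dict[str, float] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not self.values

    def get(self, gene_name: str) -> float:
        """Expression of a gene; genes absent from the table count as 0."""
        return self.values.get(gene_name, 0.0)

    def __contains__(self, gene_name: str) -> bool:
        return gene_name in self.values

    def __len__(self) -> int:
        return len(self.values)


def read_expression_table(path=None) -> ExpressionTable:
    """Read a 2-column (gene, value) table; ``None`` -> empty table.

    A first line whose second column is non-numeric is treated as a
    header.  Duplicate gene names keep the maximum value (a gene is
    "expressed" if any of its entries is) with a logged warning.
    """
    if path is None:
        return ExpressionTable()
    values: Dict[str, float] = {}
    duplicates = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise BedParseError(path, lineno, "expected 2 columns: gene name, expression value")
            name, raw_val = fields[0], fields[1]
            try:
                val = float(raw_val)
            except ValueError:
                if lineno == 1 and not values:
                    continue  # header
                raise BedParseError(path, lineno, f"non-numeric expression value {raw_val!r}") from None
            if val < 0:
                raise BedParseError(path, lineno, f"negative expression value {val} for gene {name!r}")
            if name in values:
                duplicates += 1
                val = max(val, values[name])
            values[name] = val
    if duplicates:
        logger.warning("expression table %s: %d duplicate gene name(s); kept the maximum value",
                       path, duplicates)
    return ExpressionTable(values)


def read_chrom_sizes(path) -> ChromSizes:
    """Read a 2-column (chromosome, length) table."""
    sizes: ChromSizes = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(path, lineno, "expected 2 columns: chromosome, length")
            try:
                length = int(fields[1])
            except ValueError:
                raise BedParseError(path, lineno, f"non-integer length {fields[1]!r}") from None
            if length <= 0:
                raise BedParseError(path, lineno, f"non-positive length {length} for {fields[0]!r}")
            sizes[fields[0]] = length
    return validate_chrom_sizes(sizes)


@dataclass
class ReferenceSet:
    """A loaded gene reference: models, chromosome sizes, optional feature BEDs.

    ``feature_beds`` holds per-feature interval lists keyed by feature
    name when the reference folder ships explicit ``5UTR.bed`` /
    ``3UTR.bed`` / ``exon.bed`` / ``intron.bed`` files; those take
    precedence over derivation from the BED12 unless derivation is
    forced at load time.
    """

    genes: List[GeneModel]
    chrom_sizes: ChromSizes
    feature_beds: Dict[str, List[GenomicInterval]] = field(default_factory=dict)


_FEATURE_FILES = {"5UTR": "5UTR.bed", "3UTR": "3UTR.bed", "Exon": "exon.bed", "Intron": "intron.bed"}


def load_reference(ref_dir, force_derive: bool = False) -> ReferenceSet:
    """Load a reference folder: ``genes.bed12`` + ``chrom.sizes`` (+ feature BEDs).

    With ``force_derive=True`` any shipped per-feature BED files are
    ignored and features are always derived from the BED12 blocks.
    """
    ref_dir = Path(ref_dir)
    genes_path = ref_dir / "genes.bed12"
    sizes_path = ref_dir / "chrom.sizes"
    for p in (genes_path, sizes_path):
        if not p.exists():
            raise FileNotFoundError(f"reference folder {ref_dir} is missing {p.name}")
    genes = read_bed12(genes_path)
    sizes = read_chrom_sizes(sizes_path)
    feature_beds: Dict[str, List[GenomicInterval]] = {}
    if not force_derive:
        for feat, fname in _FEATURE_FILES.items():
            p = ref_dir / fname
            if p.exists():
                feature_beds[feat] = read_bed(p)
    missing = sorted({g.chrom for g in genes} - set(sizes))
    if missing:
        raise ReferenceFormatError(
            f"genes on chromosome(s) {', '.join(missing)} absent from chrom.sizes"
        )
    return ReferenceSet(genes=genes, chrom_sizes=sizes, feature_beds=feature_beds)


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED (4 or 6 columns depending on strand presence)."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name or "."]
            if iv.strand is not None:
                cols += ["0", iv.strand]
            fh.write("\t".join(cols) + "\n")


def write_annotation_table(records: Sequence, path) -> None:
    """Write annotation records as the 14-column tab-separated table.

    Columns: peak coordinates and name, assigned gene name / strand /
    expression value, the six 0/1 feature flags, and the 0/1 warning
    flag.  Intergenic peaks are not part of this table; they go to a
    separate BED file.
    """
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for rec in records:
            flags = rec.features
            fh.write("\t".join([
                rec.peak.chrom, str(rec.peak.start), str(rec.peak.end),
                rec.peak.name or ".",
                rec.gene_name, rec.gene_strand,
                _fmt_expr(rec.expression_value),
                *("1" if f else "0" for f in flags),
                "1" if rec.warning else "0",
            ]) + "\n")


def _fmt_expr(value: Optional[float]) -> str:
    if value is None:
        return "NA"
    return f"{value:g}"


def chromosome_mismatch_report(peaks: Sequence[GenomicInterval], sizes: ChromSizes) -> List[str]:
    """Chromosomes present in the peaks but absent from the reference sizes."""
    return sorted({p.chrom for p in peaks} - set(sizes))
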