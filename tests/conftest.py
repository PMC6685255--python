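import numpy as np
import pytest

from rlanno.annotator import AnnotationParams
from rlanno.bed_io import ExpressionTable
from rlanno.fixtures import FixtureSpec, generate
from rlanno.genome_model import GeneModel, GenomicInterval


@pytest.fixture
def two_exon_gene() -> GeneModel:
    """chr1:[100,1000)+ with exons [100,300) and [700,1000), CDS [200,800)."""
    return GeneModel(
        GenomicInterval("chr1", 100, 1000, name="geneA", strand="+"),
        thick_start=200, thick_end=800,
        block_starts=(0, 600), block_sizes=(200, 300),
    )


@pytest.fixture
def default_params() -> AnnotationParams:
    return AnnotationParams()


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic study: 2x1 Mb genome, 40 genes, 200 peaks, seed 1."""
    return generate(FixtureSpec())


@pytest.fixture(scope="session")
def default_expr(default_fixture) -> ExpressionTable:
    return ExpressionTable(dict(default_fixture.expression))


def random_gene(rng: np.random.Generator, chrom: str = "chr1",
                max_start: int = 100_000) -> GeneModel:
    """A random, structurally valid gene model (shared helper for property tests)."""
    n_exons = int(rng.integers(1, 7))
    exon_sizes = rng.integers(1, 200, size=n_exons)
    intron_sizes = rng.integers(1, 500, size=max(0, n_exons - 1))
    starts, pos = [], 0
    for i, size in enumerate(exon_sizes):
        starts.append(pos)
        pos += int(size)
        if i < len(intron_sizes):
            pos += int(intron_sizes[i])
    length = pos
    start = int(rng.integers(0, max_start))
    end = start + length
    if rng.random() < 0.25:
        thick_start = thick_end = start
    else:
        a, b = sorted(rng.integers(start, end + 1, size=2).tolist())
        thick_start, thick_end = a, b
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(
        GenomicInterval(chrom, start, end, name=f"g{rng.integers(1e9)}", strand=strand),
        thick_start, thick_end, tuple(starts), tuple(int(s) for s in exon_sizes),
    )
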