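# Methods

## Model and assumptions

`rlanno` treats peak-to-gene annotation as a deterministic decision
procedure over genomic intervals, under two biological assumptions:

1. **R-loops are co-transcriptional.** A DNA:RNA hybrid needs a nascent
   transcript, so when a peak overlaps several genes the transcribed one
   is the plausible host, and among transcribed candidates the most
   expressed is the best guess. The template strand then follows as the
   complement of the assigned gene's annotated strand.
2. **Peaks are broad.** Kilobase-scale peaks routinely span several gene
   features and can reach genes whose TSS is far away. Overlap is
   therefore tested with the peak's full `[start, end)` extent against
   gene spans extended by both flanks, and all overlapped features are
   reported, not a single winner.

What the procedure cannot know from unstranded data is antisense
transcription. It does not try to infer it; it flags the two situations
where an antisense R-loop would silently invert the call — flank-only
peaks and peaks over multiple expressed genes — and leaves exclusion to
the user. That is a stated limitation, not a tunable.

## Coordinates and formats

All coordinates are BED-convention 0-based half-open, preserved verbatim
from input to output. Genes come from a 12-column BED (`genes.bed12`):
exons are the blocks, introns the gaps, and UTRs the exonic sequence on
either side of the thick (CDS) interval, oriented by strand;
`thick_start == thick_end` marks a non-coding record with no UTRs, and a
CDS covering the whole span likewise yields empty UTRs. Multiple records
sharing a gene name are kept as independent models; whichever record wins
selection is reported. If a reference folder ships explicit per-feature
BED files they take precedence over derivation (a loader flag forces
derivation); nothing in the pipeline depends on whether those files are
per-transcript or per-gene unions. Chromosome names are matched exactly —
no `chr` normalization — and peaks on chromosomes missing from
`chrom.sizes` are reported in a mismatch warning and classed intergenic,
because silent naming mismatches are the dominant real-world failure.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `up_size`, `down_size` | 5000 bp | strand-aware flank added to each gene for the genic test and the Upstream/Downstream features |
| `expression_threshold` | 0 | a gene is expressed when its value is strictly greater; 0 is the least-assuming choice and makes "expressed" mean "any signal" |
| `n_shuffles` | 10 | shuffle replicates for enrichment; ≥ 2 so the SD is defined, 10 balances SD stability against runtime |
| `seed` | 0 | drives all shuffling; replicate *i* uses rng seed `[seed, i]` |

Expression values are consumed raw — never rescaled or log-transformed —
so any consistent normalized metric (TPM, FPKM, CPM…) gives identical
assignments under any strictly monotone re-metric that preserves which
genes clear the threshold; the test suite asserts this invariance.
Duplicate names in the expression table keep the maximum value (the
conservative choice for an "is expressed" question), and genes absent
from the table count as 0.

## Tie-breaking and determinism

The selection order is: single gene; else highest expression (when the
candidates' values are not all equal and the maximum exceeds the
threshold); else largest overlap with the flank-extended span. Exact ties
fall through overlap to the lexicographically smallest gene name, giving
a total order, so two runs on identical inputs produce byte-identical
output directories — including figures, which are written with a fixed
SVG hash salt and no date metadata. "Largest overlap" deliberately uses
the extended span, consistent with the genic test itself.

## Shuffle null and the chi-squared test

Shuffling is implemented internally rather than shelling out to an
external binary, with the standard semantics: each peak keeps its length,
lands on a chromosome drawn with probability proportional to chromosome
length (restricted to chromosomes that can hold it), at a uniform start;
overlaps among shuffled peaks are allowed and there are no exclusion
regions, and placement is genome-wide rather than source-chromosome
restricted. Each replicate is annotated with exactly the query's
parameters and expression table. Per feature, fold = observed /
mean(shuffled); a zero mean with observed peaks reports an infinite fold,
and 0/0 reports 1 (no signal either way). The per-feature p-value is a
Pearson chi-squared (df = 1, no continuity correction) on the 2×2 table
`[[obs_in, obs_out], [round(mean_in), round(mean_out)]]` — the minimal
contingency construction yielding one p-value per feature; a zero
marginal is flagged degenerate with p = 1 rather than raising. Rounding
the random means to integers makes the second row a bona fide count
vector; with ≥ 10 replicates the rounding bias is far below the test's
resolution.

## Synthetic studies: what they emulate, and what not

The fixtures generator lays out non-overlapping genes in fixed-width
slots on small chromosomes (default two of 1 Mb, 40 genes of 2–20 kb,
1–6 exons, 70% expressed with log-uniform values on [0.1, 1000] and exact
zeros otherwise — a realistic TPM dynamic range whose zeros exercise the
threshold rule). Peaks are placed in four classes with recorded truth:
`gene_body` (120, unambiguous), `flank_only` (30, warned), `two_gene_overlap`
(20, both genes expressed with distinct values, decided by expression and
warned), `intergenic` (30, clear of every extended span). Truth flags are
computed by separate straight-line interval arithmetic inside the
generator, so end-to-end scoring cross-checks two independent code
paths. Problem sizes throughout the suite (hundreds of peaks, tens of
genes, tens of shuffle trials) were chosen as the smallest at which the
checked properties are statistically meaningful.

What the fixtures do **not** emulate: read-level noise, peak-caller
artifacts, GC or chromatin composition, overlapping transcript isoforms,
and — crucially — genuine antisense transcription. A perfect score on
synthetic data therefore demonstrates fidelity of the decision rules and
interval arithmetic, not biological accuracy on real DRIP data, where
ambiguous placements are exactly the flagged classes. The ambiguous
classes' truth is defined by this package's own tie-break rules, so they
test implementation consistency, not biology.

## Numerical and edge-case choices

* Minimum overlap to count is 1 bp everywhere; half-open adjacency is 0.
* Flanks clamp to `[0, chrom_len)`; a flank squeezed to nothing at a
  chromosome edge is simply absent.
* The pie chart needs one label per peak; multi-feature peaks collapse by
  the priority 5'UTR > 3'UTR > Exon > Intron > Upstream > Downstream >
  Intergenic (transcribed gene-body features first). All plotted numbers
  are also written as TSVs, which are the canonical artifact.
* Without an expression table every record is classed unexpressed, the
  expression column prints `NA`, and selection is purely largest-overlap.
* Null calibration is judged as |fold − 1| ≤ 3·SE with
  SE = sd·√(1 + 1/n)/mean — the SD of a single null draw plus the
  uncertainty of the estimated mean.

## Known limitations

Antisense R-loop peaks are flagged, never resolved. The shuffle null is
composition-blind (no GC/chromatin matching, no blacklist support). No
GTF/GFF ingestion and no isoform collapsing — references must be BED12.
Expression ties across genes are decided by geometry, which on real data
is arbitrary at exact equality (vanishingly rare with continuous
metrics).
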