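# Methods notes

This note records the model behind `difcir`, the parameter choices, the
numerical conventions, and what the synthetic data generator does and does
not emulate.

## Signal model

The quantitative unit throughout is the **split read**: a read spanning a
circle's ligation junction. Split-read counts behave like the count units
of RNA-seq differential analysis — many cells in a tissue sample can shed
the same circle, so the junction count acts as a copy-number proxy — and,
unlike coverage-based quantification, they do not favour genes that shed
longer circles. All downstream statistics are computed on per-gene sums of
these counts.

Coordinates are 0-based half-open (BED convention) everywhere internally;
GTF input is shifted at the parsing boundary. Strand is ignored: a circular
junction is an unstranded observation.

## Processing cascade

Per sample, in order:

| step | rule | default | note |
|---|---|---|---|
| mito filter | chrom in {chrM, MT, chrMT} | — | kept aside, not discarded |
| length filter | drop length > `L_max` | 100 000 bp | length == cap survives |
| junction merge | link when same chrom, \|Δstart\| < `D_min` and \|Δend\| < `D_min` | 10 bp | distance == `D_min` does not link |
| split-read floor | drop merged circles with split reads < `JT_min` | 2 | count == floor survives |

Thresholds are applied strictly as stated ("greater than", "smaller than",
"less than"), which fixes the boundary behaviour exhaustively exercised by
the worked toy fixture.

Merging is **junction-level**, not interval-overlap: two calls merge only
when *both* endpoints nearly coincide. Overlap-based merging would collapse
distinct circles that happen to share one breakpoint. Clusters are the
connected components of the linkage relation (transitive closure); the
representative spans (min start, max end) and carries the summed split
reads. The implementation (union-find over a start-sorted sliding window)
is validated against a brute-force all-pairs transitive closure in the test
suite and the acceptance script. A second merge pass can occasionally merge
further when cluster representatives become linkable (chain merging); the
tests flag this case explicitly rather than hiding it, and the pipeline
performs a single pass.

MtDNA content is quantified as the split-read sum over the **raw**
(pre-merge, pre-floor) mitochondrial calls: interval merging collapses
mitochondrial circles into one ~16 kb entry, destroying the copy-number
signal.

## PpGC quantification

- Overlap means **gene body** overlap of at least 1 bp (a circle "carrying
  a fragment of the gene"), not exon overlap.
- A circle overlapping k genes contributes its full split-read count to
  every one of them; no apportioning. This mirrors plain interval
  intersection; any split would be an undescribed refinement. The choice is
  isolated in `compute_ppgc`.
- Genes with zero total across all samples are dropped from the matrix.
- Gene length `L_i` is the annotation body span, not summed exon length.
- `L_Max` is the longest gene **retained in the table** by default ("found
  in the dataset"); an option uses the whole annotation instead. Scaling by
  `L_Max / L_i` never shrinks a value and leaves the longest gene's row
  unchanged.
- Equalization is `log2(x + 1)`, applied after scaling; it maps 0 to 0 and
  stabilises the heavy-tailed split-read sums.

## Differential calling

The log2 fold change is the **difference of equalized group means** — the
values are already on the log2 scale, so no ratio is formed, and the
pseudo-count is inside the transform. The test is the classical two-sided
two-sample Student's t-test with pooled variance (n = 8 per group in the
motivating design; Welch available behind a flag). Selection:
`|log2FC| >= theta` (default 1) and `p <= alpha` (default 0.05), raw
p-values by default with Benjamini–Hochberg optional — the method is a
screening tool and its published usage reports raw p-values.

Degenerate rows (zero variance in both groups) take the t statistic's
limits: p = 0 when the means differ, p = 1 when they agree.

Records are ranked within each direction by (p ascending, |log2FC|
descending, gene id) — the deterministic tie-break makes rank-comparison
tables reproducible. The scaled-vs-unscaled comparison reruns the identical
code path on the unscaled matrix and joins significant genes by id; the
gene-length bias check is an OLS regression of −log10 p on gene length over
the selected genes (constant response is reported as slope 0, R² 0 rather
than an undefined correlation).

The selection rule is implemented as `|Δmean| >= theta`. One published
description words the rule as "less than" the threshold, which contradicts
the accompanying volcano plots and standard practice; this package treats
that wording as an erratum.

## Democratic voting

The vote threshold is the **floor of the mode** of the group's pooled
equalized PpGC distribution, estimated by a fixed-width histogram
(default bin 0.5 on the log2 scale) smoothed with a centered 3-bin moving
average. Two deliberate details:

- **Zeros are excluded** from the pooled values: the matrix is
  zero-inflated and a zero mode would pin the threshold at 0, making every
  vote trivially positive.
- Smoothing a narrow peak produces tied bins; ties are resolved by the raw
  bin count, then leftmost. This keeps the estimator on the loaded bin
  (a point mass at 6.3 yields threshold 6, not 5) while equal genuine modes
  resolve to the lower one.

The distribution is taken on the scaled, equalized values: a threshold of
~6 is plausible on the log2 scale (2^6 = 64 split-read equivalents) and
implausibly low on the raw scale. A sample votes for a gene at value >=
threshold (inclusive, matching the "at least" phrasing of the quorum);
the quorum is 4 votes by default. Both are configurable, as is a manual
threshold override in the CLI.

## Whole-gene detection

Containment is inclusive at both ends on the half-open convention: a circle
with exactly the gene's coordinates carries the full gene. Containment must
be achieved by a **single** (merged) circle, not by a patchwork of
fragments. The Boolean presence matrix uses 1 = present. Genes are reported
when contained in at least 2 samples by default.

## Synthetic data generator

`generate_dataset` emulates the *structure* of a purified-eccDNA two-group
study, with defaults matching the motivating design where one exists:

| parameter | default | rationale |
|---|---|---|
| samples per group | 8 | the study design the method targets |
| genes | 200 over 8 chromosomes | desk-scale; enough rows for stable group statistics |
| gene length | uniform 1–20 kb | typical annotation span at this scale |
| circles per gene per sample | Poisson(2) | a few observations per gene, like sparse real matrices |
| split reads | shifted geometric (p = 0.5, min 1) | heavy-tailed positive counts; no published distribution exists |
| circle lengths | peaks at 160/320/480 bp (sd 15) + exponential tail (scale 2 kb) | nucleosome-repeat periodicity plus long circles |
| group effects | multiplicative rate spikes | "production" is a rate; effects scale it |
| mito calls | Poisson(5) per sample | nonzero MtDNA accounting |
| near-duplicates | 10% of circles, jitter < 10 bp | exercises junction merging |

Circle starts sit on a 50 bp grid inside each gene, sampled without
replacement, so distinct generated circles are never linkable at the
default merge distance — only the deliberate jittered duplicates merge, and
ground truth stays exact under merging. A drawn length exceeding the gene
length becomes a whole-gene carrier (small pads into the intergenic gap),
recorded in the ground truth.

What the generator does **not** emulate: sequencing depth and library-prep
variation between samples, PCR amplification bias, chromosomal hotspots,
overlapping genes, and annotation errors. Passing the recovery tests
therefore shows the pipeline's bookkeeping and statistics are correct under
the declared model, not that real Circle-Seq libraries meet that model.

The worked toy dataset is hand-written (8 genes, 2×4 samples, ~45 calls)
with every stage's expected output computed by hand and frozen in the test
suite; its sample S1 packs all the filter/merge boundary cases.

## Problem sizes and numerical choices

The test suite and acceptance script use 200-instance oracle sweeps
(≤ 100 calls each), 1000–2000 gene matrices for t-test exactness and null
calibration, 5000 pooled values for mode detection, and the 200-gene
simulated study; together they complete in well under a minute on one core
while keeping every check statistically meaningful at its stated tolerance
(binomial 99% band for calibration, 1e-10 for t-test agreement).

Seeds: every stochastic component takes an explicit seed;
`scripts/acceptance.py` derives independent per-component seeds from the
single `--seed` via `numpy.random.SeedSequence`.

## Known limitations

- Per-gene attribution double-counts circles spanning several genes; rank
  comparisons between overlapping genes are therefore not independent.
- The t-test is applied to log-transformed sums with n = 8 per group;
  heavy zero-inflation in a gene row degrades its calibration (the null
  calibration check uses well-behaved rows on purpose).
- The democratic threshold depends on histogram bin width where the mode
  region is flat; the bin width is exposed rather than hidden.
- Chain merging means junction merging is not guaranteed idempotent;
  a single pass is the defined behaviour.
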