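# Methods

This note documents the models, conventions and numerical choices behind
`craniopipe`, and what the synthetic-data tests do and do not demonstrate
about real array data.

## Synthetic probe-level data

The generator emulates a four-arm osteoblast expression study. The sample
table reproduces the study layout by default: group sizes 50 (control),
100 (sagittal), 50 (coronal), 49 (metopic); integer ages drawn uniformly
within each group's published range (control 1–120 months, coronal 4–24,
metopic 3–19, sagittal 2–28); sex Bernoulli at each group's published male
fraction (0.70 / 0.77 / 0.36 / 0.73); batches assigned round-robin. Ages
are drawn from the ranges rather than matched to the published group
means: the ranges are hard constraints, the means emerge. The number of
processing batches is not published; the default of 8 is a realistic
count of processing dates for 249 arrays and is configurable.

For gene *g* and sample *s* the latent signal is

    z_gs = baseline + lfc(group(s)) + beta_age*age + beta_sex*sex
           + batch_effect(batch(s)) + N(0, sample_sd^2)

and probe *p* observes

    y_pgs = z_gs * sqrt(coherence) * a_p + N(0, noise_sd^2) * sqrt(1 - coherence)

with per-probe affinities a_p ~ N(1, 0.2²) fixed per gene, emulating
probe-specific hybridization efficiency that summarization must absorb.

Parameter defaults, with rationale:

| parameter | default | meaning |
|---|---|---|
| beta_age | 0.002 log2/month | age confounder, detectable but not dominant |
| beta_sex | 0.1 log2 | sex confounder |
| batch_sd | 0.3 log2 | between-batch scatter |
| noise_sd | 0.5 log2 | probe-level measurement noise |
| sample_sd | 0.5 log2 | biological sample-to-sample scatter of z |
| baseline | 7.0 log2 | typical expressed-gene intensity |
| n_probes | uniform 4–26 | plausible probe-set sizes for whole-transcript arrays |
| coherence (planted genes) | 0.95 | a well-measured probe set |

`sample_sd` defaults to `noise_sd` so that the coherence parameter is
interpretable as the approximate share of probe variance carried by the
shared signal. Because affinities enter multiplicatively, a median-polish
estimate of a planted log2 fold change is attenuated by roughly
`median(a_p) * sqrt(coherence)` — under 3% at coherence 0.95 — which the
parameter-recovery tolerances accommodate; exact-recovery unit tests use
coherence 1 with unit affinities, the noiseless limit.

What the generator does **not** emulate: raw (pre-log) intensity scale,
optical background, spatial artifacts, probe GC effects, correlated genes
(co-expression modules), or outlier arrays. Passing tests therefore
demonstrate correctness of the statistical machinery under the assumed
additive log2 model, not robustness to vendor-level artifacts — those are
the province of array QC upstream of this pipeline.

## Normalization and summarization

Quantile normalization maps every sample onto the row-wise mean of the
sorted columns; ties receive the mean of the reference values at their
tied rank positions (average-rank dialect), making the transform
deterministic. It is exactly idempotent on tie-free data and approximately
so with ties. Background correction of raw intensities is out of scope:
inputs are assumed log2 already.

Probe sets are summarized by Tukey median polish on the additive model
`value ~ overall + probe + sample`, sweeping rows first, midpoint medians
for even counts, convergence when the summed absolute residual changes by
< 1e-6 (relative) with at most 20 sweeps, reported value = overall +
sample effect. Blocks of equal size are polished as one vectorized stack;
each block is frozen at its own convergence point, so batched results are
bit-identical to polishing each gene alone. `summarize_probe_subset`
reruns the polish on a probe subset (e.g. 5' vs 3' probes) to test whether
subsets disagree on differential expression — the signature of
cross-hybridization with a paralogous transcript.

## GIC and the permutation cutoff

GIC = s₁²/Σsᵢ² from the SVD of the row-centered probe block. Conventions
the source analyses leave open, fixed here:

- **Centering**: per-probe mean centering before the SVD. Variance
  explained is only meaningful on centered data; otherwise probe affinity
  offsets dominate s₁.
- **Input**: GIC consumes the quantile-normalized probe matrix, before
  probe-set summarization (summarization would erase the probe-level
  structure the statistic measures).
- **Null**: each permutation reshuffles the probe → probe-set assignment
  uniformly while preserving every set's probe count, because GIC depends
  strongly on block size; scores from all permutations are pooled into a
  single null and the cutoff is its 99th percentile. A single pooled
  cutoff (rather than per-size nulls) matches the one-number cutoff the
  analysis design describes; per-size calibration can be obtained by
  filtering the stored null scores.
- **Percentile rule**: linear interpolation between order statistics,
  applied identically to observed and permuted scores.
- **Degenerate cases**: an all-constant block has zero total variance and
  scores 0.0, flagged; single-probe genes score 1.0 by construction and
  are excluded from top-K selection by default since their coherence is
  vacuous (configurable).
- **Selection**: genes at or below the cutoff are removed (strictly
  greater passes), survivors ranked by GIC descending with ties broken by
  gene id, top K = 2000 kept by default.

On iid Gaussian probe data the observed pass rate at the cutoff is ~1% by
construction; the acceptance suite verifies 1% ± 0.5% over 20 replicates
(1000 genes × 100 samples, 200 permutations per replicate — permutations
scaled down from the 1000 default to keep the suite fast; the cutoff is
insensitive to this because scores are pooled across permutations).

## Differential expression

Per gene: OLS of log2 expression on intercept, group indicators (control
reference), age in months, sex (0 = female, 1 = male). Batch handling:

- `gls` (default): consensus intra-batch correlation estimated by pooling
  per-gene one-way-ANOVA intraclass correlations of the no-batch OLS
  residuals on the Fisher-z scale (a moment analogue of
  duplicateCorrelation), clipped to [0, 0.95]; each gene then fit by GLS
  under the block-equicorrelated covariance via a symmetric whitening
  transform.
- `fixed`: batch indicator columns. The two modes agree closely on
  balanced designs (tested); `fixed` spends B−1 residual df, `gls` none.

The all-cases-vs-control contrast pools the three case groups into one
indicator in a separate fit; case-vs-case contrasts are coefficient
differences, so lfc(A,B) = −lfc(B,A) exactly. Rank-deficient designs
raise an error naming the collinear columns.

Variance moderation follows the limma moment-matching algorithm on
log s² (digamma/trigamma inversion by Newton iteration); one test checks
agreement with `limma::squeezeVar` to 4 decimals. Degenerate branch: when
the spread of log s² does not exceed its χ² sampling noise, d₀ = +∞ and
s₀² is set to the mean variance so the posterior equals the common
variance exactly. Moderated t = lfc / (se·s̃), df = residual df + d₀;
two-sided p; BH step-up across genes per contrast (statsmodels
implementation, hand-checked oracle in tests).

Reporting: percent change = sign(lfc)·(2^|lfc|−1)·100, rounded half away
from zero for display (the unrounded value is kept and used for
thresholding). The "significant" flag applies the 0.05 threshold to the
**raw** moderated p-value, not the BH-adjusted one — with ~37% of
selected genes significant, the published ratio is only consistent with a
raw-p threshold — and is switchable to adjusted p. "Large" means
|% change| strictly greater than 50; p must be strictly below 0.05.

## Set logic, clustering, enrichment

Venn regions: m1 = C∩M∩S, m2 = (C∩M)∖S, m3 = (C∩S)∖M, m4 = (M∩S)∖C,
m5/m6/m7 the unique remainders. m2 is pinned to the coronal–metopic pair;
m3/m4 follow in contrast-name order (the labeling of those two is
otherwise arbitrary). The partition is exact: region sizes sum to
|C∪M∪S| and each contrast's total is the sum of its four covering
regions.

Clustering: genes z-scored, distance 1 − Pearson correlation, average
linkage (both configurable; the standard heatmap recipe). Zero-variance
rows are dropped with a warning since correlation distance is undefined
for them. Leaf order is made deterministic — smaller subtree first, ties
by lexicographically smallest member id — so reruns are byte-identical.

Enrichment: one-sided Fisher exact test per set, computed as the
hypergeometric upper tail on (overlap, query, set, universe); `ease` mode
subtracts one from the overlap cell (EASE score), which is always ≥ the
Fisher p. The universe defaults to all genes on the platform under
analysis. Sets are size-filtered after intersection with the universe;
query genes outside the universe are dropped with a warning.

## Problem sizes in the test suite

The statistical acceptance tests run at deliberately chosen scales: 20
replicates wherever a rate or a mean is asserted; 1000 genes × 100
samples with 200 permutations for null calibration; 2000 genes for
type-I-error checks; n = 50 vs 50 with noise_sd 0.5 for planted-effect
recovery (planted values 0.89, 1.17, −1.04 — effect sizes taken from the
range the pipeline is meant to detect). These sizes make the binomial /
sampling error of each asserted quantity several times smaller than its
tolerance.

## Known limitations

- The GLS batch mode estimates a single consensus correlation; genes with
  atypical batch sensitivity are mildly mis-weighted (as with any
  duplicateCorrelation-style approach).
- Median polish has no closed-form standard error; probe-level uncertainty
  is not propagated into the gene-level model beyond the residual
  variance.
- The permutation null assumes exchangeability of probes across probe
  sets after quantile normalization; strong probe-sequence effects shared
  within real probe sets could make it slightly liberal.
- Enrichment treats genes as exchangeable units; no correction for
  probe-set size or expression-level bias is applied.
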