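# Methods

## Signal model

A sample's cfDNA is a mixture of maternal and placental (fetal)
fragments. On a fixed grid of 20 kb bins, the expected read count of
mappable bin *b* for a sample with *R* total reads is

    mu_b = R · w_b / Σ w,     w_b = g(GC_b) · exp(Σ_k s_k L_kb) · c_b

with `g` a smooth GC bias curve, `L` low-rank batch loadings with
per-sample scores `s`, and `c_b` the copy ratio

    c_b = (1 − ff) · maternal_copies/2 + ff · fetal_copies/2.

A maternal heterozygous gain/loss therefore shifts the diploid ratio by
±0.5 (the model assumes the fetus co-inherits the maternal allele, so
the shift is independent of fetal fraction `ff`), while a fetal-only
het event shifts it by ±ff/2 — at most ±0.125 at ff = 0.25. This
asymmetry is the entire basis of the maternal designation rule.

## Synthetic cohort generator

The generator exists so every downstream stage can be scored against a
known truth set. Its defaults are the study conditions of the assay it
emulates:

| parameter | default | meaning |
|---|---|---|
| `bin_size` | 20,000 bp | counting grid |
| `reads_range` | 5–20 M | reads per sample at genome scale (0.12–0.5×) |
| `fetal_fraction` | N(0.10, 0.04), clipped to [0.01, 0.30] | mixture proportion |
| `gc_bias_strength` / `peak` | 8.0 / 0.42 | log-quadratic bias, unimodal near GC 0.42 |
| `batch_rank` / `batch_scale` | 2 / 0.08 | low-rank artifact components, per-component log-score SD |
| `dispersion` | 0.01 | NB overdispersion: var = μ + d·μ² (Poisson as d→0) |

Counts are negative-binomial (gamma–Poisson); a multinomial mode
partitions `R` exactly when strict conservation is wanted. Carriers
are independent Bernoulli draws per variant (Hardy–Weinberg
homozygotes are ignored — at sub-percent frequencies they are
vanishingly rare). Twin pregnancies and mosaicism are not modelled.

Batch loadings are white noise smoothed with a 5-bin (100 kb) window
and normalized to unit RMS. The short coherence length is deliberate:
flow-cell/library artifacts are correlated over a few bins, not over
megabases — megabase-coherent multiplicative artifacts at this
amplitude would be indistinguishable from real CNVs (especially on
chrX, which PCA never touches) and would make any read-depth CNV assay
unusable.

The **toy genome** (4 autosomes + X, 30–40 Mb each, 165 Mb, 8,250
bins, 2 Mb centromere masks) keeps per-chromosome bin counts
(1,400–1,900) in the regime where segmentation behaves as it does
genome-wide while full-cohort runs finish in minutes. On it, ~0.25×
coverage corresponds to 380–520 k reads per sample (the same ~55 reads
per bin that 5–20 M reads give at genome scale). Real hg19 chromosome
sizes are available for genome-scale runs.

## Normalization

LOESS first, PCA second — GC bias is a per-sample chemistry effect and
must be removed before cross-sample structure is estimated.

* **LOESS**: statsmodels `lowess` (tricube weights, locally linear),
  span 0.3, two robustness iterations (so CNV bins do not drag the GC
  fit), fitted on autosomal mappable bins and evaluated everywhere by
  interpolation; fitted values are floored at 5% of their median to
  keep ratios finite. Ratios are scaled to autosomal median exactly 1.
* **Reference panel**: the (samples × autosomal bins) ratio matrix is
  column-mean-centered, each centered row's mean is removed (the
  overall depth scale belongs to median normalization, so components
  carry shape only), and the top-k right singular vectors are kept
  (k = 3 by default; component signs fixed by making the
  largest-magnitude coordinate positive). Numerically null directions
  are dropped with a warning.
* **Denoising**: the projection of (ratio − panel mean) onto the
  components is subtracted; re-centering then *subtracts*
  (median − 1) rather than dividing by the median. With DC-free
  components this makes the whole operation exactly idempotent —
  applying it twice is a machine-precision no-op — which a
  multiplicative rescale would break at the ~1e-6 level. Ratios are
  clipped at 0 (they are physical).
* **Leave-one-out panels** are the default when the analyzed sample
  belongs to the cohort: projecting a sample onto components fitted
  *with* that sample demonstrably erases part of its own CNV signal.
* **Noise scale**: 1.4826 × MAD of autosomal ratios — a robust SD that
  CNV outlier bins cannot inflate.
* **X chromosome**: excluded from panel fitting and projection (the
  subjects are pregnant women; X is expected diploid, but its
  cross-sample structure differs from autosomes). X bins receive the
  median re-centering only.

Signal preservation has a geometric limit worth knowing: the panel
attenuates an injected CNV in proportion to how strongly the variant
direction competes with the noise floor of the SVD, which scales as
(carrier rows in panel)/√(number of bins). At genome scale this is
negligible for sub-percent variants; on very small genomes (~1,500
bins) a variant carried by ≥4–5 panel samples is visibly absorbed.
Tests therefore check the preservation invariant on the full toy
genome at ≤5% carrier frequency.

## Segmentation

Circular binary segmentation: on the current segment (length n ≥ 4),
every arc (i, j] is scored with

    Z_ij = (mean_in − mean_out) / (s · √(1/k + 1/(n−k))),

s² the pooled within-group variance with n−2 degrees of freedom.
Complementary arcs have equal |Z| on a circle, so the search runs over
linear sub-intervals; an interior arc yields two breakpoints, an arc
touching an edge yields one. Significance is assessed by permutation:
p = fraction of `n_perm` shuffles whose maximal statistic reaches the
observed one; if p ≤ α the segment splits and recursion continues.
Defaults α = 0.01, n_perm = 1,000, min_width = 2 (the permutation
convention of the classical implementation of this algorithm family);
no undo/pruning pass is applied. A constant segment defines T = 0 (no
split); an arc with zero within-variance on a non-constant segment
scores +∞.

Implementation notes:

* Maximizing |Z| is equivalent to maximizing the between-group sum of
  squares V = U²/(k(n−k)) with U the mean-centered arc sum, because
  Z² = nV(n−2)/(W − nV) and the total sum of squares W is invariant
  under permutation. The kernel therefore scans arcs with ~3 flops
  each (numba-compiled), and a permutation "exceeds" iff any arc
  reaches the observed V — allowing early exit per shuffle.
* The permutation loop stops as soon as the exceedance count already
  guarantees p > α; the split decision is provably identical to the
  full run.
* Ties: an edge arc (0, b) and its complement (b, n) always tie
  exactly; forcing the centered prefix sum's last element to its exact
  value 0 makes the tie bitwise, and the first arc in (i, j)
  lexicographic order wins — matching the brute-force oracle.
* Determinism: the recursion consumes one RNG stream left-to-right;
  identical inputs and seed give identical breakpoints.

The segment z-score `z = (mean_ratio − 1)·√n_bins / noise_sd` is the
display statistic: how many noise units the segment mean sits away
from diploid, credited √n for averaging.

## Maternal calling

A segment becomes a call iff span ≥ 200,000 bp AND
|mean_ratio − 1|/0.5 > 0.75 (i.e. ratio ≤ 0.625 or ≥ 1.375). The
deviation threshold is read as a fraction of the heterozygous
single-copy shift: the only interpretation under which maternal het
events (deviation ≈ 1.0) pass while fetal events (deviation ≈ ff)
fail. The length test is inclusive at exactly 200 kb — the reference
frequency table contains 200 kb variants. Calls are never merged
across segments and are bin-aligned by construction. No genome-wide
multiple-testing correction is applied to calls; the thresholding is
deterministic post-segmentation.

## Cohort statistics

* **Clustering**: same-chromosome, same-type calls link when
  reciprocal overlap ≥ 0.75; connected components are variants.
  Exact-coordinate identity would shatter clusters under ±1-bin
  breakpoint jitter, while 0.75 keeps a 1.6 Mb deletion and a 480 kb
  duplication of the same region distinct, as a frequency table should.
  The representative interval is the modal exact interval (ties:
  leftmost, then shortest); occurrences count distinct samples;
  components seen ≥ 2 times are MOVs. Gains and losses never merge.
* **Database contrast**: databases publish frequencies, not counts, so
  the carrier count is reconstructed as round(freq% · N_db); the 2×2
  table is tested with Pearson chi-squared, 1 df, no Yates correction.
  Tables with a zero margin are flagged degenerate instead of tested.
* **Density outliers**: variants per megabase of *effective*
  (mappable) chromosome length; mean and **sample (n−1)** SD across
  chromosomes; lower-tail normal p per chromosome, flagged at
  p < 0.05. The n−1 choice and the lower tail are validated by
  reproducing the reference table's printed p-values to six decimals
  (the population-SD variant does not reproduce them). A chromosome in
  the *upper* tail (chrX, p ≈ 0.9989) is deliberately not flagged; a
  two-sided option exists but is off by default.

## Validation experiments

`matcnv.validation` packages the two standing experiments:

* **Recovery** (default 100 samples, toy genome, ~0.25×): 40 maternal
  het CNVs of 300–500 kb at catalog frequencies 1%/0.5% plus 3
  fetal-only gains at 20% frequency. An event counts as detected when
  matching-type calls cover ≥ 50% of its interval (union coverage —
  CBS may legitimately split one event into adjacent sub-segments); a
  call is a false positive when < 50% of its length is covered by
  matching truth. Recovered per-variant carrier counts are compared
  with central 95% binomial intervals: with 40 simultaneous intervals
  the correct expectation is ~95% coverage, so the check requires
  ≥ 90% of variants inside plus both frequency-group pooled counts
  inside their group intervals.
* **Normalization efficacy** (default 80 samples): mean |corr(ratio,
  GC)| after LOESS; reduction of median cross-sample per-bin variance
  after PCA; mean ratio inside an injected 1.5× gain at 5% frequency
  (redrawn deterministically at seed+1 if a draw has no carrier).

What passing these shows — and does not. The generator reproduces the
depth, GC bias, overdispersion, batch structure and mixture physics of
the real assay, so the experiments validate the *algorithms* under
realistic noise. They do not exercise real-genome features the
generator omits: segmental-duplication–mediated recurrent breakpoints,
mappability structure beyond interval masks, sequencing-error and
alignment artifacts, mosaicism, or maternal malignancy signatures.
Headline counts of any real cohort (how many distinct CNVs, how many
MOVs) are data-dependent and are not reproduced here.

## Numerical and degenerate-input choices

* Constant GC track → LOESS skipped with a warning, median scaling
  only. All-zero samples rejected.
* Rank-deficient panels reduce k with a warning; k = 0 keeps the mean
  only.
* Segments shorter than max(4, 2·min_width) bins are terminal —
  a signal, not an error.
* `s = 0` (constant segment) → T = 0, no split.
* Density test with zero across-chromosome variance → all p = 0.5,
  warning, nothing flagged.
* Chromosome grids keep a trailing partial bin but always flag it
  unmappable, so every analyzed bin has identical width.
* All display coordinates are the 0-based half-open bin-grid
  coordinates with thousands separators (end − start equals the
  variant size), matching how screening reports print loci.

## Problem sizes

Test and acceptance runs use the toy genome: recovery at 100 samples
(tests) / 60 samples (acceptance script), normalization efficacy at 80
samples, type-I calibration over 500 (tests) / 300 (script) flat-noise
segments of 100 bins, and oracle agreement over 1,000 (tests) / 300
(script) random arrays of length ≤ 30. These sizes were chosen so the
full suite runs on a laptop-class single CPU in minutes while keeping
every Monte-Carlo check adequately powered.
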