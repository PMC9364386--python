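# Methods

## The problem

Between-array quantile normalization forces every sample's intensity
distribution onto one shared reference. That is justified when all samples
measure the same underlying distribution — true for autosomes, false for sex
chromosomes in a mixed-sex cohort. X inactivation leaves female X CpGs at
intermediate methylation (one largely methylated inactive copy averaged with
one active copy), while the single male X stays bimodal at half the DNA input;
Y probes carry signal only in males. Pooling these probes with autosomes makes
the per-sample quantile map sex-dependent, which leaks a systematic,
sex-directional shift into *autosomal* corrected values: spurious
sex-associated positions (saDMPs) and an inflated sex-explained variance
fraction on autosomes.

## The two-step normalizer

`adjusted_normalize` implements the interpolatedXY strategy:

1. **Autosomes only.** The base normalizer (dasen-style: per-sample additive
   alignment of the Type I intensity distribution onto Type II, then quantile
   normalization of methylated and unmethylated channels separately within
   each Infinium design type) runs on autosomal probes alone.
2. **Sex probes by rank interpolation.** Within each (channel x design type)
   stratum and each sample independently: autosomal raw values are ranked
   (average ranks for ties); each sex-probe raw value receives a fractional
   rank by piecewise-linear interpolation between the bracketing autosomal
   values; the corrected value is read off the sorted corrected autosomal
   vector at that fractional rank (`F(rank)`, linear between adjacent order
   statistics). Queries outside the observed autosomal range clamp to the
   extreme ranks rather than extrapolate, so corrected sex intensities always
   lie inside the corrected autosomal range.

Betas are recomputed from corrected intensities as `M / (M + U + offset)`
with the conventional offset 100. Sample sex is never consulted, so the
method needs no (and cannot be biased by) sex annotation. Any callable that
maps a raw per-stratum matrix to a corrected one can replace the built-in
step-one normalizer through the `plugin` seam; `quantile` (no Type I/II
alignment) is built in.

Interpolation runs on intensities, with betas derived afterwards.
`interpolate_sex_betas` offers a beta-space fallback for matrices that lack
channel data; it is non-canonical and flagged as such in its docstring.

## Numerical conventions

* **Quantile normalization.** Reference = per-rank mean of column-sorted
  values over rows complete in all samples. Tied values within a column all
  receive the mean of the reference values across the tied span (computed
  with `np.add.reduceat`, not a cumulative sum, so exact-duplicate inputs
  round-trip bitwise). Columns with missing cells map their non-missing
  values through fractional ranks rescaled to the reference length.
* **Type I/II alignment.** Per-sample offset = difference between the
  lowest-intensity density modes of the two design types. Density is a
  Gaussian-kernel KDE with Silverman's bandwidth evaluated on a 512-point
  grid; the kernel sum is taken over a 4096-bin histogram of the data (bin
  width is far below the bandwidth, and on test data the resulting mode is
  identical to a direct KDE evaluation). The mode is the first local maximum
  above 1% of the peak density *with at least 5% prominence* — the prominence
  guard stops sampling ripples on a shoulder from being read as a background
  mode — and the apex is refined by a parabolic fit through the three grid
  points around the maximum, which removes the dependence of the estimate on
  where the grid happens to start. Fewer than 50 probes of either type is
  refused (density estimate unstable) unless forced. When a chip row is known
  for every sample, per-sample offsets are smoothed by their least-squares
  linear fit against chip row before application.
* **Variance decomposition.** All variances use divisor *n* (population
  form). The sex-explained fraction
  `F_sex = 1 - (n_f V_f + n_m V_m) / ((n_f + n_m) V_total)`, with within-sex
  per-probe means, is then algebraically identical to the between-group
  fraction of a one-way ANOVA and lies in [0, 1]. Probes with fewer than two
  non-missing samples in either sex are dropped from all three terms.
* **Sex EWAS.** Per-probe two-group F-test on (1, n-2) degrees of freedom —
  the same statistic as an OLS fit of beta on a binary sex covariate — with
  Bonferroni correction at alpha = 0.05 and no further covariates.
  Zero-variance probes are skipped and never significant. Direction is the
  sign of mean(female) - mean(male).

## Evaluation protocols

**Single-sex gold standard.** In a cohort of one sex, every sample shares one
karyotype, so sex chromosomes may legitimately join the quantile pool. The
input is split by sex; each single-sex group is normalized twice — once with
sex probes pooled as ordinary autosomes (reference), once with the two-step
method (candidate) — and per-sample RMSE over X- and Y-linked betas is
reported in four categories (female/male x X/Y). Female Y values are
background noise (no Y chromosome present) and their category is reported for
completeness only.

**Bias audit.** On mixed-sex data with no true autosomal sex effect, the
mixed normalizer is compared with the adjusted one via (a) the autosomal
sex-explained variance fraction, which the mixed method inflates, and (b) the
overlap of Bonferroni-significant saDMPs, where mixed-specific hits are
predominantly higher-in-males: pooling shifts autosomal values down in
females (whose X probes crowd the mid quantiles) and up in males.

## The synthetic data generator

`simulate_dataset` emulates exactly the structure the method addresses, with
ground truth retained:

* autosomal betas from a three-component Beta mixture (modes 0.10 / 0.50 /
  0.88, weights 0.44 / 0.12 / 0.44) shared across samples up to logit-normal
  biological jitter (sd 0.1);
* female X betas intermediate (Beta with mean 0.50, concentration 20 — the
  cluster sits at the autosomal median, above roughly half the autosomal
  values, which is what makes the mixed-normalization shift sex-directional);
  male X betas bimodal like autosomes but at 0.5x total intensity (one
  chromosome copy);
* male Y betas bimodal; female Y probes receive only background-scale total
  intensity (5% of the autosomal median) with noisy betas;
* intensities invert the beta formula, `M = beta*T + e`, `U = (1-beta)*T + e`,
  floored at 0, with per-probe log-normal total intensity (median 5000,
  sigma 0.5), per-sample log-normal technical factors per channel (sd 0.15),
  an additive +2000 Type I offset, and Gaussian measurement noise (sd 50);
* probe counts default to 50k autosomal / 1.2k X / 120 Y — the real
  platforms' ~2.4% sex-probe share at desk scale — with 72% Type II;
* optional planted autosomal sex effects (+-delta on female means) for power
  studies. All randomness flows from a single seed.

What the generator does **not** model: dye bias and out-of-band signal,
control probes, cell-type composition, age effects, probe cross-reactivity
and SNP artefacts, or spatial chip effects beyond a scalar chip row. Tests
passing on this generator therefore demonstrate the algorithmic claims
(exactness, monotonicity, bias direction, calibration), not robustness to
every artefact of real arrays.

## Problem sizes used in the shipped checks

The end-to-end checks run at desk scale: the gold standard uses 12 male and
4 female samples at 5k/50k/200k autosomal probes with the 2.4% sex share;
the bias audit uses 100 + 100 samples over 20k autosomal probes and five
seeds; EWAS calibration uses 10k probes at n = 100. At 50k autosomal probes
the interpolation gap (spacing of adjacent order statistics) bounds the
achievable gold-standard RMSE near 1e-4 — denser arrays push it lower, which
the density sweep confirms.

## Known limitations

* The Type I/II alignment is this package's reproducible convention for a
  "background-mode match"; exact numerical parity with the reference dasen
  implementation's regression fit is not claimed.
* With heavy missingness the quantile reference shrinks to the complete rows;
  columns are then mapped through rescaled fractional ranks, a common but not
  unique convention.
* `F_sex` exactness holds for complete data; with per-probe missingness the
  group weights use global sample counts while per-probe variances use
  per-probe counts, so the identity is approximate.
* The EWAS assumes equal within-group variances (pooled residual); with
  strongly heteroskedastic groups a Welch-type test would differ.
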