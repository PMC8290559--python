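# Methods

## Scope and model

`mrexposome` implements an exposome-wide two-sample Mendelian randomization
(MR) screen: many candidate exposures, each instrumented by its genome-wide
significant SNPs, tested against binary longevity outcomes using only GWAS
summary statistics.  The underlying data-generating model for one exposure
is the standard instrumental-variable decomposition

    beta_Y_j = theta * gamma_j + alpha_j + e_j,        e_j ~ N(0, se_Y_j^2)
    beta_X_j = gamma_j + u_j,                          u_j ~ N(0, se_X_j^2)

where `gamma_j` is SNP *j*'s effect on the exposure, `theta` the causal
effect of one exposure SD on the log odds of the outcome, and `alpha_j`
horizontal pleiotropy (zero for a valid instrument).  All estimators consume
harmonized per-SNP pairs `(beta_X_j, se_X_j, beta_Y_j, se_Y_j)`.

## Pipeline stages

**Instrument selection.** Candidate instruments satisfy p < 5e-8 and
MAF > 0.01.  LD pruning is greedy clumping at pairwise r^2 < 0.001 against a
user-supplied LD matrix: repeatedly keep the most significant remaining SNP
(p-value ties broken by lexicographically smaller identifier, for
determinism) and discard SNPs correlated with it.  With no LD matrix the
instruments are assumed independent and a warning is logged.  Exposures are
eligible when they have >= 3 independent instruments and (if categorical)
>= 250 cases; duplicate trait identifiers after the first are excluded.

**Instrument strength and power.** Variance explained is
R^2 = sum_j 2 p_j (1 - p_j) beta_j^2 (per-SD betas on a standardized
trait).  Instrument strength is F = ((n - k - 1)/k) * (R^2/(1 - R^2)),
strong when F > 10; the joint F is primary and a mean per-SNP F is also
reported because either convention appears in applied work.  Power for a
binary outcome uses the normal-approximation closed form
`Phi(sqrt(n r^2 mu(1-mu)) |log OR| - z_{1-alpha/2})` with `mu` the outcome
case fraction; at OR = 1 it degenerates to alpha/2 (one rejection tail).

**Harmonization.** Outcome rows are aligned to the exposure's effect
allele: direct match, allele swap (negate beta, complement frequency), or
strand flip, in that order of interpretation.  Palindromic SNPs (A/T, C/G)
are resolved by allele frequency: dropped when the exposure MAF exceeds
0.42 (the frequencies are then too close to 0.5 to trust), otherwise
oriented so both datasets' frequencies fall on the same side of 0.5, with a
concordance guard |eaf_x - eaf_y| < 0.2 (configurable) against population
mismatch.  The 0.42 cut-off is applied to the exposure because instruments
originate there; palindromes lacking either frequency are dropped.  Every
candidate instrument receives exactly one logged action.

**Binary-linear exposures.** Case/control traits analysed with a linear
model are rescaled to log odds ratios before estimation:
`log OR = beta / (mu (1 - mu))`, standard errors divided by the same
factor, so z-scores and p-values are untouched.

**Estimators.**

- *IVW*: weighted regression of beta_Y on beta_X through the origin,
  weights 1/se_Y^2.  Reported under multiplicative random effects: the
  fixed-effect SE is scaled by sqrt(Q/(J-1)) when Cochran's Q exceeds its
  J-1 degrees of freedom and never deflated below the fixed-effect SE;
  normal p-value.  This is the default behaviour of the widely used
  TwoSampleMR implementation and is deliberately conservative under
  heterogeneity.
- *MR-Egger*: SNPs oriented so beta_X >= 0, then weighted regression with
  an intercept.  The slope is the causal estimate; the intercept estimates
  average directional pleiotropy.  SEs are scaled by max(1, residual SD);
  p-values are two-sided t on J-2 df.
- *Weighted median*: per-SNP Wald ratios theta_j = beta_Y_j/beta_X_j sorted
  ascending; the estimate interpolates theta against cumulative-weight
  midpoints at probability 0.5.  The SE is the SD of the estimate over a
  parametric bootstrap (default 1,000 replicates, explicit seed required)
  drawing beta_X* ~ N(beta_X, se_X), beta_Y* ~ N(beta_Y, se_Y).  An
  analytic SE would also be defensible; the bootstrap was chosen because it
  needs no density estimate at the median.
- *MR-PRESSO*: residuals are computed against leave-one-out IVW fits
  (r_j = (beta_Y_j - theta_loo_j beta_X_j)/se_Y_j, standardized for scale
  invariance), RSS_obs = sum r_j^2.  Each of n_sim (default 1,000)
  parametric replicates redraws both betas under the no-pleiotropy model
  and recomputes RSS the same way; empirical p-values use the add-one rule
  (never below 1/(n_sim+1)).  Per-SNP p-values are Bonferroni-adjusted by
  J; SNPs with adjusted p < 0.05 are outliers and an outlier-corrected IVW
  estimate is reported on the retained set.  Each SNP draws from a private
  substream keyed by its identifier, making results independent of SNP
  order.  No distortion test is computed; corrected and raw estimates are
  both emitted for descriptive comparison.
- *Multivariable MR* (validation stage, correlated exposures such as lipid
  fractions): joint weighted no-intercept regression of beta_Y on the J x K
  exposure-beta matrix; conditional per-exposure estimates, t p-values on
  J-K df, rank-deficiency rejected.

All ratio-based weights use the first-order delta SE (se_Y/|beta_X|),
ignoring se_X, matching conventional IVW weighting.  CIs are
point +/- 1.96 SE on the log scale, exponentiated to OR for reporting.

**Screening and tiers.** Within each outcome, Benjamini-Hochberg FDR is
applied to the IVW p-values of all eligible exposures (the two outcomes are
corrected separately, mirroring the separate primary and secondary exposure
families; joint correction would be a one-line change).  Tier
"significant" means q < 0.05; "suggestive" means raw p < 0.05 without
surviving FDR; otherwise "null".  Concordance is sign agreement of point
estimates across IVW and available sensitivity analyses (weighted median,
Egger slope), with the PRESSO-corrected estimate replacing raw IVW when
outliers were removed; an exact zero is discordant.  "Consistent point
estimates" has no canonical metric; sign agreement is the weakest defensible
reading and is documented as such.

**Validation merge.** An exposure is a component of the longevity exposome
when it is significant/suggestive for both outcomes with concordant
estimates, or when its validation-stage result is significant.  A
validation null with power >= 0.8 excludes it outright (the
high-power-null override takes precedence over screen support, matching how
a well-powered independent replication failure should be treated).
Otherwise the screen verdict stands, flagged "unvalidated" — absence of
validation data is not treated as disconfirmation.

## Synthetic-data generator

The generator makes the model above generative so the screen can be scored
against known truth.  Defaults emulate the screening study's scale
parameters:

| parameter | default | meaning |
| --- | --- | --- |
| `sigma_gamma` | 0.05 | SD of instrument effects (per exposure SD) |
| `se_x` | 0.004 | exposure per-SNP SE (n ~ 361k GWAS) |
| `se_y` (primary) | 0.01 | outcome per-SNP SE (11,262 cases + 25,483 controls) |
| `se_y` (secondary) | 0.018 | larger SE for the 3,484-case outcome |
| `j_snps` | 30 | instruments per exposure |
| `e_exposures` | 200 | exposome size (scaled down from 4,587) |
| `causal_fraction` | 0.1 | fraction of exposures with a real effect |
| `effect_size` | 0.35 | causal |log OR| per exposure SD, random sign |

Instrument effects are half-normal (oriented to the exposure-increasing
allele, the usual convention in MR simulation studies — with symmetric
signs, "directional" pleiotropy would cancel across SNPs and bias nothing)
and truncated at |gamma| > 2 se_x so selected instruments clear genome-wide
significance without modelling winner's curse.  Effect-allele frequencies
are Uniform(0.05, 0.95); default allele pairs are non-palindromic so the
generator's instruments all harmonize (palindrome handling is exercised
with explicitly constructed variants).  Pleiotropy regimes: balanced
(`sigma_alpha` > 0, `mu_alpha` = 0), directional (`mu_alpha` != 0),
InSIDE-violating (`alpha` correlated 0.7 with `gamma`), and planted per-SNP
outliers with stated magnitudes.  A quarter of exposome traits are stored
on the raw linear-binary scale (case fraction Uniform(0.1, 0.5)) to
exercise the log-OR conversion end to end.  A master seed spawns one
substream per exposure, so any exposure regenerates in isolation.

What the generator does **not** emulate: LD between instruments (identity
by default; a block-LD helper exists to test clumping), winner's curse in
instrument selection, sample overlap between exposure and outcome GWAS,
allele-frequency differences between cohorts, MAF-dependent standard
errors, and real trait correlation structure across exposures.  Passing
tests therefore demonstrate correctness of the estimators and the decision
logic under the assumed model, not robustness to those real-data
complications.

## Numerical and design choices

- p-values of exactly 0 on input are clipped to 1e-300; indels,
  multi-allelic and non-ACGT rows are dropped at read time (strand logic is
  defined only for single bases); duplicate outcome rows keep the smallest
  SE.  Instrument matching is by variant identifier; positions are
  informational.
- Tables are tab-separated with 17-significant-digit floats, so write/read
  round-trips are bit-exact.
- Weighted-median interpolation clamps at the extreme ratios when the
  probability 0.5 falls outside the midpoint range (degenerate only for
  J <= 2, which is rejected anyway).
- Empirical p-values use the add-one rule; Bonferroni adjustment caps at 1.
- Egger requires variation in oriented beta_X (collinearity error
  otherwise); MVMR requires J > K and full column rank.
- The R^2 formula assumes per-SD betas; for binary-linear exposures it is
  computed on the stored scale and is approximate — diagnostics only, it
  feeds no decision other than the reported F and power.
- Validation power is computed at a configurable hypothesized OR (default
  0.8) with the outcome's case fraction taken from its n_cases/n_total.

## Experiment sizes used by tests and the acceptance script

Simulation-backed checks use: 500 replicates for IVW bias/coverage
(theta = log 0.7, J = 30), 1,000 for Egger intercept type-I error under
balanced pleiotropy, 200 for weighted-median robustness (12 of 30
instruments invalid), 40 seeded replicates for PRESSO outlier detection
(n_sim = 1,000) plus 500 null replicates at n_sim = 500, 1,000 random
p-vectors against the brute-force FDR oracle, and 200-exposure exposomes
(5 seeds for the null-calibration check).  The weighted-median robustness
experiment uses the strong-instrument regime (`sigma_gamma` = 0.1,
pleiotropy 0.1 on the invalid instruments): with weak instruments the
per-SNP ratio noise (se_y/beta_x ~ 0.2) biases the median itself and the
comparison degenerates into a coin flip between two poor estimators rather
than a test of median robustness.

## Known limitations

- No proxy-SNP lookup for instruments missing in the outcome, no
  Steiger/reverse-causation filtering, no mode-based estimators, no SIMEX
  or I^2_GX weak-instrument correction for Egger, no PRESSO distortion
  test, and no reference-panel LD computation from genotypes.
- The PRESSO-corrected estimate is emitted whenever outliers are found,
  even alongside a non-significant global test; the combination is flagged
  rather than suppressed.
- Ordinal exposures analysed as continuous are treated as generic per-SD
  effects; quantitative interpretation of their estimates is limited.
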