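# Methods

This note documents the statistical procedures, the synthetic cohort that
exercises them, the numerical choices, and what the tests do and do not
establish.

## Latent executive function

The measurement model is a single-factor CFA over five task scores with
factor variance fixed at 1 (so all five loadings are free and reported),
free intercepts, and diagonal residual covariance. The likelihood is the
casewise Gaussian likelihood over each row's observed variables (FIML),
which is consistent under missing-at-random data. Rows are grouped by
missingness pattern and summarized by per-pattern counts, means and
scatter matrices, so one likelihood evaluation costs a fixed number of
small matrix operations regardless of n; cohorts of several hundred
thousand rows fit in well under a second.

Numerical choices:

* Columns are z-scored on their observed cells before fitting, so loadings
  are on the standardized metric.
* Optimizer: L-BFGS-B on (λ, log ψ, μ) with analytic gradients, fixed
  starting values (λ = 0.5, ψ = 0.5, μ = observed means) for determinism,
  and a floor of 1e-4 on ψ (a fit ending on the floor is flagged as a
  Heywood case). Convergence requires the max-norm of the per-observation
  log-likelihood gradient to fall below 1e-6; non-convergence raises an
  error carrying the iteration trace rather than returning a bad model.
* Orientation is applied before fitting: error and time scores are negated
  so "higher EF = better" holds by construction, and a global sign flip
  makes the loading sum positive.

Fit indices use χ²_model = 2(llₛₐₜ − llₘ), where the saturated model is the
unstructured Gaussian estimated by EM under the same missingness and the
baseline is the independence model (whose FIML MLE is the per-variable
observed means/variances). CFI and TLI are clamped to [0, 1]; RMSEA uses
the (n − 1) denominator; SRMR is the RMS of the residuals between the
saturated and implied matrices on the correlation metric (lower triangle
plus diagonal). Factor scores are regression (Thomson) scores with
pattern-specific weights λₒᵀ Σₒₒ⁻¹ (xₒ − μₒ), standardized over scored
rows. One caveat documented deliberately: when the five tasks are truly
independent, a free-loading one-factor model fits the diagonal covariance
essentially perfectly, so incremental indices like CFI are uninformative
rather than "near zero" — the test suite asserts the defensible property
(model χ² within a χ²₅ improvement of the baseline χ²).

## Age residualization and conditional summaries

Ages are integers, so quantile bins are defined by rank cut-points
⌊b·n/nbins⌋ with ties broken by stable input order; the default bin width
is 20% of the cohort. Residuals subtract the participant's own bin mean,
which zeroes within-bin and grand means exactly and is invariant to adding
any function of bin membership. The sliding-window curve moves a fixed
quantile-width window (default 20%, 100 equally spaced starts; duplicate
windows from heavy ties are merged) along the x distribution and smooths
the per-window means with a unit-mass Gaussian kernel. "Kernel of five" is
read as SD = 5 windows, truncated at ±3 SD and renormalized at the edges.
The heatmap cell (s, a) averages EF over participants within ±1 h of sleep
duration s and ±2 y of age a, with a parallel count matrix for
transparency mapping; the age axis extends 2 years beyond the observed
range so edge neighbourhoods are visible.

## Association and diagnostics

The EF regression mirrors the published table's term order; chronotype
enters as morning/evening dummies against the intermediate baseline;
estimation is complete-case OLS with classical standard errors (no
robustness claim is made for the synthetic cohort, which is homoskedastic
by construction). VIF is computed by explicit auxiliary regressions. The
younger/older comparison uses F = s²₁/s²₂ with an F-quantile CI on
(n₁ − 1, n₂ − 1) degrees of freedom and a two-sided p.

## Permutation volumetrics

The group statistic is the Welch t (no pooled-variance assumption). The
null is built by shuffling the band labels, with the same shuffle applied
to every region at a given permutation index so cross-region dependence is
preserved. The p-value is (k + 1)/(n_perm + 1) counting permutations with
|t| ≥ |t_obs| — two-sided, with the add-one correction for exact-test
validity. When the total number of label arrangements is at most 20,000
the null is enumerated exhaustively and p is the exact proportion.

A consequence of the add-one rule worth stating: with n_perm = 1000 the
smallest achievable p is 1/1001 ≈ 1.0e-3, which can never undercut the
corrected threshold 0.05/140 ≈ 3.6e-4. The region-test function keeps
n_perm = 1000 as its default, but the pipeline default is n_perm = 5000
(smallest p 2.0e-4) so corrected significance is attainable; recovery
analyses use that value.

Percent differences are 100·(m_band − m_other)/mean-of-means. Because
confound regression centers every volume column, the pipeline adds the
stored pre-residualization column means back for this computation only
(the t statistic is shift-invariant), keeping effect sizes on the original
volume scale. The summary volume averages z-scored significant-region
columns per participant; if no region survives correction the mediation
stage is skipped and its artifact records that fact.

## Mediation and effect-map comparison

Paths are OLS closed forms (a from m~x; b, c′ from y~x+m; c from y~x), so
c = c′ + a·b holds to machine precision and point estimates are fully
deterministic. Uncertainty for a·b comes from nonparametric case
resampling (rows), vectorized over the 1000 default replicates; the
interval is the 2.5–97.5 percentile range (not bias-corrected) and the
two-sided bootstrap p is 2·min(P(ab* ≤ 0), P(ab* ≥ 0)). The pipeline
standardizes the mediator and outcome first so coefficients are
standardized betas. Per-region EF associations are single-predictor OLS
slopes on z-scored volumes with Bonferroni correction over the region
count; the effect-map r² is the squared Pearson correlation between
percent differences and EF betas across **all** regions (not only the
significant ones), with the overlap count reported alongside.

## The synthetic cohort

The generator defines the study conditions for every validation:

* Sleep hours 1–12 drawn from a fixed distribution with median 7 and ~78%
  of mass in the 6–8 h band; ages uniform integers 38–73.
* Latent EF = −0.02·(age − midpoint) + curvature·((sleep − 7)² − mean)
  + 0.15·g + small covariate effects (daytime sleepiness, vascular count,
  APOE dose, Townsend, pack-years) + noise, with the noise variance chosen
  so the population latent variance is exactly 1 (hence standardized CFA
  loadings recover the configured values). The default curvature is
  −0.03 EF-SD per squared hour. g is a per-person structural-integrity
  factor shared with the affected regions' volumes — the generating
  mechanism for a true indirect effect.
* Tasks are linear in the latent with loadings (0.8, 0.7, 0.6, 0.5, 0.4)
  and residual SDs √(1 − λ²), then mapped to raw observables by the exact
  inverses of the preprocessing transforms (cubed pairs errors,
  exponentiated trail difference and reaction time, linear counts). Raw
  "counts" are kept continuous: rounding would break the exact one-factor
  covariance structure the faithfulness and recovery tests rely on, and no
  per-task distributional targets exist for the source cohort, so task
  scales are free parameters and documented, not claimed calibrated.
* Regions: 7/139 get an inverted-U volume effect (0.08% of base volume per
  squared hour), 39/139 a long-sleep-only deficit 0.4%·max(0, sleep − 8),
  class labels assigned by a seeded permutation; affected regions also
  load 1% of base volume on g. Noise SD is 3% of base; additive confound
  contributions (age, centered age², head size, table position, scan date)
  use per-region coefficients drawn once from a region substream. Effects
  are sized so that at n = 20,000 the corrected permutation test detects
  affected regions with high power while percent differences stay in the
  sub-percent range typical of regional grey matter.
* Log WMH is quadratic in sleep with its minimum at 8 h (SD 0.4) plus an
  age slope. Cognitive cells are masked MCAR at 10% — FIML is unbiased
  under (the weaker) MAR and no missingness mechanism is reported for the
  source data. All draws flow from one seed through named sub-streams, so
  (seed, config) reproduces tables bit-for-bit.
* `GroundTruth.true_indirect` is the population a·b of the standardized
  mediation model, computed by a 200,000-draw deterministic Monte Carlo of
  the generating equations (confound terms excluded, as they are
  independent of sleep and removed upstream); MC error is ~1e-3, and the
  latent EF stands in for the estimated score, so recovered a·b is very
  slightly attenuated relative to it.

What passing tests show — and what they do not: the pipeline recovers the
parameters of a cohort whose assumptions it matches exactly (Gaussian
noise, exact one-factor structure, MCAR missingness, additive confounds).
Real cohort data violate all of these to some degree (floor/ceiling
effects in tasks, MNAR missingness, non-Gaussian volume distributions,
residual confounding), so green tests certify the implementation, not the
substantive conclusions on any real population.

## Problem sizes and defaults

Validation runs use n = 20,000 participants for recovery analyses,
n = 100,000 for the EF-peak profile, 200-region null cohorts at n = 5,000
for calibration, 1000 bootstrap replicates, and n_perm = 5000 for
corrected inference (1000 for calibration at the uncorrected 5% level);
these sizes give stable answers at interactive runtimes on a single CPU.
Exclusion defaults: MAD outlier flagging at k = 5 on the scaled MAD
(1.4826·MAD, so k counts approximate SDs; the source analysis cites prior
work without a number, and k = 5 is deliberately conservative), zero-MAD
columns fall back to flagging values unequal to the median; non-positive
values reaching a log are set missing per cell and counted; rows with
missing confounds are dropped complete-case. Every exclusion is tallied in
the pipeline manifest so input rows always reconcile with analyzed plus
excluded rows.

## Known limitations

* The generator has no genetic linkage structure, no longitudinal
  trajectories, and covariates are mutually independent — correlated
  confounding cannot be studied with it.
* The two-sided |t| permutation reading is a design choice; the source
  analysis's sidedness is ambiguous, and one-sided tests would roughly
  halve the p-values.
* Bootstrap p-values of exactly 0 simply mean no replicate crossed zero;
  with 1000 replicates the resolution is 2e-3.
* `factanal` (R) serves as the independent CFA cross-check on complete
  data only; no independent FIML implementation is available offline, so
  FIML correctness is established by its complete-data degeneracy to the
  closed-form Gaussian likelihood plus parameter-recovery simulations.
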