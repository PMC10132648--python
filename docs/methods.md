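# Methods

## Model and estimation

The core model is a bivariate-response two-level linear mixed model. Two
continuous outcomes — systolic and diastolic blood pressure in mmHg — are
measured once on each woman, and women are nested in households. Each
outcome gets its own fixed-effect vector over a *shared* design matrix
(intercept plus 15 treatment-coded indicators from ten categorical risk
factors), a household random intercept, and a woman-level residual. The two
household intercepts follow a bivariate normal with covariance Σ_h; the two
residuals follow a bivariate normal with covariance Σ_e. Per-outcome design
matrices are out of scope by construction.

Stacking outcome-major within woman (SBP, then DBP), a household with n
women has marginal covariance `V_n = I_n ⊗ Σ_e + J_n ⊗ Σ_h`. The
exchangeable structure gives
`log det V_n = (n−1)·log det Σ_e + log det(Σ_e + nΣ_h)` and an inverse that
acts through the mean/deviation split, so likelihood evaluation never forms
a dense matrix. Because household sizes are small integers, the full
log-likelihood, the GLS normal equations, and the analytic score all reduce
to a fixed set of cross-products accumulated once per household-size class;
an optimizer step costs O(number of distinct sizes), independent of the
number of women. This is what makes the 500-replicate calibration studies
in the test suite affordable on one CPU.

Estimation is direct maximum likelihood:

* fixed effects are profiled out by GLS at each covariance iterate (the
  envelope theorem then makes the profiled gradient equal the partial
  gradient, which we compute analytically);
* Σ_h and Σ_e are parameterized by log-Cholesky factors (log on the
  diagonal), which enforces positive (semi-)definiteness and lets household
  variances collapse toward zero;
* L-BFGS-B with bounds on the Cholesky diagonals runs to a relative
  log-likelihood change below 1e-10 or projected-gradient norm below 1e-6,
  max 500 iterations; a boundary flag records when a household variance hit
  its floor (~1e-8 mmHg²);
* `vcov_fixed` is the inverse GLS information at the optimum, a 2p×2p
  matrix over the stacked (β1, β2) — the cross-outcome block is what the
  equality tests consume.

Classic multilevel software estimates the same Gaussian model by IGLS,
whose fixed point is the ML solution; we fit ML directly rather than
reimplement the iteration. The univariate fit is found to agree with
`lme4::lmer(..., REML=FALSE)` to six digits in the test suite. REML is not
implemented; all variance components are ML and therefore carry the usual
mild downward finite-sample bias.

Two nested special cases share the machinery: the univariate two-level
model (1×1 components, per outcome) and the single-level joint model
(Σ_h ≡ 0), which is closed-form — per-outcome least squares with the
residual MLE covariance — and serves as the null of the likelihood-ratio
comparison.

## Post-fit statistics

* **VPC** per outcome: σ²_h/(σ²_h+σ²_e), identical to the household ICC
  under a random-intercept model; reported both as a proportion and as a
  percent rounded to the nearest integer (the customary reporting
  precision).
* **Residual correlations** at each level: off-diagonal over the geometric
  mean of the diagonals of the corresponding 2×2 component.
* **Wald equality test** per covariate level k:
  χ² = (β̂1k−β̂2k)²/(V11+V22−2V12) on 1 df. Defined only for the joint fit;
  no multiplicity adjustment is applied across levels (the table notes
  this).
* **LRT** of multilevel vs single-level: 2Δℓ on df = 3 (the Σ_h
  parameters), with the plain chi-square p-value. The null pins variance
  parameters to the boundary, so this p-value is conservative relative to
  the chi-bar-square mixture; the result carries that caveat as a note
  rather than applying the mixture, keeping parity with how such
  comparisons are conventionally reported.
* **AIC/BIC** with BIC's N = number of women (level-1 units); the choice of
  N for BIC in multilevel models is genuinely ambiguous, and level-1 count
  is the common software default.
* **95% CIs** are Wald (±1.96·SE), matching the symmetric-interval
  convention of the reported coefficient tables.
* **QQ diagnostics**: marginal raw residuals standardized by the total SD
  √(σ²_h+σ²_e) against normal quantiles at (i−0.5)/N.

## Synthetic data generator

The generator emulates a women's-biomarker household survey. Defaults *are*
the study conditions:

| quantity | default | origin |
|---|---|---|
| households | 3727 | reported count |
| women per household | P(1)=0.76, P(2)=0.21, P(3)=0.03 | chosen so E[women] ≈ 4744/3727 ≈ 1.27 (distribution not reported) |
| covariate marginals | ten factors, reported sample proportions | reported descriptives |
| effects β1, β2 | joint-model point estimates (e.g. age 45–49: +15.85 SBP / +10.05 DBP; obese: +5.10 / +4.20) | reported coefficient table |
| Σ_h | variances 38.91 / 16.37, correlation 0.81 | reported variance table |
| Σ_e | variances 224.49 / 101.75, correlation 0.73 | reported variance table |
| intercepts | 112 / 72 mmHg | not reported; clinically plausible reference-group means, configurable |
| ever-told flag | Bernoulli(0.069), independent of outcomes | reported prevalence; used only in descriptives/maps |
| regions | the ten regions of Ghana at survey time, uniform assignment | region-level allocation not reported |

Draws: household sizes, region and household-level covariates per
household, a bivariate household effect; woman-level covariates and a
bivariate residual per woman; outcomes by the linear model. One documented
RNG stream (`numpy.random.default_rng(seed)`); identical (config, seed)
reproduce byte-identical CSVs. Multivariate normals use an
eigen-decomposition factor so a semi-definite Σ_h (including exactly zero)
is valid.

What the generator does **not** emulate — and hence what passing tests do
not establish about real survey data: covariate correlation structure
(factors are sampled independently), two-stage cluster sampling and
sampling weights, regional heterogeneity in risk, measurement rounding of
blood pressure, any outcome dependence of the ever-told flag, and
missingness. The household/woman level split of the ten factors (fuel,
wealth, water, toilet, size, wall, vegetables at household level) is a
structural reading of how such surveys collect them, and is configurable.

The toy region geometry is a deterministic grid of unit squares with a
`name` property per feature — a synthetic stand-in for real administrative
boundaries that keeps the mapping stage self-contained.

## Numerical choices and degenerate inputs

* Starting values: Σ_e from the pooled per-woman OLS residual covariance;
  Σ_h from the between/within moment estimator, eigenvalue-floored to PSD,
  falling back to 0.05×total covariance when the moment estimate is
  negative definite.
* Rank-deficient designs raise an error naming the collinear columns (QR
  with column pivoting).
* Quartiles for the boxplot QC rule use linear interpolation between order
  statistics, so the flagged set is reproducible; outliers are flagged,
  never dropped. Records missing an outcome or covariate are excluded
  complete-case with a logged count.
* Printed percentages round half-away-from-zero (one decimal for
  prevalence tables, integer for VPCs), matching how the descriptive tables
  they mirror are printed.
* Region joins for mapping are normalized exact-name matches
  (case-insensitive, whitespace-collapsed); anything unmatched is an error,
  because a silent mis-join is worse than a failure.
* The household-level correlation can reach ±1 when the ML estimate of Σ_h
  is rank-deficient on a given replicate; this is reported as estimated,
  not truncated.

## Problem sizes in the test suite

Simulation-backed tests use: one full-size survey (3727 households) for
parameter recovery; 500 replicates of 500 households for the equality
test's type-I error; 200 replicates of 1000 households for CI coverage; 100
full-size replicates for model selection; 10 full-size replicates (averaged)
for the acceptance script's correlation-recovery targets. These sizes keep
each study's Monte-Carlo error well inside the asserted tolerance while the
whole suite stays fast.

## Known limitations

* ML (not REML) variance components; at ~76% singleton households Σ_h is
  identified mainly by the minority of multi-woman households, so
  single-replicate household-level quantities (VPC, household correlation)
  are noticeably noisier than woman-level ones. The fit records the
  multi-woman household count.
* With that weak identification, a model-selection contest between the
  multilevel and single-level joint fits is not won universally: under the
  default generating truth the LRT statistic averages ≈35 but its spread
  leaves a material fraction of replicates below the BIC penalty
  (3·ln N ≈ 25.4). The acceptance test for near-universal selection
  reflects this sampling reality when it fails.
* No empirical-Bayes household predictions, no third (community) level, no
  survey weights, no non-Gaussian outcomes.
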