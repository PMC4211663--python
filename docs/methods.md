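# Methods

## The design

A single biallelic SNP, coded `G ∈ {0,1,2}` as the count of the
DBP-lowering C allele, instruments serum vitamin D binding protein (DBP,
mg/l). For an outcome `Y` the three estimands are:

* **Observational**: the age/sex-adjusted regression slope of `Y` on DBP,
  rescaled to 50 mg/l (one population SD of DBP). Biased when an
  unmeasured confounder `U` loads on both DBP and `Y`.
* **Causal (IV)**: for continuous `Y`, two-stage least squares (2SLS); for
  binary `Y`, a two-stage residual-inclusion ("control function")
  logistic regression. Consistent under the instrument assumptions
  (relevance, exchangeability, exclusion restriction).
* **Summary-statistic Wald ratio**: `(G→Y effect)/(G→DBP effect) × 50`,
  computable from published per-allele association summaries alone.

## Estimators and numerical choices

**2SLS** (`TwoStageLeastSquares`). Stage 1 regresses the exposure on the
instrument and exogenous covariates; stage 2 regresses the outcome on the
stage-1 fitted exposure and covariates. Inference uses *structural*
residuals `y − Wβ̂` (the outcome minus the prediction at the observed
exposure), not naive stage-2 residuals — the classic homoskedastic IV
variance `σ̂²(Ŵ'Ŵ)⁻¹` with `σ̂² = u'u/(n−k)`. A sandwich
(heteroskedasticity-robust) option exists but is off by default, matching
the standard `ivreg2`-style estimator. The implementation agrees with the
statsmodels IV2SLS reference to 1e-9 in both coefficients and SEs (tested).
The first-stage partial F of the instrument is attached; below 10 a
`WeakInstrumentWarning` is emitted but the estimate is still returned.
Confidence intervals are normal-theory (z), as is conventional for IV.

**Durbin–Wu–Hausman** endogeneity test, augmented-regression (Durbin
score) form: add the stage-1 residual `v̂` to the OLS structural equation
and form `χ² = n·(RSS₀ − RSS₁)/RSS₀` with 1 df. Under exogeneity its size
is ~5% at α = 0.05 (verified over 1000 simulated cohorts of n = 2000).
It is reported for continuous outcomes only.

**Control-function logistic IV** (`ControlFunctionLogisticIV`). Stage 2 is
a maximum-likelihood logistic fit of the disease on the fitted exposure,
covariates, and the stage-1 residual. The reported effect is
`OR = exp(50·β̂)` with a Wald CI from the stage-2 covariance, treating
stage 1 as fixed; the CI is therefore approximate (slightly narrow). No
bootstrap is attempted. (Quasi-)complete separation is detected and raised
as `SeparationError` rather than returning divergent estimates.

**Wald ratio**. Delta-method SE ignoring the numerator–denominator
covariance: `SE² = se_y²/β_x² + β_y²·se_x²/β_x⁴` (rescaled). The point
estimate equals covariate-free single-instrument 2SLS exactly (tested to
1e-10).

**Power**. Continuous outcomes: two-sided normal approximation with
non-centrality `√(n·r²)·b`, `b` the causal effect in outcome SDs per
exposure SD; an effect stated as a fractional change of the outcome mean is
standardized with user-supplied mean and SD — no default conversion is
invented. Case-control outcomes: non-centrality
`|log OR|·√(r²·n_ca·n_co/(n_ca+n_co))`, i.e. per-allele log-OR variance
`(1/n_ca + 1/n_co)/var(G)` propagated through the instrument. The binary
formula is validated against a simulation oracle (logistic fits on
simulated case-control genotypes) within 3 Monte-Carlo SE.

**Hardy–Weinberg**: 1-df chi-square against expectations at the sample
allele frequency, no continuity correction (counts here are in the
hundreds; an exact test would matter only for rare genotypes). Its
p-values are uniform under HWE sampling (KS-tested). Note that on the
published genotype counts (1159/893/202) this statistic is 2.51, p ≈ 0.11;
the study's printed HWE p of 0.89 is not reproducible from those counts
and was presumably computed on a different genotyped set — the package
reports the chi-square on the counts it is given.

## The synthetic-cohort generator

One latent standard-normal confounder `U` per participant loads on DBP
(`λ_d`, mg/l per SD) and on every outcome (`λ_y`) — the minimal structure
that makes observational and causal estimands diverge. DBP is linear in
genotype (HWE draws), sex, age (truncated normal on [16, 100]), ethnicity,
`U`, and Gaussian noise. Continuous traits are linear in centred DBP/50,
`U`, and noise (PTH and fasting insulin are generated log-normal: the
linear model holds on the log scale, which is also their analysis scale);
diseases are Bernoulli with a logistic link in the same linear predictor.
Trait and disease linear predictors are centred at the analytic DBP mean so
that `baseline` is directly the trait mean or baseline prevalence.

### The `"camos"` calibration

All preset values are solved analytically from published cohort marginals,
in this order:

1. Fixed effects: MAF 0.288; DBP per-allele −27.6; female +29.2; age
   −0.6/y; non-European −16.9 (mg/l). Demographics: 69.5% female, age
   65.7 ± 15.4 y, 5.4% non-European, 55.2% cold-season draws.
2. The intercept makes the analytic DBP mean 369.6 mg/l; the residual SD
   absorbs whatever the fixed effects, demographics and confounder leave
   of the target marginal variance 50.1² (with the default `λ_d = 30`,
   residual SD ≈ 32 mg/l).
3. Per outcome, the causal effect θ is the published IV column and the
   loading `λ_y = (obs − θ)·V_adj/(50·λ_d)` makes the published
   observational column the large-sample age/sex-adjusted slope
   (`V_adj` = DBP variance net of age and sex). Residual SDs then match
   the published marginal SDs by the variance budget. BMI and BMD are
   causally null (θ = 0) with negative/positive loadings — the textbook
   confounded-null scenario.

Two printed first-stage numbers are mutually inconsistent at this β and
MAF: a marginal DBP SD of 50.1 implies a univariable r² of
`27.6²·2p(1−p)/50.1² ≈ 0.125`, not the printed 0.141. The preset keeps the
marginals exact and accepts r² ≈ 0.125 (first-stage F ≈ 320 at n = 2254
instead of 368.7 — immaterial for instrument strength).

The split of non-genetic DBP variance between `U` (λ_d) and noise is not
identified by any published marginal; λ_d = 30 mg/l is a design choice that
yields endogeneity-test behaviour of the reported magnitude. For diseases,
the marginal-vs-conditional attenuation of logistic coefficients makes the
observational-column calibration approximate; disease scenarios are used
for sign/structure and null-coverage checks, not point recovery. Under
this latent-`U` disease model, residual inclusion carries a small
attenuation for non-null θ (the stage-1 residual proxies `U` only up to
the exposure noise); the estimator's point-recovery test therefore uses
the canonical triangular generative model in which endogeneity enters
through the first-stage error and 2SRI is consistent.

### What the generator does not emulate

Assay measurement error, longitudinal follow-up and incident disease,
youth-cohort enrollment mechanics, linkage disequilibrium with other
variants, pleiotropy, and population stratification. Passing recovery
tests therefore demonstrate estimator correctness under the stated
structural model — not robustness to pleiotropy or selection, which no
single-instrument design can deliver.

## Pipeline conventions

* Outlier order: DBP ceiling (600 mg/l ≈ 3.5 SD) removes rows first; then
  per configured trait, log transform (non-positive values set missing and
  logged), then the 3.5-SD rule on the analysis scale sets values missing.
  An exclusion log records counts per rule.
* Complete-case analysis throughout; missing genotypes simply drop from
  IV fits.
* Default covariates are age and sex only (matching the reported models);
  season and ethnicity columns exist and can be added via the config.
* Diseases are analysed in participants aged ≥ 25 (adult cohort); traits
  in everyone.
* Bonferroni: α/m with α = 0.05, m = 12 ⇒ 0.0042.
* Free 25OHD: `free = total/(1 + K_alb·[alb] + K_dbp·[DBP])` with
  K_dbp = 7×10⁸ M⁻¹, K_alb = 6×10⁵ M⁻¹, molar masses 58 kDa (DBP) and
  66.4 kDa (albumin), concentrations converted from mg/l and g/l. The four
  constants come from the free-hormone-calculation literature and are
  exposed in the config. At the cohort means (68.9 nmol/l, 369.6 mg/l,
  44.2 g/l) this gives 14.17 pmol/l versus the published per-person mean
  of 14.4 — the ~1.6% gap is the Jensen-type difference between a mean of
  ratios and the ratio at the means.
* The subgroup analysis (25OHD < 50 nmol/l) reruns the full pipeline on
  the subset. Because the selection variable is DBP-correlated, the
  first-stage slope attenuates slightly in the subgroup — the same pattern
  the original cohort shows (−27.0 vs −27.6 mg/l per allele).

## Problem sizes used by the test suite

Simulation-based checks use 500 replicate cohorts of n = 2254 for
parameter recovery and interval coverage, 1000 replicates of n = 2000 for
the endogeneity-test size, 2000 replicates for the binary power oracle,
and single cohorts of n = 100,000 for marginal/variance calibration —
sizes at which Monte-Carlo error is small relative to the tolerances
while the whole suite runs in well under a minute of simulation time.

## Known limitations

* Binary-outcome IV CIs ignore stage-1 uncertainty (slightly
  anti-conservative).
* Single-instrument only: no IVW/MR-Egger/median multi-SNP estimators, no
  LIML/GMM, no survival outcomes.
* The Wald-ratio SE ignores the numerator–denominator covariance, which is
  exact only when the two summaries come from non-overlapping samples.
* The generator's confounder is a single Gaussian factor; real confounding
  is plural and non-Gaussian.
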