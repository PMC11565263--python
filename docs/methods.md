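# Methods note

## Setting and scope

The package implements a within-trial cost-effectiveness analysis from the
health-care payer perspective: a two-arm randomized comparison of
clinician-supported computer-assisted CBT (CCBT) added to treatment as usual
(TAU) versus TAU alone in adult primary-care patients with at least moderate
depressive symptoms (PHQ-9 ≥ 10), followed from baseline through 12 weeks of
treatment and 3- and 6-month post-treatment follow-ups. Effects are measured
as QALYs (from SF-12-derived utilities) and as treatment response (≥ 50%
PHQ-9 reduction); costs cover the intervention only — the trial collected no
non-intervention health-service use, so the incremental cost is conservative.
Long-term state-transition modeling, discounting within the ≤ 9-month
window, societal costs and survey weighting are out of scope.

Assessment times are 0, 12/52, 12/52 + 0.25 and 12/52 + 0.50 years: the 3-
and 6-month follow-ups are anchored at the end of the 12-week treatment
period. They are configurable (`RunConfig.times_years`).

## Synthetic-trial generator

The trial's participant-level records are not publicly available, so the
generator emulates their statistical structure; its defaults are fixed at the
published study conditions and are not tuning knobs:

* n = 175 (95 intervention / 80 control, exact), 84.5% female, age
  N(47.03, 13.15²) clipped to [18, 90];
* baseline utility N(0.489 | 0.495, 0.11²) by arm, truncated to [0, 1]; the
  SD is backed out of the published baseline CI half-width (0.466–0.511 at
  n ≈ 95);
* follow-up utility `u_t = μ[arm][t] + 0.703 (u0 − μ0[arm]) + 0.07 z + ε`,
  ε ~ N(0, 0.121²), clipped to [0, 1], with arm-by-timepoint means fixed at
  the published adjusted means (intervention 0.619/0.601/0.608, control
  0.563/0.606/0.561). The slope 0.703 makes the implied baseline-utility
  coefficient in the QALY regression ≈ 0.55, matching the reported value;
  the residual SD reproduces follow-up CI widths. `z ~ N(0, 1)` is a shared
  latent severity factor linking utilities, PHQ-9 and response;
* baseline PHQ-9: integers, N(16, 4²) with loading 0.6 on z, truncated to
  [10, 27] (trial inclusion);
* response at each follow-up: Gaussian-copula Bernoulli with the published
  marginal rates (intervention 0.5821/0.50/0.4516, control
  0.3396/0.2885/0.25), loading 0.30 on z and 0.50 on a persistent
  participant propensity, so response correlates with severity and across
  time without changing the marginals. Follow-up PHQ-9 scores are then drawn
  consistent with the flag (responders uniformly in [0, baseline/2] via a
  floor, non-responders strictly above baseline/2 via a ceiling), so the
  50%-reduction rule is exactly recoverable from the scores;
* sessions attended (intervention only): beta-binomial(12, 3.5, 1.5) —
  mean 8.4 and quartiles exactly 7 and 11, matching the published mean (IQR)
  of 8.4 (7–11); a plain binomial with the same mean is too concentrated;
* device lending: borrow with probability 17/95, return given borrow 9/17;
* missingness: visit-level (utility and PHQ-9 at a timepoint vanish
  together), default 20% at each follow-up — the trial's exact visitwise
  dropout rates are not published, so this default is an explicit
  placeholder — with a logistic model in standardized arm, age and baseline
  PHQ-9 (weights 0.3/0.2/0.4) whose intercept is solved numerically so the
  realized marginal rate equals the configured rate. Missingness never
  depends on the masked values themselves (MAR by construction; verified by
  a test that the masked true value carries no information after adjusting
  for the observed covariates).

### Implied generating values

The calibrated defaults imply, in closed form
(`ccbt_cea.synthetic_trial.implied_effects`):

* adjusted incremental QALY = trapezoid-weighted contrast of the arm
  trajectories at fixed baseline utility = **0.0207**;
* expected incremental cost = 8.4 × $71.10 + $75 + $39.29 expected device
  cost = **$711.5** (the published regression estimates are 0.0209 and
  $714.64; the generator keeps the published *inputs* — trajectories, unit
  costs, session distribution — as primitives, so its implied effects sit
  within ~1% of the published regression outputs rather than exactly on
  them);
* marginal 12-week response odds ratio = odds(0.5821)/odds(0.3396) =
  **2.71**. The covariate-adjusted odds ratio is slightly larger
  (non-collapsibility, plus the latent-severity loading): a large-sample
  oracle fit (`oracle_adjusted_response_or`, n = 200 000) gives ≈ **2.76**,
  which is the truth used by the recovery tests. The published adjusted
  estimate is 2.83.

What the generator does **not** emulate: item-level SF-12/PHQ-9 responses,
TAU health-service utilization, site/clinician clustering, non-monotone or
informative dropout, and the trial's exact dropout pattern. Passing
recovery tests therefore demonstrate correctness of the pipeline under MAR
with a realistic covariance structure — not robustness to violations of MAR.

## Utility tariff

The licensed SF-6D US valuation algorithm is proprietary and not reproduced.
The default tariff is a synthetic affine map
`u = −0.066 + 0.0101·MCS + 0.0062·PCS`, clamped to [0, 1], calibrated so the
published arm-level mean MCS trajectories (≈ 28 → 41 in the intervention
arm) reproduce the published mean utilities (0.489 → 0.619) at a stable
PCS ≈ 44. Any tariff can be loaded from a YAML file (`TariffSpec`). The
default generator path draws utilities directly and bypasses the tariff;
`generate_sf12=True` draws MCS/PCS and maps them through it.

## MICE-PMM

Chained equations with predictive mean matching, written in-package because
the matching variant is contractual here:

* **Type-2 matching**: per imputation step, σ² is drawn from the scaled
  inverse-χ² and β from its normal approximation; predictions for observed
  *and* missing rows use the drawn β.
* **k = 5 donors** by absolute distance in predicted value; all donors tied
  at the k-th distance are included; one is drawn uniformly. Every imputed
  cell therefore equals some observed cell of its column — PHQ-9 stays
  integer in 0–27, utilities stay in [0, 1].
* **Visit order** is fixed left-to-right in time (post-treatment utility,
  post-treatment PHQ-9, then the 3- and 6-month pairs) for 10 burn-in cycles
  per imputation; each column is imputed from arm, age, sex, baseline
  utility, baseline PHQ-9 and the current completed values of the other
  follow-up columns. Missing cells are initialized by a random draw from the
  column's observed values.
* Singular designs fall back to a small ridge term with a warning; m
  defaults to 20 for desk runs and is fully configurable (the original
  analysis used m = 1000; recovery experiments here use m = 10, which is
  ample for point-estimate recovery since pooled *points* are m-averages).
* PHQ-9 is imputed on the score scale; the response flag and QALYs are
  derived after imputation (deriving, not imputing, keeps the ≥ 50% rule
  internally consistent).

## Estimation

Cost and QALY are modeled as a bivariate gaussian identity-link system with
correlated residuals — the "joint estimation" of cost and effect. Both
equations share the regressor set (treatment, age, sex=female, baseline
utility), and with identical regressors the joint ML coefficients coincide
with per-equation OLS (the seemingly-unrelated-regressions collapse); the
joint formulation contributes the residual correlation and the
cross-equation coefficient covariance `σ₁₂ (X'X)⁻¹`, which feeds the joint
(Δcost, ΔQALY) uncertainty. The per-participant "correlated random effect"
is this shared residual term: with one observation per participant, a
participant-level random effect and a correlated residual are the same
object. Response models (treatment, age, sex, baseline PHQ-9) are
binomial-logit, fitted independently of the cost/QALY system, with a
ridge-penalized fallback (all coefficients penalized, λ = 1) on perfect
separation. The incremental response probability is the average marginal
effect of treatment (g-computation) with a delta-method variance.

Pooling follows Rubin's rules with the Barnard–Rubin small-sample degrees of
freedom (complete-data df = n − p; n = 175 is small enough for this to
matter). The pooled covariance matrix is `W̄ + (1 + 1/m) B` as a full
matrix, so the (Δcost, ΔQALY) block is PSD by construction.

## Decision analysis

* ICER point estimate = ratio of the pooled treatment coefficients (the
  stated definition); the mean of draw-wise ratios is also reported — the
  two differ by Jensen's inequality, and the draw-wise mean is typically a
  few thousand dollars higher at this effect size.
* Uncertainty: 1000 (configurable) multivariate-normal draws at the pooled
  mean/covariance; an alternative mixture sampler draws from per-imputation
  fits behind the same contract.
* The percentile ICER interval uses draws with positive incremental effect
  and reports the excluded fraction; beyond 50% exclusions it refuses (a
  ratio quantile is then meaningless) and the pipeline records the refusal.
* CEAC uses strict `NMB > 0`; ties count as not cost-effective
  (measure-zero under continuous draws). Default WTP grid: $0–$150,000 in
  $1,000 steps.
* Response-based CE plane: Δcost and the response risk difference are
  simulated with zero cross-covariance, since the two models are fitted
  separately and no joint covariance is available; this is noted in the
  output rather than hidden.
* Extrapolation: the adjusted 6-month utility gap (treatment coefficient of
  an OLS of 6-month utility on treatment, age, sex, baseline utility, pooled
  across imputations) is projected over 12–60-month horizons; added QALYs =
  gap × horizon (stable) or gap × horizon / 2 (linear waning to zero), with
  no post-trial intervention cost. Stable benefit therefore always yields
  the (weakly) lower ICER, and both scenarios decrease in horizon.

## Numerical and design choices

* Determinism: every stage seeds a `numpy.random.Generator` from its config;
  imputations use `SeedSequence.spawn` streams; a rerun with the same
  configuration is byte-identical.
* Trapezoid integration is exact for piecewise-linear trajectories (tested
  against a dense-grid oracle at 1e-9).
* Collinear designs raise with the offending column names (pivoted QR);
  constant treatment is a degenerate design, not a zero estimate.
* Utility clipping to [0, 1] at generation truncates < 2.5 SD tails;
  the induced calibration bias is below 1e-3 and ignored.
* Config objects are pydantic models with validated invariants and lossless
  YAML round-trips; emitted JSON carries a `schema_version` field and is
  validated by the same models on load.

## Problem sizes

Recovery experiments use 50 replicates of n = 175 with m = 10, k = 5 — the
point estimates being m-averages, m = 10 recovers means well while keeping a
full experiment around a minute; the published m = 1000 matters for the
*variance* of a single analysis, not for the mean over replicates. Monte
Carlo checks in the test suite use 3 SE bands around generating values.

## Known limitations

* PMM with few donors can understate between-imputation variance in very
  small strata; m and k are configurable where that matters.
* The normal approximation for (Δcost, ΔQALY) draws ignores the t-tails of
  the pooled estimates; the mixture sampler partially addresses this.
* The synthetic missingness mechanism is MAR by construction; the pipeline's
  behavior under MNAR is untested and out of scope.
* The extrapolation is deliberately simple (no uncertainty band around the
  projected gap is simulated); it mirrors a scenario analysis, not a model.
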