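# Methods

## The problem

Given survival data from two related populations — a large *reference*
cohort and a smaller *relative* cohort (the motivating case: first- and
second-graft kidney transplant recipients, with graft failure = return
to dialysis or death as the endpoint) — the question is not whether one
group fares worse, but whether individual **risk factors act
differently** in the two groups, including factors that exist only in
one of them (e.g. waiting time before re-transplantation).  `relhaz`
implements two estimators of the same target quantity, the *weighting
factor*: the ratio of a covariate's hazard ratio in the relative group
to its hazard ratio in the reference group.

## Multiplicative-regression model for relative survival (MRS)

The observed hazard of relative-cohort subject *i* is decomposed
multiplicatively,

    h_obs(t | z_i) = h_e(t | z_i^e) · h_r(t | z_i^r),

where the *expected* hazard `h_e(t|z^e) = h0_e(t) exp(βᵉ·zᵉ)` is a
semi-parametric proportional-hazards model fitted on the reference
cohort alone, and the *relative* hazard `h_r(t|z^r) = h0_r(t)
exp(βʳ·zʳ)` captures what is specific to the relative cohort.  Plugging
the fitted expected coefficients into the relative-cohort partial
likelihood as per-subject constants makes `β̂ᵉ·z_i^e` an **offset**, so
stage two is an ordinary Cox fit with offsets:

    log PLr(βʳ) = Σ_i δ_i [ β̂ᵉ·z_i^e + βʳ·z_i^r
                  − log Σ_{k: t_k ≥ t_i} exp(β̂ᵉ·z_k^e + βʳ·z_k^r) ].

Interpretation: for a covariate present in both stages, `exp(βʳ)` is
the weighting factor (`βʳ = 0` ⇒ same effect in both cohorts); for a
covariate present only in the relative stage, `exp(βʳ)` is simply its
hazard ratio within the relative cohort.

### Uncertainty propagation

Unlike classical relative-survival models whose expected rates come
from population life tables, `β̂ᵉ` here is estimated, and its noise
must be propagated.  `run_mc_bootstrap` repeats, B times:

1. draw `βᵉ*` from MVN(`β̂ᵉ`, `V̂(β̂ᵉ)`)  (expected-model variance);
2. resample the relative cohort with replacement (sampling variance);
3. refit the relative model on the resample with `βᵉ*` in the offsets.

Means, SDs, and confidence intervals come from the B draws.  Choices
made where the procedure is underdetermined:

* **B defaults to 1000**; the calibration studies in the test suite use
  B = 80–200, which is enough for an SD and far cheaper.
* **CIs default to percentile** of the draws; a normal approximation
  (point ± z·SD) is available (`ci_method="normal"`).
* **p-values** are two-sided normal tests of point estimate / SD(draws).
* The **point estimate is the stage-two fit at `β̂ᵉ`**, not the mean of
  the draws; draws measure dispersion only.
* The MVN draw uses a symmetric eigenvalue square root with a 1e-10
  diagonal jitter, so an exactly singular `V̂(β̂ᵉ)` (including the test
  hook `vcov_e = 0`) is tolerated.
* Two **independent seeded streams** drive steps 1 and 2, so either
  variance source can be switched off in isolation (`mvn=False`,
  `resample=False`).
* Resamples whose refit fails (monotone likelihood, constant covariate,
  no events) are dropped, counted and replaced, capped at
  `max_refit_failures` (default 50); a 1000-iteration run should not
  abort because one resample is degenerate.

### Variable selection

`backward_select` follows the common epidemiological two-stage recipe:
univariable screen at p < 0.20, then backward elimination by
multivariable Wald test at p < 0.05, with a `forced` list (adjustment
covariates) exempt from both stages.

## Stratified Cox model (SCM)

The same comparison can be phrased as a single stratified partial
likelihood over both cohorts, `h_k(t|z) = h_{k,0}(t) exp(β·z)` with
stratum k ∈ {reference, relative} keeping its own baseline.  The
covariate vector is decomposed into four role blocks:

* `e` — reference-only (zeroed in relative rows),
* `c` — common effect,
* `s` — separate effect: an interaction column `z·1[relative]` added on
  top of a `c` column (the s-flag is only legal on a `c` covariate),
* `r` — relative-only (zeroed in reference rows).

For a c+s covariate the reference hazard ratio is `exp(βᶜ)` and the
relative one `exp(βᶜ+βˢ)`, so `exp(βˢ)` is again the weighting factor.
Composed hazard ratios get delta-method variances
(`var_c + var_s + 2·cov`) from the joint covariance; the relative-table
p-value for a c+s covariate tests the *difference* `βˢ = 0`.
Strata are fixed to the two groups; the design would generalize to more
strata but the role semantics assume one relative group.

## The partial-likelihood engine

Both estimators sit on one hand-written engine (`coxcore`) because the
required combination — per-subject fixed offsets, strata, and direct
access to score and information — is the heart of the method.

* **Risk sets**: subject k is at risk at event time t iff `t_k ≥ t`
  within the same stratum; a subject censored exactly at an event time
  is in that risk set.
* **Ties**: Breslow by default (the direct generalization of the untied
  likelihood); Efron available via `TiesPolicy("efron")`.  Breslow is
  fully vectorized (reverse cumulative sums over sorted times); Efron
  loops over tied blocks only.
* **Optimizer**: Newton–Raphson from 0 with step-halving (max 40
  halvings), gradient max-norm tolerance 1e-9, max 100 iterations.  The
  objective is concave, parameter counts are small; this converges in
  5–10 iterations on every study in the test suite.
* **Monotone likelihood**: any |coefficient| > 15 (hazard ratio beyond
  e¹⁵) flags non-convergence with a warning rather than failing
  silently.
* **Numerical stability**: the linear predictor is shifted by its
  maximum before exponentiation; the shift cancels exactly in every
  term.
* Constant covariates and singular information matrices raise
  `NonIdentifiableError`; datasets must be complete cases (missing
  values are excluded and counted by the CSV reader, mirroring
  complete-case analysis).
* Left truncation is not supported: all subjects enter at time 0, the
  natural scale for time-since-transplantation data.

Cross-checks in the test suite: lifelines (Efron) and scikit-survival
(Breslow) as independent fitters, a loop-based risk-set enumerator plus
scipy BFGS as a from-first-principles oracle, and finite differences
for score/information.

## Proportional-hazards diagnostics

`ph_test` is the Grambsch–Therneau score test: for each covariate, zero
correlation between Schoenfeld residuals and a centered transform of
event time (`km` default — 1 − KM(t−) of the pooled sample — plus
identity, rank, log).  The test variance uses the exact per-event
risk-set covariances with the correction for estimated coefficients;
the global statistic agrees with the reference implementation of the
test to ~5 decimals on fixtures.  Scaled residuals use the classical
average-information scaling `β̂ + m·r·V̂`.  Diagnostics are meant to be
run separately within each cohort (the `diagnose` CLI does this), since
proportionality of both groups' hazard ratios is what makes the
weighting factor time-constant.  `km_log_minus_log` exports
Kaplan–Meier log(−log S) curves per covariate level as plot-ready
tables (lifelines supplies the product-limit estimate).

## Synthetic data

The generator draws event times by inverse-transform sampling from
group-specific Weibull or exponential proportional-hazards models:
`T = H0⁻¹(−log U / exp(η))`.  `default_divat_like_config()` emulates a
national kidney-regraft registry: 2206 reference and 566 relative
subjects, ~20 independent binary covariates with group-specific
prevalences 0.04–0.95 and reference hazard ratios 0.77–2.50, four focal
shared covariates with non-unit weighting factors, two relative-only
covariates (hazard ratios 1.53 and 1.92), Weibull baselines with
deliberately different shapes per group (1.2 vs 0.9 — so stratified
baselines genuinely differ and the SCM's stratification matters), and
censoring (administrative horizon 13.7 plus exponential dropout, rate
0.28) calibrated once by stochastic root-finding so the expected event
fractions are ~13.6% (reference) and ~18.7% (relative).

What the generator does **not** emulate: covariate dependence (all
covariates independent; a real registry's comorbidities are
correlated), informative censoring, time-varying effects, and the
clinical semantics of the covariate labels.  Passing recovery and
calibration tests therefore demonstrate correctness of the estimators
under the stated model, not robustness to those violations.  A
`shared_subject_fraction` knob can duplicate a fraction of reference
subjects' covariate vectors into the relative cohort for robustness
experiments (off by default; the two cohorts are disjoint).

## Problem sizes used in the automated studies

The repeated-replicate studies (recovery, type-I error, CI coverage, PH
calibration/power) are sized to give informative binomial bounds while
keeping a full run of the suite and the acceptance script in the
minutes range: recovery uses the full registry-scale configuration with
100 replicates per weighting factor (60 in the acceptance script) and
B = 80; calibration studies use a compact 800 + 500-subject
configuration with 200 replicates and B = 100–200; the PH power study
uses n = 1000 with a hazard ratio of e^1.2 vanishing after t = 0.6.

## Known limitations

* No baseline-hazard estimation and hence no absolute survival curves —
  everything is conditional on the partial likelihood.
* No time-dependent covariates.
* The MRS stage-two model conditions on the expected model being
  correctly specified for the relative cohort's shared covariates.
* Backward selection inherits the usual caveats of stepwise procedures;
  the noise-retention test bounds, but does not remove, selection bias.
* No goodness-of-fit statistic for the relative model.
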