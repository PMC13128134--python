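# Methods

## Problem and estimand

Some treatments move a prognostic biomarker within weeks of initiation.
In the motivating setting — SGLT-2 inhibitors in chronic kidney disease —
eGFR typically *drops* acutely after the drug is started, and clinicians
ask whether a large early decline signals harm. The quantity of interest
is the conditional average treatment effect on absolute risk at horizon
`k`, given the acute change that would be observed under treatment:

    Δ_e(k | w1) = Pr[T(1) ≤ k, E(1) = e | W(1) = w1]
                − Pr[T(0) ≤ k, E(0) = e | W(1) = w1]

where `W(a)` is the percent biomarker change from baseline to month 1
under arm `a`, `T(a)` the event time, and `E(a)` ∈ {1 = primary
(kidney-failure-like), 2 = competing (death-like)} the event type. Results
are reported as risk reductions (control risk minus treated risk), so a
positive value favors treatment. A formally exact estimand would also
condition on 1-month event-free survival; because events in the first
month are a negligible fraction in the motivating trials, that
conditioning is omitted throughout.

The first term is identified from treated-arm data. The second is not:
`W(1)` and `T(0)` are never observed together. Identification requires a
cross-world model.

## Copula model and assumptions

Each arm's acute change is modeled as `W(a) = Xβ(a) + r(a)` with
covariates `X` (baseline eGFR, log proteinuria, age, SBP, sex, diabetes),
arm-specific OLS coefficients, and residuals `r(a)` whose marginal law is
a Johnson SU distribution fitted by maximum likelihood. The latent scores
`ε(a) = Φ⁻¹(F_r(a)(r(a)))` are assumed jointly bivariate normal with
correlation `ρ_ε` — a Gaussian copula on the residual scale. `ρ_ε` is not
identifiable from any randomized trial; it is the sensitivity parameter
swept over `[0, 1]` (negative values are supported for completeness). The
third assumption is cross-world no-confounding: given `(W(0), X)`, the
control-arm event process carries no further information about `ε(1)`.

Under these assumptions the conditional law of `W(0)` given
`W(1) = w1, X = x` is obtained by conditioning the latent bivariate
normal: `ε(0) | ε(1) ~ N(ρ_ε ε(1), 1 − ρ_ε²)`, mapped back through the
control residual quantile function. `|ρ_ε| = 1` is handled as an explicit
degenerate branch (point mass at the quantile-matched value), since the
sweep includes 1 exactly.

The SU family is used (not SB/SL): residuals of percent changes are
unbounded and mildly skewed, which SU covers while containing near-normal
shapes. The fitting criterion is maximum likelihood with quantile-based
initialization and a bounded L-BFGS-B optimizer on
`(γ, log δ, ξ, log λ)` with an analytic gradient; a second, near-normal
start is used if the first fails, and a moment-matched near-normal SU is
the loudly-logged last resort. The residual cdf used in the estimator is
the fitted parametric SU cdf by default; an empirical-cdf mode
(`residual_cdf="empirical"`) is available for sensitivity analysis.

## Outcome models and absolute risk

Within each arm, the endpoint model is:

* **primary / competing endpoint** — Fine-Gray subdistribution-hazard
  regression, fitted by the weighted estimating-equation approach:
  subjects failing from the other cause remain in the risk set with
  time-varying inverse-probability-of-censoring weights
  `G(t−)/G(Y_i−)` from an unstratified product-limit estimate of the
  censoring distribution in that fit's data;
* **composite endpoint** — Cox proportional hazards on time to any event.

Both use a single weighted Newton solver (step-halving, convergence at
gradient max-norm < 1e−6, ≤ 100 iterations) with Breslow tie handling,
and a Breslow baseline cumulative (sub)hazard, giving absolute risks
`1 − exp(−Λ̂₀(k) e^{lp})`. The biomarker enters through a restricted
cubic spline: 4 knots by default at the conventional quantiles
(0.05, 0.35, 0.65, 0.95) of the pooled two-arm acute-change sample, so
that both arms' fits share one basis. Constant covariate columns are
dropped per fit with a logged warning (e.g. diabetes in an all-diabetic
trial). Designs are centered before fitting; the baseline refers to the
covariate centroid, which cancels in predictions.

Arm-specific models are fitted separately rather than via one interacted
model: the estimation algorithm needs each arm's risk surface evaluated
at counterfactual biomarker values, and separate fits keep the two
surfaces free of shared-parameter leakage.

## Covariate mixing (SIR)

The estimand averages over `f(x | W(1) = w1)`. Rather than regress a
mixed continuous/binary covariate vector on `w1`, covariate profiles are
drawn by sampling-importance-resampling: propose from an estimate of the
unconditional covariate law — strata of the dichotomous covariates drawn
at their empirical frequencies, continuous covariates multivariate normal
within stratum — and weight by `f̂(w1 | x)`, the normal density of `w1`
at the treated-arm regression mean with the homoscedastic residual SD.
Because the proposal already targets `f(x)`, that factor cancels from the
importance weight. Strata with fewer than 5 rows are merged into the
modal stratum with a warning. The effective sample size
`1/Σ w²` is reported in diagnostics; a `w1` so far outside the support
that all weights underflow raises an error naming the offending value.
Treated-arm covariate rows are used, since the target conditions on
`W(1)`.

## Estimation algorithm

Per trial, per grid value `w1` (default grid −20% to +20% in 1% steps,
horizon `k = 2` years):

1. fit the biomarker regressions and residual SU laws;
2. fit the arm-specific outcome models;
3. draw covariate profiles `x̂` by SIR; the treated term is the average
   predicted risk at `(w1, x̂)` from the treated-arm model;
4. for each `x̂`: compute `r̂₁ = w1 − x̂β̂(1)`, score it,
   draw `J` (default 100) conditional control scores, map back to
   `ŵ₀ = x̂β̂(0) + r̂₀`, and average the control-arm model's predicted
   risk at `(ŵ₀, x̂)`;
5. the estimate is the control average minus the treated average.

Trials are estimated separately and pooled by relative sample size.
Pointwise 95% confidence intervals come from a percentile bootstrap
(default B = 1000) that resamples subjects within trial × arm strata and
reruns the entire pipeline; empirical percentiles are taken with
outward rounding (`lower`/`higher`), so B = 2 yields the min/max.
Replicates whose fits fail are dropped and counted; more than 5% failures
aborts. The effect-modification contrast `estimate(w1) − estimate(0)` is
computed within each replicate before taking percentiles.

Randomness is governed by one master seed; SIR draws per grid point,
copula draws per grid point, bootstrap replicates, and every generator
component use named substreams, so results are invariant to iteration
order and safe to parallelize.

Rows are dropped if any required field is missing, and the acute change
is trimmed at its pooled 0.5/99.5 percentiles before analysis (all counts
logged). Trimming quantiles are computed on the pooled sample across
trials and arms.

## Plausibility bounds on ρ_ε

Lower `ρ_ε` implies a wider distribution of the individual acute effect
`W(1) − W(0)` and hence a larger fraction of patients whose biomarker
would *improve* by more than a fixed absolute amount within a month. The
`rho_bound` module simulates that distribution under each candidate
`ρ_ε` (default grid 0 to 1 by 0.1, 15,000 draws): latent normal pairs
with correlation `ρ_ε` are mapped through the fitted arm-specific
residual quantile functions and added to the regression means at a
representative covariate profile (continuous covariates at sample means;
sex and diabetes configurable, defaulting to male, diabetic). The
absolute threshold (default 1 ml/min/1.73 m², converted to percent via
the sample mean baseline eGFR) then yields the exceedance proportion per
`ρ_ε`. The package reports the table; the judgment of which proportions
are biologically implausible is the analyst's.

## Synthetic-data generator

The generator emulates the structure of the motivating trials and serves
as the package's oracle, because both arms' potential outcomes are drawn
for every subject:

* covariates with trial-like moments (eGFR 61.9 ± 22.3, log proteinuria
  5.5 ± 1.8, age 62.8 ± 9.8, SBP 137.2 ± 16.8, 31% female, 92% diabetic,
  mild correlations);
* acute changes with covariate-dependent means calibrated to −0.6%
  (control) and −6.4% (treated), total SD 12.7%, left-skewed SU residuals,
  and latent cross-world residual correlation `rho_true` (default 0.8);
* a kidney-failure-like event from the standard mixture construction for
  subdistribution-proportional-hazards models — cause-1 lifetime
  probability `1 − (1 − p)^{e^{lp}}` with `lp` linear in `W(a)`, centered
  covariates and arm — so the Fine-Gray fit is correctly specified by
  construction; a death-like competing event from an exponential hazard in
  covariates and arm; administrative censoring at 2.6 years plus a small
  random censoring rate. Defaults give roughly 4–5% primary and 6–7%
  competing events observed.

`true_cate` estimates the estimand directly from the truth table by
averaging both potential event indicators among subjects with `W(1)`
within a bandwidth of `w1` — no censoring, no identification assumptions.
A `violate_no_confounding` switch adds a shared frailty to the treated
acute change and the control event process, as a negative control that
breaks the estimator's key assumption.

What the generator does **not** emulate: visit schedules, informative
dropout, measurement error structure in eGFR, non-proportional hazards,
or between-trial heterogeneity in the biomarker-outcome link. Passing
tests therefore demonstrate internal validity of the machinery under the
stated model, not robustness to these real-data features.

## Problem sizes used in the test suite

The suite exercises the pipeline at reduced but statistically meaningful
sizes chosen as a compromise between Monte-Carlo error and iteration
speed: parameter-recovery runs at n = 2,000–8,000 subjects, the oracle
comparison against a 200,000-subject truth table with a 4,000-per-arm
analysis dataset and 40 bootstrap replicates for its standard error, and
null-calibration coverage with 50 outer repeats of a 250-per-arm trial
with 200 bootstrap replicates each. Production defaults (B = 1000, J =
100, full grid) are correspondingly larger and configurable.

## Known limitations

* `ρ_ε` is not estimable; everything downstream is a sensitivity analysis.
* Plug-in risk prediction with splines is slightly biased upward in the
  tails of the biomarker distribution at moderate sample sizes (convexity
  of `exp` in a noisy linear predictor); at 4,000 subjects per arm this is
  within the bootstrap uncertainty but visible when averaging across many
  replications.
* The SIR proposal assumes within-stratum multivariate normality of the
  continuous covariates; heavily non-normal covariates would call for a
  different proposal.
* The homoscedastic normal `f̂(w1 | x)` mirrors the OLS biomarker model;
  heteroscedastic acute changes would misweight the SIR draws.
* Left truncation, time-varying effects, and frailty terms are out of
  scope of the hazard module.
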