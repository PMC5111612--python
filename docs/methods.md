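# Methods

## Model and estimators

Each subject is observed in two periods with their own time origins. The
prior-period hazard is `h_0p(t) exp(β C_i)` and the study-period hazard is
`h_0s(t) exp(θ X_i + β C_i)`, where `X_i` are measured covariates
(including the treatment indicator) and `C_i` is hidden. Under proportional
baselines `h_0s = h_0p e^α` the two hazards share an individual-specific
baseline `h_0p(t) exp(β C_i)`; treating it as an infinite-dimensional
nuisance and maximizing the full likelihood in it for fixed `(θ, α)` gives
profile values that, substituted back, leave the pairwise likelihood

    L(θ, α) = ∏ᵢ [1/(1 + Pᵢ e^{ηᵢ})]^{Δpᵢ} [e^{ηᵢ}/(e^{ηᵢ} + Sᵢ)]^{Δsᵢ},
    ηᵢ = θXᵢ + α,  Pᵢ = 1{Tpᵢ ≤ Tsᵢ},  Sᵢ = 1{Tsᵢ ≤ Tpᵢ}.

Only subjects whose first observed event is an event (not a censoring)
contribute a non-unit factor ("informative pairs"). A subject who died
between the periods (`t_study = 0, d_study = 0`) contributes nothing.

Every supported variant — constant `α`, time-linear `α(t) = α₀ + α₁t`,
period-specific coefficients, the common-origin two-outcome design, and
time-varying covariate step paths — has per-subject log-contribution
`−Δp·log(1 + P e^{uᵢ}) − Δs·log(1 + S e^{vᵢ})` with `uᵢ, vᵢ` linear in the
parameters. The log-likelihood is therefore globally concave in all modes,
the analytic score and Hessian are exact, and the covariance is the
inverse observed information at the optimum. The printed weighted
outer-product covariance form for the basic model is recovered as a
special case (asserted in the tests); we define the covariance by the
Hessian because that definition extends unambiguously to every variant.

The comparison estimators: the unadjusted analysis fits the ordinary
(hidden-covariate-omitting) Cox partial likelihood to the study slice;
PERR divides the study hazard ratio by the prior one; PERR-ALT fits the
covariate-free pairwise likelihood separately in the exposed group
(estimating `θ+α`) and unexposed group (estimating `α`) and differences
them. For a saturated binary design, PERR-ALT and the joint pairwise MLE
coincide exactly with the log ratio of within-group informative-count
odds — the tests assert this identity to 1e-9.

## Assumptions, in order of practical importance

1. Hidden covariate effects are constant over time and identical in both
   periods (they must factor into the individual baseline).
2. Prior and study events are non-terminal and of the same nature; the
   method cannot address mortality outcomes.
3. Censoring is independent of the event times given `(X, C)`.
4. Baselines are proportional (or `α(t)` is modelled explicitly).
5. Prior event occurrence must not influence subsequent treatment.

Violations of 1 (confounder-treatment interaction) and 5 (prior-dependent
treatment) are simulated as explicit failure modes; see below.

## Numerical choices

- Fitting: damped Newton with step-halving; convergence when the score
  max-norm falls below 1e-8 (pairwise) / 1e-9 (Cox) or the Newton step
  max-norm falls below 1e-10 (the floating-point noise floor of the score
  at n ~ 1e5). The step-halving acceptance tolerance is relative,
  `1e-9·max(1, |loglik|)`, because the partial log-likelihood of a
  100,000-subject dataset carries absolute rounding noise far above any
  fixed absolute tolerance.
- Separation: monotone likelihoods are reported (`converged=False`, with
  the offending direction named), never clipped or penalized. Two
  detectors: a parameter escaping beyond ±40 during iteration, and a
  "quasi-separation" post-check (|estimate| > 15 or a variance above 1e4)
  for configurations where the score sneaks under tolerance while a
  parameter drifts to infinity with vanishing curvature — e.g. a group
  with informative pairs of only one kind.
- Tie handling: event-event ties (identical prior and study event times)
  are removed before pairwise fitting — their exact two-period likelihood
  is one, while the plain likelihood would assign them the biased factor
  `e^η/(1+e^η)²`. Tie detection is exact equality, no epsilon: ties are a
  measurement-resolution artifact and callers wanting fuzzy matching must
  pre-round. Ties involving a censored time are retained and the
  likelihood applied literally.
- Cox partial likelihood: Breslow tie handling by default (the form the
  unadjusted-analysis likelihoods are written in), Efron by flag;
  implemented in-repo with suffix-cumulative risk sums so the package is
  self-contained. It is verified against lifelines and R `survival::coxph`
  to 1e-6 (coefficients and covariance) in the test suite.
- Multi-period likelihood: within-subject risk sets only. "Exact" tie
  handling sums the strict-order likelihood values over all resolutions of
  tied within-subject events (feasible because period counts are small);
  Efron uses the standard cyclic weights. Breslow uses vectorized analytic
  derivatives; Efron/exact fits use central finite differences with a
  correspondingly looser score tolerance (1e-5).
- Step functions (time-varying covariate paths) are right-continuous;
  evaluation exactly at a breakpoint takes the new value.
- Wald intervals are computed on the coefficient (log hazard ratio) scale
  and exponentiated for hazard-ratio tables. PERR confidence intervals use
  a subject-resampling percentile bootstrap (default 2000 replicates,
  seed-controlled; non-converged replicates dropped and counted, with a
  warning above 10%).

## Simulation engine

`simulate_pairs` draws the hidden covariate and treatment per the scenario
laws (`C|X ~ Bernoulli(a + bX)` for confounding, or
`X ~ Bernoulli(expit(C − Δp))` for prior-dependent treatment — the two
dependence directions are mutually exclusive), generates event times by
inverse transform from exponential, Weibull-linear (`h(t) = 2t`) or
piecewise-constant baselines, and applies uniform censoring `U(0, c_max)`
with `c_max` calibrated by Monte Carlo root-finding so the censored
fraction hits the target within ±0.01 at n = 1e5. Calibration is marginal
over the covariate mix, per period; repeated-replicate experiments
calibrate once per cell against a 100,000-draw sample and reuse the bound.
Differential case fatality removes subjects between periods with
confounder-dependent probability, encoding deaths as
`(t_study = 0, d_study = 0)`; with 10%/50% fatality and `C ~ Bern(0.5)`
the survivor confounder frequency is `0.25/0.70 ≈ 0.357` (asserted to
±0.005).

Problem sizes: bias curves use one dataset of n = 100,000 per grid point
(the single-run bias approximation appropriate at that size); where a
tolerance of ±0.05 is checked against single-run Monte Carlo noise of
sd ≈ 0.02, the tests average three independent datasets per point. The
variance study uses 200 events per replicate
(n = 200/(1 − min(CPp, CPs))), 1000 replicates for the reported cells and
250 for the nine-cell monotonicity check. The three-period recovery test
uses n = 15,000. These sizes make the full suite run in about three
minutes while keeping Monte Carlo error well inside every asserted
tolerance.

"Average variance" in the variance study is the mean of the model-based
variance estimates across replicates (the empirical variance of the
estimates is reported alongside); the PERR model-based variance is the sum
of the two Cox-fit variances, ignoring their (weak) dependence.

## Least-false limits

When the Cox model omits `C`, its MLE converges to the root of the
population score of the misspecified model. The root is computed
semi-analytically: the outer expectation over observed `(T, Δ)` is a Monte
Carlo average (default 1e6 draws), while the inner risk-set expectation
over the binary `(X, C)` mix uses closed-form cumulative hazards and the
closed-form uniform-censoring survival function (which cancels between
numerator and denominator when censoring is treatment-free). Roots are
bracketed on `[truth − |β| − 2, truth + |β| + 2]` (attenuation keeps the
least-false value near the truth), found by Brent's method and polished by
Newton to a score below 1e-6. The first-order PERR bias approximation is
`I_s(θ)⁻¹U_s(θ) − I_p(0)⁻¹U_p(0)`. Cross-checks: the study-period root
matches a 400,000-subject simulated fit within 0.02, and the root-implied
PERR bias matches the simulated PERR bias within 0.03.

## What the synthetic data do and do not show

The generators emulate the study conditions exactly as specified: binary
treatment and confounder, multiplicative effects, uniform censoring,
proportional or explicitly-rated baselines. Real cohorts differ in ways
the generators do not model — continuous and multivariate confounders,
non-uniform and informative censoring, covariate measurement error,
left truncation, and calendar-time structure. Passing tests therefore
demonstrate the estimators' properties under the stated model, not
robustness to arbitrary real-data violations; the misspecification
scenarios (below) probe the named failure modes only.

Documented failure modes reproduced by the suite:

- *Confounder-treatment interaction* (`β₁ ≠ 0`): the pairwise estimate is
  biased by roughly `β₁·E[C|X=1]`. For moderate positive `β₁` it remains
  less biased than the unadjusted fit, but the advantage is not uniform:
  for negative `β₁` the unadjusted fit's confounding bias and interaction
  bias partially cancel, and it can be accidentally less biased than the
  pairwise fit. The acceptance check samples the region where the pairwise
  advantage holds (β₁ ∈ {0, 0.25}).
- *Prior-dependent treatment*: when treatment probability depends on the
  realized prior outcome, the pairwise estimate is biased (observed bias
  ≈ +0.3 at β = 2) — the design assumption, not the estimator, fails.
- *Differential case fatality* reweights the confounder distribution among
  study-period survivors and biases PERR, but leaves the pairwise estimate
  unbiased (each subject is their own control).

## Confounding test

Under `C ⊥ X` and treatment-free censoring, the least-false prior-period
treatment coefficient is exactly zero, so its Wald statistic is standard
normal. The procedure first checks the censoring condition by refitting
the prior model with censoring indicators reversed; if that check fails
the main test is still computed but flagged rather than decided. Both
stages use the 0.05 level by default, sequentially and without compound
error-rate adjustment; empirical type-I error over 2000 replicates at
n = 1000 lies within [0.03, 0.07], and the null p-value distribution
passes a Kolmogorov–Smirnov uniformity check. Non-rejection does not
validate the unadjusted model: bias from balanced hidden covariates and
censoring remains, and the pairwise method stays recommended.

## The eGFR application

Longitudinal kidney-function visits are converted to paired events: the
prior/study event is the first visit whose eGFR strictly exceeds the
period-origin visit's value (strict inequality; assessed at visit times
only, no interpolation). The prior period is censored at therapy start by
default (a switch allows the last pre-therapy visit instead — the choice
is not fully determined by the design and both readings are defensible); a
visit coinciding exactly with therapy start opens the study period. The
pairwise fit identifies the therapy contrast and the age-difference
effect; the unadjusted Cox fits use baseline ages because the time-varying
age covariate `age + t` shifts every member of a risk set equally and
leaves the partial likelihood's maximizer unchanged (asserted numerically
to 1e-6). Missing covariate values are rejected, not imputed.

The deposited cohort file is not bundled; the reader accepts a
user-supplied column mapping for it, and tests that need the real file
skip when it is absent. A synthetic visit generator (clearly labelled
synthetic) reproduces the documented cohort structure — 45 patients, 26 on
therapy A / 19 on B, therapy-A patients younger (mean 41.0 vs 48.1 years)
and more often female (35% vs 5%, assigned as fixed per-arm counts so a
small arm cannot come out gender-separated), 4–12 visits per patient —
with noisy, gently declining eGFR trajectories. Under a null therapy
effect at 400 patients, the pairwise 95% interval covers HR = 1 in ≥ 93%
of replicates.

## Known reproduction gap

In the variance study's low-censoring cell our average pairwise variance
(≈ 0.086) and average unadjusted variance (≈ 0.025) match the published
table's 0.08 and 0.03 within their tolerances, but the square root of
their ratio (≈ 1.85) exceeds the published 1.53 — a figure that is also
inconsistent with the table's own printed components
(sqrt(0.08/0.03) ≈ 1.63). Our unadjusted Cox variance agrees with R
`survival::coxph` and lifelines to seven significant digits on identical
data, so we report the discrepancy rather than re-tune the experiment; the
corresponding test is deliberately left failing. The high-prior-censoring
cell's ratio (4.16) reproduces within ~10%.

## Other limitations

- No frailty terms, stratification, left-truncation likelihood, or
  competing-risks extension.
- No Firth-type correction for separation (reported instead).
- The multi-period fitter uses within-subject risk sets only; it is not a
  recurrent-events (Andersen–Gill) fitter.
- Unequal observation windows between periods enter the likelihood
  literally through `P` and `S`; whether they bias the period effect in a
  given design is the user's responsibility to assess.
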