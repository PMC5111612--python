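# perrcox

Pairwise Cox likelihood and prior event rate ratio (PERR) adjustment for
hidden confounding in before/after observational survival designs.

## The problem

Observational studies of treatment effectiveness are prone to bias from
unmeasured confounders: patients who receive a treatment differ from those
who do not in ways the data never record. When each subject is observed in
two periods — a *prior* period before anyone is treated and a *study*
period in which some are — the subject can serve as their own control.
PERR adjustment divides the unadjusted study-period hazard ratio by the
prior-period hazard ratio, `HR_PERR = HR_s / HR_p`, hoping the prior ratio
captures the confounding. This package implements the likelihood framework
that puts that idea on a firm footing, shows exactly when it works, and
provides a better estimator when it does not.

## The model

For subject *i* with covariates `X_i` (including treatment) and hidden
covariates `C_i`, the prior- and study-period event hazards are

    h_pi(t) = h_0p(t) · exp(β C_i)
    h_si(t) = h_0s(t) · exp(θ X_i + β C_i)

With proportional baselines, `h_0s(t) = h_0p(t) e^α`, both hazards share an
individual-specific factor `h_0p(t) exp(β C_i)`. Profiling that nuisance
hazard out of the full two-period likelihood leaves the **pairwise Cox
likelihood**

    L(θ, α) = ∏_i [ 1 / (1 + P_i e^{θX_i+α}) ]^{Δ_pi} · [ e^{θX_i+α} / (e^{θX_i+α} + S_i) ]^{Δ_si}

where `P_i = 1{T_pi ≤ T_si}`, `S_i = 1{T_si ≤ T_pi}` and `Δ_pi, Δ_si` are
the event indicators. The data enter only through *which* of the two
within-subject events is observed first — and every hidden covariate with a
constant, shared effect cancels exactly. The estimates `(θ̂, α̂)` are
consistent and asymptotically normal, with standard errors from the
observed information. The likelihood generalizes to a time-linear period
effect `α(t) = α₀ + α₁t`, period-specific effects, time-varying covariate
paths, and more than two periods (with Breslow/Efron/exact tie handling).

The package also provides: the classical PERR and PERR-ALT estimators; a
prior-period hypothesis test for hidden confounding (under independence of
`C` and `X`, the least-false prior-period treatment coefficient is exactly
zero); least-false limits and a first-order Taylor approximation for the
bias of the misspecified fits; a simulation engine covering the bias and
variance experiments (confounder grids, censoring grids, interaction,
prior-dependent treatment, differential case fatality); and a worked
application deriving paired events from longitudinal eGFR visit records.

## Worked example

Simulate a confounded two-period cohort (true treatment log-HR θ = 0.7,
period effect α = −0.5, hidden confounder with β = 1.5 whose distribution
depends on treatment, 30% censoring in each period), then fit:

```python
import numpy as np
from perrcox import (SimulationScenario, simulate_pairs, fit_pairwise,
                     perr_estimate, test_unmeasured_confounding)

scn = SimulationScenario(n=20_000, theta=0.7, alpha=-0.5, beta=1.5,
                         c_law=("conditional", 0.3, 0.4),
                         censor_prior=0.3, censor_study=0.3, seed=12)
data = simulate_pairs(scn)
print(fit_pairwise(data).summary().round(3))

perr = perr_estimate(data, bootstrap_reps=500, seed=2)
print("PERR HR:", np.exp(perr.estimates[0]).round(3))
res = test_unmeasured_confounding(data)
print("confounding test p:", res.p_wald)
```

Output:

```
        coef     hr     se  ci_low  ci_high    p
x1     0.739  2.094  0.034   0.672    0.806  0.0
alpha -0.503  0.604  0.026  -0.554   -0.453  0.0

PERR HR: 1.772 95% CI: [1.695, 1.849]
confounding test: p_check=0.626 p_wald=2.2e-172 reject=True
```

The pairwise fit recovers the truth: θ̂ = 0.739 (true 0.7, HR ≈ 2.09) and
α̂ = −0.503 (true −0.5), with Wald intervals covering both. The PERR
ratio-of-ratios is left with residual bias (HR 1.77 vs the true 2.01)
because the ratio cancellation is only approximate under censoring. The
prior-period test passes its censoring-independence precondition
(p = 0.63) and then detects the hidden confounding overwhelmingly
(Wald p ≈ 1e-172): treatment predicts the prior event rate even though no
one is treated in the prior period, which can only come through
confounding.

## Command line

One entry point with subcommands mirroring the library:

```sh
perrcox fit-pairwise --input pairs.csv --model shared --ci 0.95 --out fit.json
perrcox fit-perr     --input pairs.csv --bootstrap 2000 --seed 1 --out perr.json
perrcox test-confounding --input pairs.csv --treatment x1
perrcox simulate     --scenario scenario.txt --seed 1 --out pairs.csv
perrcox bias-curve   --scenario scenario.txt --grid -10:10:21 --seed 1 --out bias.csv
perrcox variance-table --reps 1000 --seed 1 --out variances.csv
perrcox fabry        --visits visits.csv --seed 1 --out table.json
```

Model fits are written as JSON with the resolved configuration and seed
embedded; simulation outputs are tidy CSV.

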