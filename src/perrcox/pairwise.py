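"""Pairwise Cox likelihood: the profile likelihood of a two-period design.

Each subject carries an individual-specific baseline hazard (the shared
baseline times the exponentiated hidden-covariate term).  Profiling that
nuisance hazard out of the full two-period likelihood leaves a "pairwise"
likelihood that depends on the data only through which of the two
within-subject events was observed first.  For the basic model with shared
covariate effects and a constant log baseline-hazard ratio ``alpha`` the
per-subject contribution is::

    (1 / (1 + P_i * exp(eta_i)))**d_prior  *  (exp(eta_i) / (exp(eta_i) + S_i))**d_study

with ``eta_i = theta @ x_i + alpha``, ``P_i = 1{T_p <= T_s}`` and
``S_i = 1{T_s <= T_p}``.  Hidden covariates with constant, shared effects on
both periods cancel entirely, which is what makes the estimator robust to
unmeasured confounding.

Every supported variant (time-linear ``alpha(t)``, period-specific effects,
the two-effect common-origin design, and time-varying covariate paths) has
per-subject log-contribution ``-d_p*log1p(P*exp(u_i)) - d_s*log1p(S*exp(v_i))``
where ``u_i`` and ``v_i`` are linear in the parameters, so the log-likelihood
is globally concave and Newton iteration converges monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core import FitResult, PairedSurvivalData, remove_tied_pairs

__all__ = [
    "PairwiseModelSpec",
    "StepFunction",
    "SingularInformationError",
    "pairwise_loglik",
    "pairwise_score_and_information",
    "fit_pairwise",
    "profile_baseline_mles",
]


class SingularInformationError(np.linalg.LinAlgError):
    """Observed information is singular: a parameter direction is not identified."""


class StepFunction:
    """Right-continuous step function of time (vector-valued allowed).

    ``values[k]`` applies on ``[times[k-1], times[k])`` with ``values[0]``
    before the first breakpoint; evaluation exactly at a breakpoint uses the
    new value.
    """

    def __init__(self, times, values):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape[0] != self.times.shape[0] + 1:
            raise ValueError("need len(times) + 1 value rows")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("breakpoints must be strictly increasing")

    def __call__(self, t):
        idx = np.searchsorted(self.times, t, side="right")
        return self.values[idx]


@dataclass
class PairwiseModelSpec:
    """Which pairwise likelihood variant to evaluate.

    covariate_mode:
      ``shared``            same coefficients in both periods (basic model);
      ``period_specific``   separate prior/study coefficients with the study
                            hazard carrying the period effect;
      ``wlw_two_effects``   the common-time-origin two-outcome design (e.g.
                            left/right eye), structurally identical to
                            ``period_specific``;
      ``time_varying``      coefficients constant, covariate values supplied
                            as per-subject step-function paths evaluated on
                            each period's own clock.
    alpha_form: ``constant``, ``linear_in_time`` (alpha0 + alpha1*t, shared
      mode only) or ``zero`` (no period effect; common-baseline designs).
    """

    covariate_mode: str = "shared"
    alpha_form: str = "constant"
    paths: list | None = field(default=None, repr=False)

    def __post_init__(self):
        modes = {"shared", "period_specific", "wlw_two_effects", "time_varying"}
        if self.covariate_mode not in modes:
            raise ValueError(f"unknown covariate_mode {self.covariate_mode!r}")
        if self.alpha_form not in {"constant", "linear_in_time", "zero"}:
            raise ValueError(f"unknown alpha_form {self.alpha_form!r}")
        if self.alpha_form == "zero" and self.covariate_mode not in {"shared", "wlw_two_effects"}:
            raise ValueError("alpha_form='zero' requires shared or wlw_two_effects mode")
        if self.alpha_form == "linear_in_time" and self.covariate_mode != "shared":
            raise ValueError("linear-in-time alpha is only supported in shared mode")


def _design(data: PairedSurvivalData, spec: PairwiseModelSpec):
    """Build (W_u, W_v, names): u_i = W_u[i] @ params is the log hazard-rate
    contrast at the prior event time (study vs prior hazard), v_i the
    contrast at the study event time (prior vs study hazard)."""
    n, x = data.n, data.x
    mode = spec.covariate_mode
    if mode == "shared":
        names = list(data.x_names)
        if spec.alpha_form == "constant":
            wu = np.column_stack([x, np.ones(n)])
            wv = -np.column_stack([x, np.ones(n)])
            names += ["alpha"]
        elif spec.alpha_form == "zero":
            wu, wv = x.copy(), -x.copy()
        else:  # linear_in_time: alpha(t) = alpha0 + alpha1 * t
            wu = np.column_stack([x, np.ones(n), data.t_prior])
            wv = -np.column_stack([x, np.ones(n), data.t_study])
            names += ["alpha0", "alpha1"]
    elif mode in {"period_specific", "wlw_two_effects"}:
        if data.x_prior is None:
            raise ValueError(f"covariate_mode {mode!r} requires x_prior")
        xp = data.x_prior
        names = [f"theta_s_{c}" for c in data.x_names]
        names += [f"theta_p_{j + 1}" for j in range(xp.shape[1])]
        cols_u = [x, -xp]
        if spec.alpha_form == "constant":
            cols_u.append(np.ones((n, 1)))
            names += ["alpha"]
        wu = np.column_stack(cols_u)
        wv = -wu
    else:  # time_varying
        if spec.paths is None or len(spec.paths) != n:
            raise ValueError("time_varying mode needs one covariate path per subject")
        tau = data.tau if data.tau is not None else np.zeros(n)
        tp, ts = data.t_prior, data.t_study
        x_tp = np.array([np.atleast_1d(spec.paths[i](tp[i])) for i in range(n)])
        x_tp_off = np.array([np.atleast_1d(spec.paths[i](tp[i] + tau[i])) for i in range(n)])
        x_ts = np.array([np.atleast_1d(spec.paths[i](ts[i])) for i in range(n)])
        x_ts_off = np.array([np.atleast_1d(spec.paths[i](ts[i] + tau[i])) for i in range(n)])
        names = list(data.x_names) + ["alpha"]
        wu = np.column_stack([x_tp_off - x_tp, np.ones(n)])
        wv = np.column_stack([x_ts - x_ts_off, -np.ones(n)])
    return wu, wv, names


def _masks(data: PairedSurvivalData):
    ind = data.pair_indicators()
    # between-period deaths (t_study = 0, d_study = 0) contribute factor 1
    dead = (data.t_study == 0) & (data.d_study == 0)
    mp = data.d_prior * ind.p * (~dead)
    ms = data.d_study * ind.s * (~dead)
    return mp, ms


def _check_params(params, dim):
    params = np.asarray(params, dtype=float)
    if params.shape != (dim,):
        raise ValueError(f"expected {dim} parameters, got shape {params.shape}")
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite parameter value")
    return params


def pairwise_loglik(params, data: PairedSurvivalData, spec: PairwiseModelSpec | None = None) -> float:
    """Log of the pairwise Cox likelihood at ``params``.

    The caller is responsible for removing event-event tied pairs first
    (:func:`fit_pairwise` does this automatically).
    """
    spec = spec or PairwiseModelSpec()
    wu, wv, _ = _design(data, spec)
    params = _check_params(params, wu.shape[1])
    mp, ms = _masks(data)
    u = wu @ params
    v = wv @ params
    return float(-(mp * np.logaddexp(0.0, u)).sum() - (ms * np.logaddexp(0.0, v)).sum())


def pairwise_score_and_information(params, data: PairedSurvivalData,
                                   spec: PairwiseModelSpec | None = None):
    """Exact gradient and observed information (negative Hessian) of the
    pairwise log-likelihood.  For the shared/constant-alpha model the
    information reduces to the weighted outer-product sum
    ``sum_i w_i [[x x', x], [x', 1]]`` with logistic weights ``w_i``."""
    spec = spec or PairwiseModelSpec()
    wu, wv, _ = _design(data, spec)
    params = _check_params(params, wu.shape[1])
    mp, ms = _masks(data)
    u = wu @ params
    v = wv @ params
    su, sv = expit(u), expit(v)
    score = -(mp * su) @ wu - (ms * sv) @ wv
    w_u = mp * su * (1.0 - su)
    w_v = ms * sv * (1.0 - sv)
    info = (wu * w_u[:, None]).T @ wu + (wv * w_v[:, None]).T @ wv
    return score, info


def fit_pairwise(data: PairedSurvivalData, spec: PairwiseModelSpec | None = None, *,
                 ci_level: float = 0.95, max_iter: int = 100, tol: float = 1e-8,
                 start=None, remove_ties: bool = True) -> FitResult:
    """Maximize the pairwise likelihood by damped Newton iteration.

    Converged when the score max-norm drops below ``tol``; the covariance is
    the inverse observed information at the optimum and Wald intervals are on
    the coefficient (log hazard ratio) scale.  Monotone likelihoods
    (separation) are reported through ``converged=False`` with a diagnostic
    message rather than silently clipped.
    """
    from scipy.stats import norm

    spec = spec or PairwiseModelSpec()
    n_removed = 0
    if remove_ties:
        data, n_removed = remove_tied_pairs(data)
    wu, _, names = _design(data, spec)
    p = wu.shape[1]
    params = np.zeros(p) if start is None else _check_params(start, p)

    ll = pairwise_loglik(params, data, spec)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        score, info = pairwise_score_and_information(params, data, spec)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        # guard against non-identified directions
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = None
        if step is None or not np.all(np.isfinite(step)):
            eigval, eigvec = np.linalg.eigh(info)
            j = int(np.argmin(np.abs(eigval)))
            direction = ", ".join(f"{nm}:{c:+.3f}" for nm, c in zip(names, eigvec[:, j]))
            raise SingularInformationError(
                f"observed information is singular; non-identified direction ({direction})")
        if np.max(np.abs(step)) < 1e-10:  # at the floating-point noise floor
            converged = True
            break
        # damped update with step halving
        lam = 1.0
        for _ in range(60):
            trial = params + lam * step
            ll_new = pairwise_loglik(trial, data, spec)
            if ll_new >= ll - 1e-9 * max(1.0, abs(ll)):
                break
            lam *= 0.5
        params, ll = params + lam * step, ll_new
        if np.max(np.abs(params)) > 40.0:
            message = ("monotone likelihood (separation): parameter diverging along "
                       + names[int(np.argmax(np.abs(params)))])
            break
    else:
        it = max_iter
    if not converged and not message:
        score, _ = pairwise_score_and_information(params, data, spec)
        message = (f"no convergence in {max_iter} iterations "
                   f"(score max-norm {np.max(np.abs(score)):.3g})")

    score, info = pairwise_score_and_information(params, data, spec)
    if converged:
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            eigval, eigvec = np.linalg.eigh(info)
            j = int(np.argmin(np.abs(eigval)))
            direction = ", ".join(f"{nm}:{c:+.3f}" for nm, c in zip(names, eigvec[:, j]))
            raise SingularInformationError(
                f"observed information at optimum is singular; "
                f"non-identified direction ({direction})")
        # quasi-separation: the score can drop under tolerance while a
        # parameter escapes to +-inf with vanishing curvature
        if np.max(np.abs(params)) > 15.0 or not np.all(np.isfinite(cov)) \
                or np.max(np.diag(cov)) > 1e4:
            converged = False
            message = ("separation suspected: estimate "
                       f"{params[int(np.argmax(np.abs(params)))]:.2f} on "
                       + names[int(np.argmax(np.abs(params)))]
                       + " with unbounded variance")
    else:
        cov = np.full((p, p), np.nan)
    z = norm.ppf(0.5 + ci_level / 2.0)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    ci = np.column_stack([params - z * se, params + z * se])
    return FitResult(names=names, estimates=params, covariance=cov, loglik=ll,
                     ci_level=ci_level, ci=ci, n_used=data.n,
                     n_ties_removed=n_removed, converged=converged,
                     n_iter=it, message=message)


def profile_baseline_mles(theta, alpha, x, t_prior, d_prior, t_study, d_study):
    """Profile MLEs of the individual baseline hazard and cumulative hazard
    at the two observed times, for given ``(theta, alpha)``.

    Returns a dict with ``h_tp``, ``H_tp``, ``h_ts``, ``H_ts``.  Plugging
    these into the full two-period likelihood recovers the pairwise
    likelihood up to a factor free of ``(theta, alpha)``; used for testing.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    x = np.atleast_1d(np.asarray(x, dtype=float))
    eta = float(theta @ x + alpha)
    P = 1.0 if t_prior <= t_study else 0.0
    S = 1.0 if t_study <= t_prior else 0.0
    e = np.exp(eta)
    h_tp = d_prior / (1.0 + P * e)
    h_ts = d_study / (S + e)
    return {
        "h_tp": h_tp,
        "H_tp": d_prior / (1.0 + P * e) + S * d_study / (S + e),
        "h_ts": h_ts,
        "H_ts": d_study / (S + e) + P * d_prior / (1.0 + P * e),
    }
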