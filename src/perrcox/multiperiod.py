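"""Within-subject partial likelihood for designs with more than two periods.

Each subject contributes a sequence of periods, each with its own observed
time, event indicator, period offset and covariate vector.  Risk sets are
formed *within* subject across that subject's periods (this is not a
between-subject recurrent-events fitter): the contribution of an event in
period k is ``exp(eta_ik) / sum_{j: t_ij >= t_ik} exp(eta_ij)`` with
``eta_ij = theta @ x_ij + alpha_j`` and the first-period effect fixed at
``alpha_1 = 0``.  Covariates are per-period constants; a treated-only-later
design is encoded by zeroing the treatment column in early periods, which
makes the two-period case reduce exactly to the pairwise likelihood.

Within-subject tied times are handled by Breslow or Efron approximations or
by the exact likelihood, defined as the sum of the strict-ordering
likelihood values over all resolutions of the tied events.  With only two
periods the Breslow form is a poor approximation (an event-event tied pair
gets a non-unit factor instead of the exact value one), so ``exact`` is the
recommended method there.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
import pandas as pd

from .core import FitResult
from .pairwise import SingularInformationError

__all__ = ["MultiPeriodData", "multi_period_loglik", "fit_multi_period"]


@dataclass
class MultiPeriodData:
    """Per-subject sequences of period observations.

    ``times[i]``, ``events[i]``, ``taus[i]`` are length ``m_i`` arrays and
    ``xs[i]`` is ``(m_i, q)``; ``taus[i][0]`` must be 0 (first-period origin).
    """

    subject_id: list
    times: list
    events: list
    taus: list
    xs: list

    def __post_init__(self):
        self.times = [np.asarray(t, dtype=float) for t in self.times]
        self.events = [np.asarray(d, dtype=float) for d in self.events]
        self.taus = [np.asarray(t, dtype=float) for t in self.taus]
        self.xs = [np.atleast_2d(np.asarray(x, dtype=float)) for x in self.xs]
        for i, (t, d, tau, x) in enumerate(zip(self.times, self.events, self.taus, self.xs)):
            m = t.shape[0]
            if m < 1:
                raise ValueError(f"subject {i}: needs at least one period")
            if d.shape != (m,) or tau.shape != (m,) or x.shape[0] != m:
                raise ValueError(f"subject {i}: inconsistent sequence lengths")
            if tau[0] != 0.0:
                raise ValueError(f"subject {i}: tau for the first period must be 0")
            if not set(np.unique(d)) <= {0.0, 1.0}:
                raise ValueError(f"subject {i}: event indicators must be 0/1")

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def q(self) -> int:
        return self.xs[0].shape[1]

    @property
    def n_periods(self) -> int:
        return max(t.shape[0] for t in self.times)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, x_cols=None) -> "MultiPeriodData":
        """Build from long format: subject_id, period (1-based), t, d, tau, x-columns."""
        if x_cols is None:
            x_cols = sorted((c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
                            key=lambda c: int(c[1:]))
        ids, times, events, taus, xs = [], [], [], [], []
        for sid, g in df.groupby("subject_id", sort=False):
            g = g.sort_values("period")
            ids.append(sid)
            times.append(g["t"].to_numpy(dtype=float))
            events.append(g["d"].to_numpy(dtype=float))
            taus.append(g["tau"].to_numpy(dtype=float) if "tau" in g else
                        np.zeros(len(g)))
            xs.append(g[x_cols].to_numpy(dtype=float))
        return cls(ids, times, events, taus, xs)


def _split_params(params, q, n_periods):
    params = np.asarray(params, dtype=float)
    expect = q + n_periods - 1
    if params.shape != (expect,):
        raise ValueError(f"expected {expect} parameters (theta x{q}, alpha_2..alpha_{n_periods})")
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite parameter value")
    theta = params[:q]
    alpha = np.concatenate([[0.0], params[q:]])  # alpha_1 fixed at 0
    return theta, alpha


def _subject_eta(theta, alpha, x, m):
    return x @ theta + alpha[:m]


def _loglik_breslow(theta, alpha, data: MultiPeriodData) -> float:
    ll = 0.0
    for t, d, x in zip(data.times, data.events, data.xs):
        eta = _subject_eta(theta, alpha, x, t.shape[0])
        w = np.exp(eta)
        for k in np.flatnonzero(d == 1.0):
            denom = w[t >= t[k]].sum()
            ll += eta[k] - np.log(denom)
    return ll


def _loglik_efron(theta, alpha, data: MultiPeriodData) -> float:
    ll = 0.0
    for t, d, x in zip(data.times, data.events, data.xs):
        eta = _subject_eta(theta, alpha, x, t.shape[0])
        w = np.exp(eta)
        for tval in np.unique(t[d == 1.0]):
            dead = np.flatnonzero((t == tval) & (d == 1.0))
            m = dead.size
            s0 = w[t >= tval].sum()
            wd = w[dead].sum()
            ll += eta[dead].sum()
            for ell in range(m):
                ll -= np.log(s0 - (ell / m) * wd)
    return ll


def _subject_exact_lik(eta, t, d) -> float:
    """Exact subject likelihood: sum over resolutions of within-subject ties
    of the strict-order likelihood value."""
    w = np.exp(eta)
    # groups of tied *events*; censored periods keep their literal position
    groups = []
    for tval in np.unique(t[d == 1.0]):
        g = np.flatnonzero((t == tval) & (d == 1.0))
        if g.size > 1:
            groups.append(list(g))
    if not groups:
        lik = 1.0
        for k in np.flatnonzero(d == 1.0):
            lik *= w[k] / w[t >= t[k]].sum()
        return lik
    total = 0.0
    for orderings in product(*(permutations(g) for g in groups)):
        rank = {}
        for order in orderings:
            for pos, k in enumerate(order):
                rank[k] = pos
        lik = 1.0
        for k in np.flatnonzero(d == 1.0):
            # risk set: strictly later times; same-time censored periods;
            # same-time tied events not yet resolved earlier; itself
            risk = w[t > t[k]].sum() + w[k]
            same = np.flatnonzero((t == t[k]) & (np.arange(t.size) != k))
            for j in same:
                if d[j] == 0.0 or rank.get(j, 0) > rank.get(k, 0):
                    risk += w[j]
            lik *= w[k] / risk
        total += lik
    return total


def _loglik_exact(theta, alpha, data: MultiPeriodData) -> float:
    ll = 0.0
    for t, d, x in zip(data.times, data.events, data.xs):
        eta = _subject_eta(theta, alpha, x, t.shape[0])
        ll += np.log(_subject_exact_lik(eta, t, d))
    return ll


_METHODS = {"breslow": _loglik_breslow, "efron": _loglik_efron, "exact": _loglik_exact}


def multi_period_loglik(params, data: MultiPeriodData, tie_method: str = "breslow") -> float:
    """Within-subject partial log-likelihood over all periods.

    ``params`` is ``(theta_1..theta_q, alpha_2..alpha_K)`` with K the maximum
    number of periods; ``alpha_1`` is fixed at zero.
    """
    if tie_method not in _METHODS:
        raise ValueError(f"unknown tie_method {tie_method!r}")
    theta, alpha = _split_params(params, data.q, data.n_periods)
    return float(_METHODS[tie_method](theta, alpha, data))


def _breslow_derivs(params, data: MultiPeriodData):
    """Vectorized Breslow log-likelihood, score and information in long form."""
    q, K = data.q, data.n_periods
    theta, alpha = _split_params(params, q, K)
    p = q + K - 1
    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    for t, d, x in zip(data.times, data.events, data.xs):
        m = t.shape[0]
        eta = _subject_eta(theta, alpha, x, m)
        w = np.exp(eta)
        # design rows: (x_k, period indicator columns for periods 2..K)
        W = np.zeros((m, p))
        W[:, :q] = x
        for k in range(1, m):
            W[k, q + k - 1] = 1.0
        for k in np.flatnonzero(d == 1.0):
            at_risk = t >= t[k]
            s0 = w[at_risk].sum()
            s1 = (w[at_risk, None] * W[at_risk]).sum(axis=0)
            s2 = (w[at_risk, None, None] * W[at_risk][:, :, None]
                  * W[at_risk][:, None, :]).sum(axis=0)
            ll += eta[k] - np.log(s0)
            mbar = s1 / s0
            score += W[k] - mbar
            info += s2 / s0 - np.outer(mbar, mbar)
    return ll, score, info


def _numeric_derivs(fun, params, h=1e-5):
    p = params.shape[0]
    grad = np.zeros(p)
    for j in range(p):
        e = np.zeros(p)
        e[j] = h
        grad[j] = (fun(params + e) - fun(params - e)) / (2 * h)
    hess = np.zeros((p, p))
    for j in range(p):
        for k in range(j, p):
            ej, ek = np.zeros(p), np.zeros(p)
            ej[j], ek[k] = h, h
            hess[j, k] = hess[k, j] = (
                fun(params + ej + ek) - fun(params + ej - ek)
                - fun(params - ej + ek) + fun(params - ej - ek)) / (4 * h * h)
    return grad, hess


def fit_multi_period(data: MultiPeriodData, *, tie_method: str = "breslow",
                     ci_level: float = 0.95, max_iter: int = 100,
                     tol: float = 1e-8, start=None) -> FitResult:
    """Newton fit of the multi-period likelihood under the chosen tie method.

    Breslow uses analytic derivatives; Efron and exact use central finite
    differences (these paths are intended for small datasets with ties).
    Raises a singularity error when a period effect has no within-subject
    contrast (e.g. every subject observed in a single period).
    """
    from scipy.stats import norm

    if tie_method not in _METHODS:
        raise ValueError(f"unknown tie_method {tie_method!r}")
    if tie_method != "breslow":
        tol = max(tol, 1e-5)  # finite-difference derivatives limit attainable accuracy
    q, K = data.q, data.n_periods
    p = q + K - 1
    names = [f"theta_{j + 1}" for j in range(q)] + [f"alpha_{k}" for k in range(2, K + 1)]
    params = np.zeros(p) if start is None else np.asarray(start, dtype=float)

    def derivs(par):
        if tie_method == "breslow":
            return _breslow_derivs(par, data)
        fun = lambda z: _METHODS[tie_method](*_split_params(z, q, K), data)
        g, h = _numeric_derivs(fun, par)
        return fun(par), g, -h

    ll, score, info = derivs(params)
    converged, message, it = False, "", 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = None
        if step is None or not np.all(np.isfinite(step)):
            eigval, eigvec = np.linalg.eigh(info)
            j = int(np.argmin(np.abs(eigval)))
            direction = ", ".join(f"{nm}:{c:+.3f}" for nm, c in zip(names, eigvec[:, j]))
            raise SingularInformationError(
                f"information is singular; non-identified direction ({direction})")
        if np.max(np.abs(step)) < (1e-10 if tie_method == "breslow" else 1e-7):
            converged = True  # numeric-derivative paths have a higher noise floor
            break
        lam = 1.0
        for _ in range(60):
            trial = params + lam * step
            ll_new, score_new, info_new = derivs(trial)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-9 * max(1.0, abs(ll)):
                break
            lam *= 0.5
        params, ll, score, info = trial, ll_new, score_new, info_new
        if np.max(np.abs(params)) > 40.0:
            message = ("monotone likelihood (separation): parameter diverging along "
                       + names[int(np.argmax(np.abs(params)))])
            break
    if not converged and not message:
        message = (f"no convergence in {max_iter} iterations "
                   f"(score max-norm {np.max(np.abs(score)):.3g})")

    if converged:
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            eigval, eigvec = np.linalg.eigh(info)
            j = int(np.argmin(np.abs(eigval)))
            direction = ", ".join(f"{nm}:{c:+.3f}" for nm, c in zip(names, eigvec[:, j]))
            raise SingularInformationError(
                f"information at optimum is singular; non-identified direction ({direction})")
    else:
        cov = np.full((p, p), np.nan)
    z = norm.ppf(0.5 + ci_level / 2.0)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    ci = np.column_stack([params - z * se, params + z * se])
    return FitResult(names=names, estimates=params, covariance=cov, loglik=ll,
                     ci_level=ci_level, ci=ci, n_used=data.n,
                     converged=converged, n_iter=it, message=message)
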