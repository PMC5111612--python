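"""Classical right-censored Cox partial likelihood fitting, the ratio-of-ratios
PERR estimator, and the group-wise PERR-ALT estimator.

The partial likelihood is implemented here directly (Breslow tie handling by
default, Efron optional) so the unadjusted analyses, the PERR numerator and
denominator, and the confounding test do not depend on an external survival
package; an independent implementation serves as a test-time oracle only.
"""

from __future__ import annotations

import numpy as np

from .core import FitResult, PairedSurvivalData
from .pairwise import PairwiseModelSpec, SingularInformationError, fit_pairwise

__all__ = ["cox_loglik", "cox_score_and_information", "fit_cox",
           "perr_estimate", "perr_alt_estimate"]


def _prepare(time, event, x):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != time.shape[0]:
        x = x.T
    if np.any(time < 0):
        raise ValueError("negative time")
    if event.sum() == 0:
        raise ValueError("no events in dataset")
    order = np.argsort(time, kind="stable")
    return time[order], event[order], x[order]


def _risk_stats(time, eta, x):
    """Suffix sums S0(t_i), S1(t_i), S2(t_i) over the risk set {j: t_j >= t_i},
    for times sorted ascending; tied times share the risk set of the first
    index of their tie group."""
    n, q = x.shape
    w = np.exp(eta)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((x * w[:, None])[::-1], axis=0)[::-1]
    xx = x[:, :, None] * x[:, None, :]
    s2 = np.cumsum((xx * w[:, None, None])[::-1], axis=0)[::-1]
    # map each index to the first index of its tie group
    first = np.zeros(n, dtype=int)
    for i in range(1, n):
        first[i] = first[i - 1] if time[i] == time[i - 1] else i
    return w, s0[first], s1[first], s2[first]


def _breslow_parts(time, event, x, beta):
    eta = x @ beta
    w, s0, s1, s2 = _risk_stats(time, eta, x)
    d = event.astype(bool)
    ll = float(np.sum(eta[d] - np.log(s0[d])))
    m1 = s1[d] / s0[d, None]
    score = (x[d] - m1).sum(axis=0)
    v = s2[d] / s0[d, None, None] - m1[:, :, None] * m1[:, None, :]
    info = v.sum(axis=0)
    return ll, score, info


def _efron_parts(time, event, x, beta):
    eta = x @ beta
    w, s0, s1, s2 = _risk_stats(time, eta, x)
    d = event.astype(bool)
    ll, score, info = 0.0, np.zeros(x.shape[1]), np.zeros((x.shape[1],) * 2)
    i = 0
    n = time.shape[0]
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        dead = [k for k in range(i, j + 1) if d[k]]
        m = len(dead)
        if m:
            wd = w[dead].sum()
            s1d = (x[dead] * w[dead, None]).sum(axis=0)
            s2d = (x[dead][:, :, None] * x[dead][:, None, :] * w[dead, None, None]).sum(axis=0)
            ll += float(eta[dead].sum())
            score += x[dead].sum(axis=0)
            for ell in range(m):
                f = ell / m
                a0 = s0[i] - f * wd
                a1 = s1[i] - f * s1d
                a2 = s2[i] - f * s2d
                ll -= np.log(a0)
                score -= a1 / a0
                info += a2 / a0 - np.outer(a1, a1) / a0 ** 2
        i = j + 1
    return ll, score, info


def cox_loglik(beta, time, event, x, ties: str = "breslow") -> float:
    """Cox log partial likelihood at ``beta``."""
    time, event, x = _prepare(time, event, x)
    parts = _breslow_parts if ties == "breslow" else _efron_parts
    return parts(time, event, x, np.asarray(beta, dtype=float))[0]


def cox_score_and_information(beta, time, event, x, ties: str = "breslow"):
    time, event, x = _prepare(time, event, x)
    parts = _breslow_parts if ties == "breslow" else _efron_parts
    _, score, info = parts(time, event, x, np.asarray(beta, dtype=float))
    return score, info


def fit_cox(time, event, x, *, names=None, ties: str = "breslow",
            ci_level: float = 0.95, max_iter: int = 100, tol: float = 1e-9,
            start=None) -> FitResult:
    """Newton-Raphson fit of the Cox partial likelihood.

    ``ties``: ``breslow`` (default; the form the unadjusted-analysis
    likelihoods are written in) or ``efron``.  Raises on zero events or a
    covariate with no contrast (singular information); separation is
    reported through the ``converged`` flag.
    """
    from scipy.stats import norm

    if ties not in {"breslow", "efron"}:
        raise ValueError(f"unknown tie method {ties!r}")
    time, event, x = _prepare(time, event, x)
    q = x.shape[1]
    names = list(names) if names is not None else [f"x{j + 1}" for j in range(q)]
    parts = _breslow_parts if ties == "breslow" else _efron_parts
    beta = np.zeros(q) if start is None else np.asarray(start, dtype=float)

    ll, score, info = parts(time, event, x, beta)
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
        if np.max(np.abs(step)) < 1e-10:  # at the floating-point noise floor
            converged = True
            break
        lam = 1.0
        for _ in range(60):
            trial = beta + lam * step
            ll_new, score_new, info_new = parts(time, event, x, trial)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-9 * max(1.0, abs(ll)):
                break
            lam *= 0.5
        beta, ll, score, info = trial, ll_new, score_new, info_new
        if np.max(np.abs(beta)) > 40.0:
            message = ("monotone likelihood (separation): coefficient diverging along "
                       + names[int(np.argmax(np.abs(beta)))])
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
        if np.max(np.abs(beta)) > 15.0 or not np.all(np.isfinite(cov)) \
                or np.max(np.diag(cov)) > 1e4:
            converged = False
            message = ("separation suspected: estimate "
                       f"{beta[int(np.argmax(np.abs(beta)))]:.2f} on "
                       + names[int(np.argmax(np.abs(beta)))]
                       + " with unbounded variance")
    else:
        cov = np.full((q, q), np.nan)
    z = norm.ppf(0.5 + ci_level / 2.0)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    ci = np.column_stack([beta - z * se, beta + z * se])
    return FitResult(names=names, estimates=beta, covariance=cov, loglik=ll,
                     ci_level=ci_level, ci=ci, n_used=time.shape[0],
                     converged=converged, n_iter=it, message=message)


def perr_estimate(data: PairedSurvivalData, *, bootstrap_reps: int = 2000,
                  ci_level: float = 0.95, seed: int | None = None,
                  ties: str = "breslow") -> FitResult:
    """Original PERR: ratio of the unadjusted study-period hazard ratio to
    the unadjusted prior-period hazard ratio.

    Fits the misspecified (hidden-covariate-omitting) Cox model separately
    to the prior and study slices; ``log HR_PERR = theta_s* - theta_p*``,
    elementwise over covariates.  The reported covariance is the sum of the
    two model-based covariances; when ``bootstrap_reps > 0`` the confidence
    interval is instead the subject-resampling percentile bootstrap
    (non-converged replicates are dropped and counted).
    """
    from scipy.stats import norm

    fit_p = fit_cox(data.t_prior, data.d_prior, data.x, names=data.x_names, ties=ties)
    fit_s = fit_cox(data.t_study, data.d_study, data.x, names=data.x_names, ties=ties)
    est = fit_s.estimates - fit_p.estimates
    cov = fit_s.covariance + fit_p.covariance
    q = data.q
    message = ""
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty((bootstrap_reps, q))
        dropped = 0
        for b in range(bootstrap_reps):
            idx = rng.integers(0, data.n, size=data.n)
            try:
                fp = fit_cox(data.t_prior[idx], data.d_prior[idx], data.x[idx], ties=ties)
                fs = fit_cox(data.t_study[idx], data.d_study[idx], data.x[idx], ties=ties)
            except (ValueError, np.linalg.LinAlgError):
                fp = fs = None
            if fp is None or not (fp.converged and fs.converged):
                reps[b] = np.nan
                dropped += 1
            else:
                reps[b] = fs.estimates - fp.estimates
        good = reps[~np.isnan(reps).any(axis=1)]
        lo, hi = (1.0 - ci_level) / 2.0, 1.0 - (1.0 - ci_level) / 2.0
        ci = np.column_stack([np.quantile(good, lo, axis=0),
                              np.quantile(good, hi, axis=0)])
        if dropped > 0.10 * bootstrap_reps:
            message = f"warning: {dropped}/{bootstrap_reps} bootstrap replicates dropped"
        elif dropped:
            message = f"{dropped} bootstrap replicates dropped"
    else:
        z = norm.ppf(0.5 + ci_level / 2.0)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        ci = np.column_stack([est - z * se, est + z * se])
    return FitResult(names=[f"perr_{c}" for c in data.x_names], estimates=est,
                     covariance=cov, loglik=fit_s.loglik + fit_p.loglik,
                     ci_level=ci_level, ci=ci, n_used=data.n,
                     converged=fit_p.converged and fit_s.converged,
                     n_iter=fit_p.n_iter + fit_s.n_iter, message=message)


def perr_alt_estimate(data: PairedSurvivalData, *, treatment_col: int = 0,
                      ci_level: float = 0.95) -> FitResult:
    """PERR-ALT: fit the covariate-free pairwise likelihood separately in the
    exposed and unexposed groups and take the ratio of within-pair hazard
    ratios.

    The exposed-group fit estimates ``theta + alpha``, the unexposed-group
    fit estimates ``alpha``; their difference is consistent for ``theta``.
    For a saturated binary design it equals the joint pairwise MLE exactly.
    The CI is delta-method from the two independent one-parameter fits.
    """
    from scipy.stats import norm

    t = data.x[:, treatment_col]
    if not set(np.unique(t)) <= {0.0, 1.0}:
        raise ValueError("treatment column must be binary 0/1")
    spec = PairwiseModelSpec(covariate_mode="shared", alpha_form="constant")
    fits = {}
    for label, mask in (("exposed", t == 1.0), ("unexposed", t == 0.0)):
        grp = data.subset(mask)
        grp = PairedSurvivalData(subject_id=grp.subject_id, t_prior=grp.t_prior,
                                 d_prior=grp.d_prior, t_study=grp.t_study,
                                 d_study=grp.d_study, x=np.zeros((grp.n, 0)),
                                 x_names=[])
        mp, ms = _informative_counts(grp)
        if mp + ms == 0:
            raise ValueError(f"{label} group has no informative pairs")
        if mp == 0 or ms == 0:
            raise ValueError(f"{label} group has informative pairs of only one kind "
                             "(monotone likelihood)")
        fits[label] = fit_pairwise(grp, spec, ci_level=ci_level)
    est = fits["exposed"].estimates[0] - fits["unexposed"].estimates[0]
    var = fits["exposed"].covariance[0, 0] + fits["unexposed"].covariance[0, 0]
    z = norm.ppf(0.5 + ci_level / 2.0)
    se = np.sqrt(var)
    return FitResult(names=["theta_perr_alt"], estimates=np.array([est]),
                     covariance=np.array([[var]]),
                     loglik=fits["exposed"].loglik + fits["unexposed"].loglik,
                     ci_level=ci_level,
                     ci=np.array([[est - z * se, est + z * se]]),
                     n_used=data.n,
                     n_ties_removed=fits["exposed"].n_ties_removed
                     + fits["unexposed"].n_ties_removed,
                     converged=fits["exposed"].converged and fits["unexposed"].converged,
                     n_iter=fits["exposed"].n_iter + fits["unexposed"].n_iter)


def _informative_counts(data: PairedSurvivalData) -> tuple[int, int]:
    """(prior-first, study-first) informative pair counts, ties excluded."""
    from .core import remove_tied_pairs
    d, _ = remove_tied_pairs(data)
    ind = d.pair_indicators()
    dead = (d.t_study == 0) & (d.d_study == 0)
    mp = int(((d.d_prior == 1) & (ind.p == 1) & ~dead & ~((ind.s == 1) & (d.d_study == 1))).sum())
    ms = int(((d.d_study == 1) & (ind.s == 1) & ~dead).sum())
    return mp, ms
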