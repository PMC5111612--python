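"""Shared domain types, paired-CSV input/output, and tied-pair preprocessing.

The central container is :class:`PairedSurvivalData`: one record per subject
holding the observed prior-period time/indicator, the observed study-period
time/indicator, and a fixed-length covariate vector (the treatment indicator
is simply one of the covariate columns).  Times are unit-agnostic; whatever
unit the caller uses must be consistent within a dataset.

Subjects whose prior and study events are observed at exactly the same time
("event-event ties") carry no information in the exact two-period likelihood
and are removed by :func:`remove_tied_pairs` before fitting.  Ties involving
at least one censored time are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PairedSurvivalData",
    "PairIndicators",
    "FitResult",
    "SchemaError",
    "ValidationError",
    "read_paired_csv",
    "write_paired_csv",
    "remove_tied_pairs",
]


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ValidationError(ValueError):
    """A data value violates the paired-survival contract."""


@dataclass
class PairedSurvivalData:
    """Paired right-censored survival data, one record per subject.

    Parameters
    ----------
    subject_id
        Opaque labels, length ``n``.
    t_prior, d_prior
        Observed prior-period time (min of event and censoring time) and
        event indicator (1 = event observed).
    t_study, d_study
        Same for the study period.  A subject who died between the periods
        is encoded as ``t_study = 0, d_study = 0`` and is retained; such a
        record contributes a factor of one to the pairwise likelihood.
    x
        Covariate matrix of shape ``(n, q)``; includes treatment indicator(s).
    x_names
        Column names for ``x``.
    x_prior
        Optional covariate matrix used in the prior-period hazard (for
        period-specific / two-effect designs).
    tau
        Optional per-subject offset between prior and study period start
        points (needed only for time-varying covariate paths).
    """

    subject_id: np.ndarray
    t_prior: np.ndarray
    d_prior: np.ndarray
    t_study: np.ndarray
    d_study: np.ndarray
    x: np.ndarray
    x_names: list[str] = field(default_factory=list)
    x_prior: np.ndarray | None = None
    tau: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id)
        self.t_prior = np.asarray(self.t_prior, dtype=float)
        self.d_prior = np.asarray(self.d_prior, dtype=float)
        self.t_study = np.asarray(self.t_study, dtype=float)
        self.d_study = np.asarray(self.d_study, dtype=float)
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if self.x.shape[0] != self.t_prior.shape[0] and self.x.shape[1] == self.t_prior.shape[0]:
            self.x = self.x.T
        n = self.t_prior.shape[0]
        for name, arr in (("t_prior", self.t_prior), ("d_prior", self.d_prior),
                          ("t_study", self.t_study), ("d_study", self.d_study)):
            if arr.shape != (n,):
                raise ValidationError(f"{name} has shape {arr.shape}, expected ({n},)")
        if self.x.shape[0] != n:
            raise ValidationError(f"x has {self.x.shape[0]} rows, expected {n}")
        if not self.x_names:
            self.x_names = [f"x{j + 1}" for j in range(self.x.shape[1])]
        if len(self.x_names) != self.x.shape[1]:
            raise ValidationError("x_names length does not match covariate dimension")
        self._validate_values()
        if self.x_prior is not None:
            self.x_prior = np.atleast_2d(np.asarray(self.x_prior, dtype=float))
            if self.x_prior.shape[0] != n:
                raise ValidationError("x_prior row count does not match")
        if self.tau is not None:
            self.tau = np.asarray(self.tau, dtype=float)
            if self.tau.shape != (n,):
                raise ValidationError("tau length does not match")
            if np.any(self.tau < 0):
                raise ValidationError("tau must be nonnegative")

    def _validate_values(self) -> None:
        for name, t in (("t_prior", self.t_prior), ("t_study", self.t_study)):
            bad = np.where(~np.isfinite(t) | (t < 0))[0]
            if bad.size:
                raise ValidationError(f"{name} negative or non-finite at row {bad[0]}")
        for name, d in (("d_prior", self.d_prior), ("d_study", self.d_study)):
            bad = np.where((d != 0.0) & (d != 1.0))[0]
            if bad.size:
                raise ValidationError(
                    f"{name} must be 0 or 1; got {d[bad[0]]!r} at row {bad[0]}")
        if not np.all(np.isfinite(self.x)):
            bad = np.where(~np.isfinite(self.x).all(axis=1))[0][0]
            raise ValidationError(f"missing/non-finite covariate at row {bad}")

    @property
    def n(self) -> int:
        return self.t_prior.shape[0]

    @property
    def q(self) -> int:
        return self.x.shape[1]

    def pair_indicators(self) -> "PairIndicators":
        """P_i = 1{T_p <= T_s} and S_i = 1{T_s <= T_p} (both 1 only on a tie)."""
        return PairIndicators(
            p=(self.t_prior <= self.t_study).astype(float),
            s=(self.t_study <= self.t_prior).astype(float),
        )

    def subset(self, idx: np.ndarray) -> "PairedSurvivalData":
        return PairedSurvivalData(
            subject_id=self.subject_id[idx],
            t_prior=self.t_prior[idx], d_prior=self.d_prior[idx],
            t_study=self.t_study[idx], d_study=self.d_study[idx],
            x=self.x[idx], x_names=list(self.x_names),
            x_prior=None if self.x_prior is None else self.x_prior[idx],
            tau=None if self.tau is None else self.tau[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "subject_id": self.subject_id,
            "t_prior": self.t_prior, "d_prior": self.d_prior.astype(int),
            "t_study": self.t_study, "d_study": self.d_study.astype(int),
        })
        for j, name in enumerate(self.x_names):
            df[name] = self.x[:, j]
        if self.x_prior is not None:
            for j in range(self.x_prior.shape[1]):
                df[f"xp{j + 1}"] = self.x_prior[:, j]
        if self.tau is not None:
            df["tau"] = self.tau
        return df


@dataclass
class PairIndicators:
    """Order indicators of the within-subject pair."""

    p: np.ndarray
    s: np.ndarray


@dataclass
class FitResult:
    """Estimates, covariance and Wald intervals from a likelihood fit."""

    names: list[str]
    estimates: np.ndarray
    covariance: np.ndarray
    loglik: float
    ci_level: float
    ci: np.ndarray  # (p, 2) intervals on the coefficient (log-HR) scale
    n_used: int
    n_ties_removed: int = 0
    converged: bool = True
    n_iter: int = 0
    message: str = ""

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.estimates / self.se

    @property
    def pvalues(self) -> np.ndarray:
        from scipy.stats import norm
        return 2.0 * norm.sf(np.abs(self.zvalues))

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.estimates)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.estimates,
            "hr": self.hazard_ratios,
            "se": self.se,
            "ci_low": self.ci[:, 0],
            "ci_high": self.ci[:, 1],
            "p": self.pvalues,
        }, index=self.names)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "estimates": self.estimates.tolist(),
            "hazard_ratios": self.hazard_ratios.tolist(),
            "se": self.se.tolist(),
            "covariance": self.covariance.tolist(),
            "loglik": float(self.loglik),
            "ci_level": float(self.ci_level),
            "ci": self.ci.tolist(),
            "n_used": int(self.n_used),
            "n_ties_removed": int(self.n_ties_removed),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "message": self.message,
        }


DEFAULT_SCHEMA = {
    "subject_id": "subject_id",
    "t_prior": "t_prior",
    "d_prior": "d_prior",
    "t_study": "t_study",
    "d_study": "d_study",
}


def read_paired_csv(path, schema: dict | None = None) -> PairedSurvivalData:
    """Read paired survival data from CSV.

    Default column names: ``subject_id, t_prior, d_prior, t_study, d_study,
    x1..xq`` with optional ``xp1..xpq`` (prior-period covariates) and ``tau``.
    ``schema`` maps the canonical names above to the file's column names;
    unmapped extra columns are ignored.  Covariate columns are every column
    named ``x<k>`` (or listed under schema key ``"x"``).
    """
    mapping = dict(DEFAULT_SCHEMA)
    x_cols = None
    xp_cols = None
    tau_col = None
    if schema:
        for key, val in schema.items():
            if key == "x":
                x_cols = list(val)
            elif key == "x_prior":
                xp_cols = list(val)
            elif key == "tau":
                tau_col = val
            else:
                mapping[key] = val
    df = pd.read_csv(path)
    for canonical, col in mapping.items():
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} (for {canonical})")
    if x_cols is None:
        x_cols = sorted(
            (c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
    if not x_cols:
        raise SchemaError("no covariate columns found (expected x1..xq)")
    for c in x_cols:
        if c not in df.columns:
            raise SchemaError(f"missing covariate column {c!r}")
    if xp_cols is None:
        found = sorted(
            (c for c in df.columns if c.startswith("xp") and c[2:].isdigit()),
            key=lambda c: int(c[2:]),
        )
        xp_cols = found or None
    if tau_col is None and "tau" in df.columns:
        tau_col = "tau"

    def _num(colname, canonical):
        try:
            return pd.to_numeric(df[colname], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"column {colname!r} ({canonical}) is not numeric: {exc}")

    return PairedSurvivalData(
        subject_id=df[mapping["subject_id"]].to_numpy(),
        t_prior=_num(mapping["t_prior"], "t_prior"),
        d_prior=_num(mapping["d_prior"], "d_prior"),
        t_study=_num(mapping["t_study"], "t_study"),
        d_study=_num(mapping["d_study"], "d_study"),
        x=df[x_cols].to_numpy(dtype=float),
        x_names=list(x_cols),
        x_prior=None if xp_cols is None else df[xp_cols].to_numpy(dtype=float),
        tau=None if tau_col is None else _num(tau_col, "tau"),
    )


def write_paired_csv(data: PairedSurvivalData, path) -> None:
    """Write paired data as CSV (UTF-8, '.' decimal, shortest round-trip floats)."""
    data.to_frame().to_csv(path, index=False)


def remove_tied_pairs(data: PairedSurvivalData) -> tuple[PairedSurvivalData, int]:
    """Drop subjects whose prior and study *events* are observed at the same time.

    Only event-event ties (``d_prior = d_study = 1`` and ``t_prior == t_study``
    exactly) are removed: their exact two-period likelihood contribution is
    one, so they carry no information, while keeping them would bias the
    plain pairwise likelihood.  Ties involving a censored time are retained.
    No epsilon is applied; callers wanting fuzzy tie detection must pre-round.
    """
    tied = (data.d_prior == 1) & (data.d_study == 1) & (data.t_prior == data.t_study)
    keep = ~tied
    return data.subset(keep), int(tied.sum())
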