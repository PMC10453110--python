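"""Conditional least squares (CLS) estimation for linear-conditional-mean count models.

The conditional mean of every supported family is linear in the parameters,

    E[Y_t | past] = sum_{j=1}^{p} phi_j Y_{t-j} + lambda,

so the CLS estimator minimizing S(theta) = sum_t (Y_t - E[Y_t|past])^2 solves the
normal equations of an ordinary regression of Y_t on its first p lags and a
constant.  A candidate model m is a subset of the lags (the innovation-mean term
lambda is always included); its CLS fit constrains the excluded coefficients to
zero and is reported padded back to the full dimension p+1.

The estimating-equation vector at time t is

    Psi_t(theta) = u_t(theta) * (Y_{t-1}, ..., Y_{t-p}, 1)',   u_t = Y_t - E[Y_t|past],

whose per-coordinate sums vanish at the unrestricted CLS solution.  The CLS
asymptotic covariance is the sandwich (1/n) V^{-1} W V^{-1} with
V = (1/n) sum X_t X_t' and W = (1/n) sum u_t^2 X_t X_t' over the model's own
regressors (the conditional mean is linear, so the second-derivative term in V
vanishes identically).

All candidates share the common estimation window t = p_max+1 .. T so that their
H statistics are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Tuple, Union

import numpy as np

from .simulators import CountSeries

__all__ = [
    "DegenerateSeriesError",
    "LagModel",
    "CLSFit",
    "build_design",
    "cls_fit",
    "psi_matrix",
    "sandwich_covariance",
]

#: condition number beyond which a pseudo-inverse replaces the direct solve
COND_LIMIT = 1e12


class DegenerateSeriesError(ValueError):
    """Raised when the data cannot identify a candidate's parameters at all
    (e.g. a constant series makes every lag column collinear with the intercept)."""


@dataclass(frozen=True)
class LagModel:
    """A candidate model: a subset of the lags {1..p_max}; lambda is always included."""

    lags: Tuple[int, ...]
    p_max: int

    def __post_init__(self) -> None:
        if self.p_max < 1:
            raise ValueError("p_max must be >= 1")
        lags = tuple(sorted(set(int(j) for j in self.lags)))
        if lags and (lags[0] < 1 or lags[-1] > self.p_max):
            raise ValueError(f"lags must lie in 1..{self.p_max}, got {lags}")
        object.__setattr__(self, "lags", lags)

    @property
    def dim(self) -> int:
        """|m|: number of free parameters, counting the lambda term."""
        return len(self.lags) + 1

    @property
    def label(self) -> str:
        """Short human/CSV label: 'iid' or comma-joined lags like '1,3'."""
        return "iid" if not self.lags else ",".join(str(j) for j in self.lags)

    def column_indices(self) -> list:
        """0-based columns of this model in the full design (lags then intercept)."""
        return [j - 1 for j in self.lags] + [self.p_max]


@dataclass(frozen=True)
class CLSFit:
    """A constrained CLS fit, padded to the full parameter dimension.

    ``theta`` has length p_max + 1: thinning-coefficient estimates at the
    model's lags, exact zeros elsewhere, and the innovation-mean estimate last.
    ``score_sum`` and ``psi_outer`` are sum_t Psi_t and sum_t Psi_t Psi_t'
    evaluated at ``theta`` over the common window; ``cov`` is the sandwich
    covariance of the |m| free parameters (order: lags ascending, then lambda).
    """

    model: LagModel
    theta: np.ndarray
    n_used: int
    residuals: np.ndarray
    score_sum: np.ndarray
    psi_outer: np.ndarray
    cov: np.ndarray
    objective: float
    negative_estimates: bool

    @property
    def phi(self) -> np.ndarray:
        return self.theta[:-1]

    @property
    def lam(self) -> float:
        return float(self.theta[-1])

    @property
    def standard_errors(self) -> np.ndarray:
        """SEs of the free parameters (lags ascending, lambda last)."""
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def to_dict(self) -> dict:
        se = self.standard_errors
        return {
            "lags": list(self.model.lags),
            "p_max": self.model.p_max,
            "phi": {int(j): float(self.theta[j - 1]) for j in self.model.lags},
            "phi_se": {int(j): float(se[i]) for i, j in enumerate(self.model.lags)},
            "lambda": self.lam,
            "lambda_se": float(se[-1]),
            "n_used": int(self.n_used),
            "objective": float(self.objective),
            "negative_estimates": bool(self.negative_estimates),
        }


SeriesLike = Union[CountSeries, np.ndarray, Iterable[float]]


def _series_values(series: SeriesLike) -> np.ndarray:
    if isinstance(series, CountSeries):
        return np.asarray(series.values, dtype=float)
    return np.asarray(series, dtype=float)


def build_design(series: SeriesLike, p_max: int) -> Tuple[np.ndarray, np.ndarray]:
    """Regression form of the conditional mean over the window t = p_max+1 .. T.

    Returns ``(y, X)`` with one row per window time point; the columns of X are
    (Y_{t-1}, ..., Y_{t-p_max}, 1) and y holds the responses Y_t.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1 (at least one lag column required)")
    v = _series_values(series)
    T = v.size
    if T < p_max + 2:
        raise ValueError(
            f"series too short for p_max={p_max}: need at least {p_max + 2} observations, got {T}"
        )
    n = T - p_max
    X = np.empty((n, p_max + 1))
    for j in range(1, p_max + 1):
        X[:, j - 1] = v[p_max - j : T - j]
    X[:, -1] = 1.0
    return v[p_max:].copy(), X


def _solve_spd(A: np.ndarray, b: np.ndarray, what: str) -> np.ndarray:
    """Solve A x = b for symmetric PSD A, falling back to pinv when ill-conditioned."""
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        warnings.warn(f"{what} ill-conditioned (cond={cond:.3g}); using pseudo-inverse", RuntimeWarning)
        return np.linalg.pinv(A) @ b
    return np.linalg.solve(A, b)


def cls_fit(series: SeriesLike, model: LagModel) -> CLSFit:
    """Constrained CLS fit of ``model``: exact normal-equation solution on the
    model's lag columns plus the intercept, padded to the full dimension.

    Estimates are unconstrained (negative values are legal and flagged via
    ``negative_estimates``).  A rank-deficient restricted design is resolved by
    the minimum-norm least-squares solution with a warning; a constant series is
    rejected for any model with lag terms.
    """
    y, X = build_design(series, model.p_max)
    v = _series_values(series)
    if model.lags and np.ptp(v) == 0:
        raise DegenerateSeriesError(
            "constant series: lag columns are collinear with the intercept; "
            "only the i.i.d. (intercept-only) model is identifiable"
        )
    cols = model.column_indices()
    Xm = X[:, cols]
    beta, _, rank, sv = np.linalg.lstsq(Xm, y, rcond=None)
    if rank < Xm.shape[1]:
        warnings.warn(
            f"rank-deficient design for model {model.label!r}; minimum-norm CLS solution used",
            RuntimeWarning,
        )
    theta = np.zeros(model.p_max + 1)
    theta[cols] = beta
    u = y - Xm @ beta
    Psi = u[:, None] * X
    score_sum = Psi.sum(axis=0)
    psi_outer = Psi.T @ Psi
    n = y.size
    cov = _sandwich(Xm, u, n)
    return CLSFit(
        model=model,
        theta=theta,
        n_used=n,
        residuals=u,
        score_sum=score_sum,
        psi_outer=psi_outer,
        cov=cov,
        objective=float(u @ u),
        negative_estimates=bool(np.any(beta[:-1] < 0)),
    )


def _sandwich(Xm: np.ndarray, u: np.ndarray, n: int) -> np.ndarray:
    V = Xm.T @ Xm / n
    W = (Xm * (u**2)[:, None]).T @ Xm / n
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        warnings.warn(
            f"singular/ill-conditioned V in sandwich covariance (cond={cond:.3g}); using pseudo-inverse",
            RuntimeWarning,
        )
        Vinv = np.linalg.pinv(V)
    else:
        Vinv = np.linalg.inv(V)
    cov = Vinv @ W @ Vinv / n
    return 0.5 * (cov + cov.T)


def psi_matrix(theta: np.ndarray, series: SeriesLike, p_max: int) -> np.ndarray:
    """Rows Psi_t = u_t(theta) * (Y_{t-1}, ..., Y_{t-p_max}, 1) over the common window.

    ``theta`` must be the full (p_max+1)-dimensional padded parameter vector,
    innovation mean last.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (p_max + 1,):
        raise ValueError(f"theta must have length p_max + 1 = {p_max + 1}")
    y, X = build_design(series, p_max)
    u = y - X @ theta
    return u[:, None] * X


def sandwich_covariance(fit: CLSFit, series: SeriesLike) -> np.ndarray:
    """Sandwich covariance (1/n) V^-1 W V^-1 of ``fit``'s free parameters.

    Recomputed from the data; equal to ``fit.cov``.  Standard errors are the
    square roots of the diagonal.
    """
    _, X = build_design(series, fit.model.p_max)
    Xm = X[:, fit.model.column_indices()]
    return _sandwich(Xm, fit.residuals, fit.n_used)
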