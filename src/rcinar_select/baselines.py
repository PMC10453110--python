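"""Likelihood-based AIC/BIC order selection for the comparison families.

Two families with tractable likelihoods serve as baselines for the
estimating-equation criterion:

* Poisson INARCH: Y_t | past ~ Poisson(phi_0 + sum_{j in m} phi_j Y_{t-j}),
  fitted by conditional maximum likelihood with non-negativity bounds.
* Gaussian AR: Y_t = phi_0 + sum_{j in m} phi_j Y_{t-j} + Z_t with Z_t ~ N(0, sigma^2);
  the Gaussian MLE of the mean parameters is least squares and the profile
  likelihood at sigma_hat^2 = RSS/n has a closed form.

Both condition on the first p_max observations so every candidate uses the
common window t = p_max+1 .. T (n = T - p_max effective observations), and
AIC = 2k - 2 loglik, BIC = k log(n) - 2 loglik with k counting the intercept
plus the included lags (plus one for sigma^2 in the AR family).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .estimation import LagModel, SeriesLike, _series_values, build_design
from .criterion import TIE_TOL, ModelRecord, SelectionResult, enumerate_models
from .simulators import CountSeries

__all__ = [
    "LikelihoodFit",
    "inarch_mle",
    "ar_fit",
    "information_criterion",
    "select_by_ic",
]

#: lower bound keeping the INARCH intensity strictly positive
INARCH_EPS = 1e-8


@dataclass(frozen=True)
class LikelihoodFit:
    """A conditional-likelihood fit of one candidate.

    ``coef`` is ordered (phi_{j1}, ..., phi_{jk}, phi_0) — lags ascending, the
    intercept last, matching the design columns.  ``sigma`` is the innovation
    standard deviation for the AR family (None for INARCH).
    """

    model: LagModel
    coef: np.ndarray
    sigma: Optional[float]
    loglik: float
    k: int
    n: int
    converged: bool

    @property
    def intercept(self) -> float:
        return float(self.coef[-1])

    @property
    def lag_coefs(self) -> np.ndarray:
        return self.coef[:-1]


def inarch_mle(
    series: CountSeries, model: LagModel, nonnegative: bool = False
) -> LikelihoodFit:
    """Conditional Poisson MLE of an INARCH candidate (identity-link intensity).

    Maximizes sum_t [Y_t log(lambda_t) - lambda_t - log(Y_t!)] with
    lambda_t = phi_0 + sum_{j in m} phi_j Y_{t-j}, starting from the CLS
    estimate.  The default fit is *unconstrained* apart from the requirement
    that every fitted intensity stay positive on the sample: clipping
    coefficient estimates at zero would truncate the score of irrelevant lags
    and halve the classical chi-square overfitting rate of AIC/BIC, distorting
    the baseline comparison.  Pass ``nonnegative=True`` for a bound-constrained
    fit (phi_j >= 0, phi_0 >= 1e-8).

    The log-likelihood is concave on the feasible region, so the damped Newton
    iteration with feasibility-preserving step halving converges globally;
    ``converged`` reports whether the gradient criterion was met.
    """
    if isinstance(series, CountSeries) and series.mode != "integer":
        raise ValueError("INARCH likelihood requires an integer count series")
    y, X = build_design(series, model.p_max)
    Xm = X[:, model.column_indices()]
    nlag = len(model.lags)
    const = float(gammaln(y + 1.0).sum())

    def negloglik(beta: np.ndarray):
        lam = Xm @ beta
        if np.any(lam <= 0):
            return np.inf, None
        return float(lam.sum() - y @ np.log(lam) + const), lam

    if nonnegative:
        lower = np.array([0.0] * nlag + [INARCH_EPS])
        beta0, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        beta0 = np.maximum(beta0, np.maximum(lower, 1e-3))
        res = minimize(
            lambda b: (lambda f, lam: (f, Xm.T @ (1.0 - y / lam)))(*negloglik(b)),
            beta0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(lo, None) for lo in lower],
        )
        if not res.success:
            warnings.warn(
                f"INARCH optimizer did not converge for model {model.label!r}: {res.message}",
                RuntimeWarning,
            )
        beta, nll, converged = np.asarray(res.x, float), float(res.fun), bool(res.success)
    else:
        beta, nll, converged = _newton_poisson_identity(y, Xm, negloglik)
        if not converged:
            warnings.warn(
                f"INARCH Newton iteration did not converge for model {model.label!r}",
                RuntimeWarning,
            )
    return LikelihoodFit(
        model=model,
        coef=beta,
        sigma=None,
        loglik=float(-nll),
        k=nlag + 1,
        n=y.size,
        converged=converged,
    )


def _newton_poisson_identity(y, Xm, negloglik, max_iter: int = 100, tol: float = 1e-9):
    """Damped Newton ascent for the identity-link Poisson likelihood.

    Starts at CLS, pulled toward the always-feasible intercept-only fit
    (lambda_t = mean) until all intensities are positive; each Newton step is
    halved until it is feasible and increases the likelihood.
    """
    beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
    fallback = np.zeros(Xm.shape[1])
    fallback[-1] = max(float(y.mean()), INARCH_EPS)
    f, lam = negloglik(beta)
    while not np.isfinite(f):
        beta = 0.5 * (beta + fallback)
        f, lam = negloglik(beta)
        if np.allclose(beta, fallback):
            f, lam = negloglik(fallback)
            beta = fallback
            break
    converged = False
    for _ in range(max_iter):
        g = Xm.T @ (y / lam - 1.0)  # score (we maximize)
        scale = max(1.0, float(np.abs(g).max()))
        if np.abs(g).max() < 1e-8 * max(1.0, abs(f)):
            converged = True
            break
        curv = (Xm * (y / lam**2)[:, None]).T @ Xm
        curv[np.diag_indices_from(curv)] += 1e-12  # guard exact singularity
        try:
            step = np.linalg.solve(curv, g)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(curv) @ g
        t = 1.0
        improved = False
        for _ in range(40):
            f_new, lam_new = negloglik(beta + t * step)
            if np.isfinite(f_new) and f_new <= f:
                beta = beta + t * step
                improved = f - f_new > tol * (1.0 + abs(f))
                f, lam = f_new, lam_new
                break
            t *= 0.5
        if not improved:
            g = Xm.T @ (y / lam - 1.0)
            converged = bool(np.abs(g).max() < 1e-6 * max(1.0, abs(f)))
            break
    return np.asarray(beta, float), float(f), converged


def ar_fit(series: SeriesLike, model: LagModel) -> LikelihoodFit:
    """Gaussian MLE of an AR candidate: least squares plus the profile likelihood.

    sigma_hat^2 = RSS/n and loglik = -(n/2) (log(2 pi sigma_hat^2) + 1); the
    parameter count k includes sigma^2.
    """
    y, X = build_design(series, model.p_max)
    Xm = X[:, model.column_indices()]
    beta, _, rank, _ = np.linalg.lstsq(Xm, y, rcond=None)
    if rank < Xm.shape[1]:
        warnings.warn(
            f"rank-deficient design for AR model {model.label!r}; minimum-norm solution used",
            RuntimeWarning,
        )
    u = y - Xm @ beta
    n = y.size
    sigma2 = float(u @ u) / n
    if sigma2 <= 0.0:
        warnings.warn("zero residual variance; AR log-likelihood is degenerate", RuntimeWarning)
        sigma2 = np.finfo(float).tiny
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return LikelihoodFit(
        model=model,
        coef=np.asarray(beta, dtype=float),
        sigma=float(np.sqrt(sigma2)),
        loglik=float(loglik),
        k=len(model.lags) + 2,  # intercept + lags + sigma^2
        n=n,
        converged=True,
    )


def information_criterion(fit: LikelihoodFit, kind: str) -> float:
    """AIC = 2k - 2 loglik or BIC = k log(n) - 2 loglik."""
    kind = kind.lower()
    if kind == "aic":
        return 2.0 * fit.k - 2.0 * fit.loglik
    if kind == "bic":
        return fit.k * float(np.log(fit.n)) - 2.0 * fit.loglik
    raise ValueError(f"kind must be 'aic' or 'bic', got {kind!r}")


_FITTERS = {"inarch": inarch_mle, "ar": ar_fit}


def likelihood_profile(
    series: SeriesLike, p_max: int, family: str
) -> List[LikelihoodFit]:
    """Fit every candidate once; AIC and BIC selection can share the fits."""
    if family not in _FITTERS:
        raise ValueError(f"family must be 'inarch' or 'ar', got {family!r}")
    fitter = _FITTERS[family]
    return [fitter(series, model) for model in enumerate_models(p_max)]


def select_by_ic(
    series: SeriesLike,
    p_max: int,
    kind: str,
    family: str,
    profile: Optional[List[LikelihoodFit]] = None,
) -> SelectionResult:
    """Minimize AIC or BIC over all candidates of one likelihood family.

    Non-converged fits are excluded with a warning.  Ties are broken exactly as
    for the penalized criterion: smaller model first, then lexicographic.
    """
    if profile is None:
        profile = likelihood_profile(series, p_max, family)
    records = []
    for fit in profile:
        if not fit.converged:
            warnings.warn(
                f"excluding non-converged fit of model {fit.model.label!r} from selection",
                RuntimeWarning,
            )
            continue
        records.append(
            ModelRecord(
                model=fit.model,
                h=None,
                penalty=None,
                criterion=information_criterion(fit, kind),
            )
        )
    if not records:
        raise RuntimeError("no converged candidate fits; cannot select")
    vmin = min(r.criterion for r in records)
    ties = tuple(r.model for r in records if r.criterion <= vmin + TIE_TOL)
    return SelectionResult(records=tuple(records), selected=ties[0], ties=ties)
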