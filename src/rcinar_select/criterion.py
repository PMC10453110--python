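"""The estimating-equation quadratic form H and the penalized model-selection criterion.

For a padded parameter vector theta (excluded lags set to zero) the statistic

    H(theta) = (sum_t Psi_t)' (sum_t Psi_t Psi_t')^{-1} (sum_t Psi_t)

measures how far theta is from solving the full set of p_max+1 estimating
equations.  At the full-model CLS estimate every equation is solved exactly, so
H = 0; at a correctly specified submodel's constrained estimate H stays bounded
in probability, while under misspecification H diverges faster than sqrt(T).
Model selection therefore minimizes

    H(theta_hat_CLS(m)) + P_T * |m|

over all lag subsets m, where |m| counts the included lags plus the
innovation-mean term and the penalty P_T is an increasing, divergent sequence
with P_T = O(sqrt(T)) and log(T)/P_T = O(1).  Built-in penalties: log(T),
T^(1/3), T^(1/5).  Note T^(1/5) < log(T) for all T in [4, 332106], which makes
the T^(1/5) penalty the most lenient — hence best at small T — despite its
faster eventual growth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .estimation import (
    COND_LIMIT,
    CLSFit,
    DegenerateSeriesError,
    LagModel,
    SeriesLike,
    _series_values,
    cls_fit,
    psi_matrix,
)

__all__ = [
    "PenaltySpec",
    "ModelRecord",
    "SelectionResult",
    "h_statistic",
    "h_from_fit",
    "penalty_value",
    "enumerate_models",
    "evaluate_model",
    "select_model",
    "h_profile",
    "select_from_profile",
]

#: criterion values within this absolute tolerance of the minimum count as tied
TIE_TOL = 1e-9

_BUILTIN_PENALTIES = {
    "logT": math.log,
    "T13": lambda T: T ** (1.0 / 3.0),
    "T15": lambda T: T ** 0.2,
}


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty sequence P_T.  ``kind`` in {logT, T13, T15, custom}.

    A custom penalty supplies ``func``; it is sanity-checked by sampling to be
    increasing and divergent over a wide range of T.
    """

    kind: str
    func: Optional[Callable[[int], float]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("logT", "T13", "T15", "custom"):
            raise ValueError(f"unknown penalty kind {self.kind!r}")
        if self.kind == "custom":
            if self.func is None:
                raise ValueError("custom penalty requires func")
            probes = [2, 10, 100, 10_000, 1_000_000, 100_000_000]
            vals = [float(self.func(T)) for T in probes]
            if any(b <= a for a, b in zip(vals, vals[1:])) or vals[-1] <= vals[0] + 1e-12:
                raise ValueError("custom penalty must be increasing and divergent in T")

    def __call__(self, T: int) -> float:
        return penalty_value(T, self)


def _coerce_penalty(penalty: Union[str, PenaltySpec]) -> PenaltySpec:
    if isinstance(penalty, PenaltySpec):
        return penalty
    return PenaltySpec(str(penalty))


def penalty_value(T: int, spec: Union[str, PenaltySpec]) -> float:
    """P_T for the raw series length T (T >= 2)."""
    spec = _coerce_penalty(spec)
    if T < 2:
        raise ValueError(f"penalty requires T >= 2, got {T}")
    fn = spec.func if spec.kind == "custom" else _BUILTIN_PENALTIES[spec.kind]
    return float(fn(T))


def h_statistic(theta: np.ndarray, series: SeriesLike, p_max: int) -> float:
    """H(theta): quadratic form of the full (p_max+1)-dimensional estimating equations.

    Always >= 0; exactly 0 (to numerical precision) at the full-model CLS
    estimate.  A singular sum of outer products triggers a pseudo-inverse with a
    warning; identically-zero Psi rows give H = 0 by convention.
    """
    Psi = psi_matrix(theta, series, p_max)
    return _h_quadratic(Psi.sum(axis=0), Psi.T @ Psi)


def h_from_fit(fit: CLSFit) -> float:
    """H evaluated at a CLS fit's padded estimate, reusing its stored sums."""
    return _h_quadratic(fit.score_sum, fit.psi_outer)


def _h_quadratic(score_sum: np.ndarray, psi_outer: np.ndarray) -> float:
    if not np.any(psi_outer):
        warnings.warn("all estimating-equation rows are zero; H set to 0", RuntimeWarning)
        return 0.0
    cond = np.linalg.cond(psi_outer)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        warnings.warn(
            f"sum of Psi outer products ill-conditioned (cond={cond:.3g}); using pseudo-inverse",
            RuntimeWarning,
        )
        sol = np.linalg.pinv(psi_outer) @ score_sum
    else:
        sol = np.linalg.solve(psi_outer, score_sum)
    return float(max(score_sum @ sol, 0.0))


def enumerate_models(p_max: int) -> List[LagModel]:
    """All 2^p_max lag subsets, ordered by size then lexicographically.

    Each model implicitly includes the innovation-mean term.  The order matches
    the candidate layout used throughout: iid, single lags, pairs, ..., full.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    if p_max > 20:
        raise ValueError("p_max > 20 would enumerate over a million candidates; refusing")
    models: List[LagModel] = []
    for size in range(p_max + 1):
        for lags in combinations(range(1, p_max + 1), size):
            models.append(LagModel(lags, p_max))
    return models


@dataclass(frozen=True)
class ModelRecord:
    """Per-candidate bookkeeping: fit statistic, penalty and their sum."""

    model: LagModel
    h: Optional[float]
    penalty: Optional[float]
    criterion: float

    @property
    def size(self) -> int:
        return self.model.dim


@dataclass(frozen=True)
class SelectionResult:
    """Criterion table over all candidates plus the argmin model.

    ``ties`` lists every model whose criterion value is within ``TIE_TOL`` of
    the minimum (the selected model is the first: smallest |m|, then
    lexicographically smallest lag set).  ``degenerate`` marks selections forced
    to the i.i.d. model because no lag model was identifiable.
    """

    records: Tuple[ModelRecord, ...]
    selected: LagModel
    ties: Tuple[LagModel, ...]
    degenerate: bool = False

    def criterion_table(self) -> dict:
        return {r.model.label: r.criterion for r in self.records}


def evaluate_model(
    series: SeriesLike,
    model: LagModel,
    penalty: Union[str, PenaltySpec],
    fit: Optional[CLSFit] = None,
) -> ModelRecord:
    """Criterion record H(theta_hat(m)) + P_T * |m| for one candidate."""
    if fit is None:
        fit = cls_fit(series, model)
    T = _series_values(series).size
    h = h_from_fit(fit)
    pen = penalty_value(T, penalty) * model.dim
    return ModelRecord(model=model, h=h, penalty=pen, criterion=h + pen)


def h_profile(series: SeriesLike, p_max: int) -> List[Tuple[LagModel, Optional[float]]]:
    """H(theta_hat_CLS(m)) for every candidate, in enumeration order.

    A candidate whose fit is degenerate is recorded with ``None``.  Computing
    the profile once lets several penalties share the same fits.
    """
    out: List[Tuple[LagModel, Optional[float]]] = []
    for model in enumerate_models(p_max):
        try:
            out.append((model, h_from_fit(cls_fit(series, model))))
        except DegenerateSeriesError:
            out.append((model, None))
    return out


def select_from_profile(
    profile: Sequence[Tuple[LagModel, Optional[float]]],
    T: int,
    penalty: Union[str, PenaltySpec],
) -> SelectionResult:
    """Apply one penalty to a precomputed H profile and take the argmin."""
    pT = penalty_value(T, penalty)
    records = []
    degenerate_models = 0
    for model, h in profile:
        if h is None:
            degenerate_models += 1
            continue
        pen = pT * model.dim
        records.append(ModelRecord(model=model, h=h, penalty=pen, criterion=h + pen))
    if not records:  # cannot happen: the i.i.d. model always fits
        raise DegenerateSeriesError("no candidate model could be fitted")
    all_degenerate = degenerate_models == len(profile) - len(records) and len(records) == 1
    vmin = min(r.criterion for r in records)
    ties = tuple(r.model for r in records if r.criterion <= vmin + TIE_TOL)
    return SelectionResult(
        records=tuple(records),
        selected=ties[0],
        ties=ties,
        degenerate=bool(degenerate_models and all_degenerate),
    )


def select_model(
    series: SeriesLike,
    p_max: int,
    penalty: Union[str, PenaltySpec],
) -> SelectionResult:
    """Minimize H(theta_hat(m)) + P_T |m| over all 2^p_max candidates.

    Ties within ``TIE_TOL`` are broken toward the smaller model, then the
    lexicographically smaller lag set.  If no lag model is identifiable
    (constant data) the i.i.d. model is returned with ``degenerate=True``.
    """
    T = _series_values(series).size
    return select_from_profile(h_profile(series, p_max), T, penalty)
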