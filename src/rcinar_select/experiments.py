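"""Monte Carlo harness, selection-frequency tables, sweeps, and real-data I/O.

The harness replicates the standard simulation protocol for evaluating order
selection: simulate R independent series from a configured data-generating
process, run a selector on each (the estimating-equation criterion under one
or more penalties, or likelihood AIC/BIC for the comparison families), and
tabulate the frequency with which each candidate lag set is chosen.

Reproducibility: replicate r of the cell (T, variant, criterion) draws from the
dedicated stream ``default_rng([base_seed, T, variant_index, criterion_index, r])``,
so cells are mutually independent, replicates are individually re-runnable, and
parallel or serial execution gives identical tables.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .baselines import likelihood_profile, select_by_ic
from .criterion import (
    PenaltySpec,
    SelectionResult,
    enumerate_models,
    h_profile,
    penalty_value,
    select_from_profile,
)
from .estimation import LagModel, cls_fit
from .simulators import (
    CoefficientSpec,
    CountSeries,
    DGPConfig,
    InnovationSpec,
    simulate,
)

__all__ = [
    "ExperimentConfig",
    "run_cell",
    "run_table",
    "sweep_phi3",
    "read_count_csv",
    "report_fit",
    "dgp_from_dict",
    "experiment_from_dict",
]

logger = logging.getLogger("rcinar_select")

#: the three penalty settings studied throughout
DEFAULT_PENALIZED = ("H+T13", "H+logT", "H+T15")


def _parse_criterion(name: str) -> Tuple[str, str]:
    """'H+T13' -> ('penalized', 'T13'); 'AIC' -> ('ic', 'aic')."""
    if name.upper() in ("AIC", "BIC"):
        return "ic", name.lower()
    if name.startswith("H+"):
        kind = name[2:]
        PenaltySpec(kind)  # validates
        return "penalized", kind
    raise ValueError(f"unknown criterion {name!r}; use 'H+logT', 'H+T13', 'H+T15', 'AIC' or 'BIC'")


@dataclass(frozen=True)
class ExperimentConfig:
    """Specification of a selection-frequency experiment (one table).

    ``variants`` maps a display name (e.g. "Fixed", "Uniform", "Beta") to the
    per-lag coefficient specs of a DGP; every (T, variant, criterion) triple is
    one table cell evaluated over ``replicates`` independent series.
    """

    family: str
    p_max: int
    variants: Mapping[str, Tuple[CoefficientSpec, ...]]
    T_values: Tuple[int, ...]
    criteria: Tuple[str, ...] = DEFAULT_PENALIZED
    replicates: int = 1000
    base_seed: int = 0
    innovation: Optional[InnovationSpec] = None
    intercept: float = 0.0
    burn_in: int = 500
    true_lags: Tuple[int, ...] = (1, 3)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(self, "variants", dict(self.variants))
        object.__setattr__(self, "T_values", tuple(int(t) for t in self.T_values))
        object.__setattr__(self, "criteria", tuple(self.criteria))
        object.__setattr__(self, "true_lags", tuple(self.true_lags))
        for c in self.criteria:
            mode, _ = _parse_criterion(c)
            if mode == "ic" and self.family not in ("inarch", "ar"):
                raise ValueError("AIC/BIC baselines require an 'inarch' or 'ar' family")

    def dgp_for(self, variant: str, T: int) -> DGPConfig:
        return DGPConfig(
            family=self.family,
            p_max=self.p_max,
            coefficients=self.variants[variant],
            T=T,
            innovation=self.innovation,
            intercept=self.intercept,
            burn_in=self.burn_in,
        )


def _cell_rng(config: ExperimentConfig, T: int, variant: str, criterion: str, r: int):
    vi = list(config.variants).index(variant)
    ci = list(config.criteria).index(criterion) if criterion in config.criteria else 0
    return np.random.default_rng([config.base_seed, T, vi, ci, r])


def run_cell(
    config: ExperimentConfig, T: int, variant: str, criterion: str
) -> Dict[str, float]:
    """One table cell: selection frequencies over ``config.replicates`` series.

    Returns a row keyed by candidate labels ('iid', '1', ..., '1,2,3'), summing
    to 1, plus a ``degenerate`` diagnostic count (replicates on which selection
    collapsed to the i.i.d. model for lack of identifiable lag candidates —
    counted, never dropped or resampled).
    """
    mode, which = _parse_criterion(criterion)
    dgp_T = config.dgp_for(variant, T)
    counts: Counter = Counter()
    degenerate = 0
    for r in range(config.replicates):
        rng = _cell_rng(config, T, variant, criterion, r)
        series = simulate(dgp_T, rng)
        if mode == "penalized":
            sel = select_from_profile(h_profile(series, config.p_max), T, which)
        else:
            sel = select_by_ic(series, config.p_max, which, config.family)
        counts[sel.selected.lags] += 1
        degenerate += int(sel.degenerate)
    R = config.replicates
    row = {m.label: counts.get(m.lags, 0) / R for m in enumerate_models(config.p_max)}
    row["degenerate"] = degenerate
    logger.info(
        "cell T=%d variant=%s criterion=%s base_seed=%d: done (%d replicates, %d degenerate)",
        T, variant, criterion, config.base_seed, R, degenerate,
    )
    return row


def run_table(config: ExperimentConfig) -> pd.DataFrame:
    """Full selection-frequency table: one row per (T, variant, criterion).

    Columns follow the canonical candidate order (iid, single lags, pairs, ...,
    full model) plus the degenerate-replicate diagnostic.
    """
    rows = []
    index = []
    for T in config.T_values:
        for variant in config.variants:
            for criterion in config.criteria:
                rows.append(run_cell(config, T, variant, criterion))
                index.append((T, variant, criterion))
    frame = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["T", "variant", "criterion"]))
    cols = [m.label for m in enumerate_models(config.p_max)] + ["degenerate"]
    return frame[cols]


def _respec(template: CoefficientSpec, mean: float) -> CoefficientSpec:
    """A coefficient spec of the template's kind with a new mean (0 -> absent lag)."""
    if mean == 0.0:
        return CoefficientSpec.fixed(0.0)
    if template.kind == "beta":
        return CoefficientSpec.beta(mean, a=template.a if template.a else 4.0)
    if template.kind == "uniform":
        return CoefficientSpec.uniform(0.0, 2.0 * mean)
    return CoefficientSpec.fixed(mean)


def sweep_phi3(
    config: ExperimentConfig,
    phi3_grid: Sequence[float],
    T_grid: Sequence[int],
    replicates: Optional[int] = None,
    lag: int = 3,
) -> pd.DataFrame:
    """Accuracy surface over a grid of lag-``lag`` coefficient means and lengths.

    For each (phi3, T, criterion) the reported accuracy is the frequency of
    selecting the *correct* model: the configured ``true_lags`` when phi3 > 0,
    and ``true_lags`` minus the swept lag when phi3 = 0 (a vanished coefficient
    changes which model is true).  The swept coefficient inherits the
    distribution family of the first variant's spec at that lag.  Returns a
    tidy frame with columns phi3, T, criterion, accuracy.
    """
    replicates = replicates or config.replicates
    base_variant = next(iter(config.variants))
    template = dict(config.variants)[base_variant]
    records = []
    for phi3 in phi3_grid:
        coeffs = list(template)
        coeffs[lag - 1] = _respec(template[lag - 1], float(phi3))
        target = tuple(j for j in config.true_lags if j != lag or phi3 > 0)
        point = replace(
            config,
            variants={f"phi{lag}={phi3}": tuple(coeffs)},
            T_values=tuple(int(t) for t in T_grid),
            replicates=replicates,
        )
        for T in T_grid:
            for criterion in config.criteria:
                row = run_cell(point, T, f"phi{lag}={phi3}", criterion)
                label = LagModel(target, config.p_max).label
                records.append(
                    {"phi3": float(phi3), "T": int(T), "criterion": criterion, "accuracy": row[label]}
                )
    return pd.DataFrame.from_records(records)


def read_count_csv(path: Union[str, Path], real: bool = False) -> CountSeries:
    """Read a univariate series from one-column CSV or whitespace-separated text.

    An optional single header line is skipped.  Rows are taken in file order
    (time order); multiple values on one line are read left to right.  Negative
    or non-integer entries are rejected unless ``real=True``.
    """
    path = Path(path)
    values: List[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.replace(",", " ").split()
            if not tokens:
                continue
            parsed = []
            for tok in tokens:
                try:
                    parsed.append(float(tok))
                except ValueError:
                    if lineno == 1 and not values:
                        parsed = None  # header line
                        break
                    raise ValueError(f"{path}:{lineno}: non-numeric entry {tok!r}")
            if parsed is None:
                continue
            if not real:
                for val, tok in zip(parsed, tokens):
                    if val < 0:
                        raise ValueError(f"{path}:{lineno}: negative count {tok!r}")
                    if val != int(val):
                        raise ValueError(
                            f"{path}:{lineno}: non-integer count {tok!r} (use --real for continuous data)"
                        )
            values.extend(parsed)
    if not values:
        raise ValueError(f"{path}: no data found")
    return CountSeries(np.asarray(values), mode="real" if real else "integer")


def report_fit(
    series: CountSeries,
    selected: LagModel,
    penalties: Sequence[str] = ("T13", "logT", "T15"),
) -> dict:
    """JSON-serializable report: selected-model CLS estimates with sandwich
    standard errors, plus the per-candidate criterion table under each penalty
    (candidates in canonical order)."""
    fit = cls_fit(series, selected)
    T = len(series)
    profile = h_profile(series, selected.p_max)
    tables = {}
    for pen in penalties:
        result = select_from_profile(profile, T, pen)
        tables[pen] = {r.model.label: round(float(r.criterion), 6) for r in result.records}
    return {
        "T": T,
        "selected": fit.to_dict(),
        "criteria": tables,
    }


# ---------------------------------------------------------------------------
# config-file plumbing (YAML/JSON dictionaries -> dataclasses)

_COEF_KEYS = {"kind", "mean", "lo", "hi", "a", "b", "lag"}


def coefficient_from_dict(d: Mapping) -> CoefficientSpec:
    kind = d.get("kind", "fixed")
    if kind == "fixed":
        return CoefficientSpec.fixed(d.get("mean", 0.0))
    if kind == "uniform":
        return CoefficientSpec.uniform(d["lo"], d["hi"])
    if kind == "beta":
        return CoefficientSpec.beta(d["mean"], a=d.get("a", 4.0))
    raise ValueError(f"unknown coefficient kind {kind!r}")


def innovation_from_dict(d: Optional[Mapping]) -> Optional[InnovationSpec]:
    if d is None:
        return None
    kind = d["kind"]
    if kind == "poisson":
        return InnovationSpec.poisson(d["mean"])
    if kind in ("geometric", "geom"):
        return InnovationSpec.geometric(d["mean"])
    if kind == "uniform_discrete":
        return InnovationSpec.uniform_discrete(d["support"])
    if kind == "gaussian":
        return InnovationSpec.gaussian(d["sd"])
    if kind == "uniform_continuous":
        return InnovationSpec.uniform_continuous(d["bound"])
    raise ValueError(f"unknown innovation kind {kind!r}")


def _coefficients_from_list(items: Sequence[Mapping], p_max: int) -> Tuple[CoefficientSpec, ...]:
    """List of per-lag dicts (with explicit 'lag' keys) -> dense tuple; absent lags are fixed 0."""
    specs = [CoefficientSpec.fixed(0.0)] * p_max
    for item in items:
        lag = int(item["lag"])
        if not (1 <= lag <= p_max):
            raise ValueError(f"coefficient lag {lag} outside 1..{p_max}")
        specs[lag - 1] = coefficient_from_dict(item)
    return tuple(specs)


def dgp_from_dict(d: Mapping) -> DGPConfig:
    """Build a DGPConfig from a parsed YAML/JSON mapping."""
    p_max = int(d["p_max"])
    return DGPConfig(
        family=d["family"],
        p_max=p_max,
        coefficients=_coefficients_from_list(d.get("coefficients", []), p_max),
        T=int(d["T"]),
        innovation=innovation_from_dict(d.get("innovation")),
        intercept=float(d.get("intercept", 0.0)),
        burn_in=int(d.get("burn_in", 500)),
    )


def experiment_from_dict(d: Mapping) -> ExperimentConfig:
    """Build an ExperimentConfig from a parsed YAML/JSON mapping."""
    p_max = int(d["p_max"])
    variants = {
        name: _coefficients_from_list(items, p_max)
        for name, items in d["variants"].items()
    }
    return ExperimentConfig(
        family=d["family"],
        p_max=p_max,
        variants=variants,
        T_values=tuple(d["T_values"]),
        criteria=tuple(d.get("criteria", DEFAULT_PENALIZED)),
        replicates=int(d.get("replicates", 1000)),
        base_seed=int(d.get("base_seed", 0)),
        innovation=innovation_from_dict(d.get("innovation")),
        intercept=float(d.get("intercept", 0.0)),
        burn_in=int(d.get("burn_in", 500)),
        true_lags=tuple(d.get("true_lags", (1, 3))),
    )
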