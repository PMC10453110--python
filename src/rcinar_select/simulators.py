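"""Simulators for integer-valued and continuous autoregressive data-generating processes.

Three families are supported, all sharing the linear conditional-mean form
``E[Y_t | past] = phi_0 + sum_j phi_j Y_{t-j} + lambda``:

* **RCINAR(p)** — random-coefficient integer-valued autoregression built from the
  binomial thinning operator ``phi ∘ Y = sum_{i=1}^{Y} Bernoulli(phi)``.  Each lag's
  thinning probability ``phi_j(t)`` is redrawn independently at every time step from a
  distribution on [0, 1) with mean ``phi_j``; innovations are i.i.d. non-negative
  integers with mean ``lambda``.
* **INARCH(p)** — conditionally Poisson counts with intensity
  ``lambda_t = phi_0 + sum_j phi_j Y_{t-j}`` (constant coefficients).
* **AR(p)** — ordinary real-valued autoregression with mean-zero innovations
  (Gaussian or continuous-uniform).

All simulators start from zeros, run a burn-in that is discarded, and are
deterministic given a :class:`numpy.random.Generator` (or an integer seed).
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "CountSeries",
    "CoefficientSpec",
    "InnovationSpec",
    "DGPConfig",
    "binomial_thinning",
    "simulate_rcinar",
    "simulate_inarch",
    "simulate_ar",
    "simulate",
]

RngLike = Union[np.random.Generator, int, None]

#: families understood by :func:`simulate`
FAMILIES = ("rcinar", "inarch", "ar")

#: default number of discarded warm-up steps; long enough for the geometric
#: forgetting rate implied by sum(phi_j) < 1 to wash out the all-zero start.
DEFAULT_BURN_IN = 500


def as_rng(rng: RngLike) -> np.random.Generator:
    """Coerce an int seed / None / Generator into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class CountSeries:
    """An ordered univariate series, integer counts or real-valued.

    Parameters
    ----------
    values : array-like
        Observations in time order.
    mode : {"integer", "real"}
        ``"integer"`` enforces non-negative integer entries (count data);
        ``"real"`` stores floats (continuous AR data).
    """

    values: np.ndarray
    mode: str = "integer"

    def __post_init__(self) -> None:
        if self.mode not in ("integer", "real"):
            raise ValueError(f"mode must be 'integer' or 'real', got {self.mode!r}")
        v = np.asarray(self.values)
        if v.ndim != 1:
            raise ValueError("series must be one-dimensional")
        if self.mode == "integer":
            if not np.issubdtype(v.dtype, np.integer):
                vf = np.asarray(v, dtype=float)
                if not np.all(np.isfinite(vf)) or not np.all(vf == np.floor(vf)):
                    raise ValueError("integer-mode series must contain integers")
                v = vf.astype(np.int64)
            else:
                v = v.astype(np.int64)
            if v.size and int(v.min()) < 0:
                raise ValueError("integer-mode series must be non-negative")
        else:
            v = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError("real-mode series must be finite")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


@dataclass(frozen=True)
class CoefficientSpec:
    """Distribution of a thinning/autoregressive coefficient on [0, 1).

    ``kind="fixed"`` draws the constant ``mean``; ``kind="uniform"`` draws from
    U[lo, hi] with mean (lo+hi)/2; ``kind="beta"`` draws from Beta(a, b) with
    mean a/(a+b).  The declared mean must agree with the distribution mean to
    1e-12 — use the classmethod constructors, which guarantee this.
    """

    kind: str
    mean: float
    lo: Optional[float] = None
    hi: Optional[float] = None
    a: Optional[float] = None
    b: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "uniform", "beta"):
            raise ValueError(f"unknown coefficient kind {self.kind!r}")
        if not (0.0 <= self.mean < 1.0):
            raise ValueError("coefficient mean must lie in [0, 1)")
        if self.kind == "uniform":
            if self.lo is None or self.hi is None:
                raise ValueError("uniform coefficient needs lo and hi")
            if not (0.0 <= self.lo <= self.hi < 1.0):
                raise ValueError("uniform support must satisfy 0 <= lo <= hi < 1")
            if abs(self.mean - 0.5 * (self.lo + self.hi)) > 1e-12:
                raise ValueError("declared mean does not match (lo+hi)/2")
        elif self.kind == "beta":
            if self.a is None or self.b is None or self.a <= 0 or self.b <= 0:
                raise ValueError("beta coefficient needs positive shapes a, b")
            if abs(self.mean - self.a / (self.a + self.b)) > 1e-12:
                raise ValueError("declared mean does not match a/(a+b)")

    @classmethod
    def fixed(cls, mean: float) -> "CoefficientSpec":
        return cls("fixed", float(mean))

    @classmethod
    def uniform(cls, lo: float, hi: float) -> "CoefficientSpec":
        return cls("uniform", 0.5 * (float(lo) + float(hi)), lo=float(lo), hi=float(hi))

    @classmethod
    def beta(cls, mean: float, a: float = 4.0) -> "CoefficientSpec":
        # mean = a/(a+b)  =>  b = a (1 - mean) / mean, with the first shape held fixed
        if not (0.0 < mean < 1.0):
            raise ValueError("beta mean must lie in (0, 1)")
        b = a * (1.0 - mean) / mean
        return cls("beta", float(mean), a=float(a), b=float(b))

    @property
    def is_zero(self) -> bool:
        """True for the degenerate 'lag absent' spec (fixed 0)."""
        return self.kind == "fixed" and self.mean == 0.0

    def draw(self, rng: np.random.Generator, size: Optional[int] = None):
        if self.kind == "fixed":
            return self.mean if size is None else np.full(size, self.mean)
        if self.kind == "uniform":
            return rng.uniform(self.lo, self.hi, size)
        return rng.beta(self.a, self.b, size)


#: innovation kinds producing non-negative integers (count families)
COUNT_INNOVATIONS = ("poisson", "geometric", "uniform_discrete")
#: mean-zero innovation kinds for the continuous AR family
AR_INNOVATIONS = ("gaussian", "uniform_continuous")


@dataclass(frozen=True)
class InnovationSpec:
    """Innovation distribution Z_t.

    Count kinds (``poisson``, ``geometric``, ``uniform_discrete``) generate
    non-negative integers with the declared ``mean``.  The geometric law lives
    on {0, 1, 2, ...} with success probability p = 1/(1+mean), so its mean is
    (1-p)/p.  AR kinds (``gaussian``, ``uniform_continuous``) have mean zero;
    ``sd`` sets the Gaussian scale and ``bound`` the uniform half-width.
    """

    kind: str
    mean: float = 0.0
    sd: Optional[float] = None
    bound: Optional[float] = None
    support: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.kind not in COUNT_INNOVATIONS + AR_INNOVATIONS:
            raise ValueError(f"unknown innovation kind {self.kind!r}")
        if self.kind in ("poisson", "geometric") and self.mean <= 0:
            raise ValueError("count innovation mean must be positive")
        if self.kind == "uniform_discrete":
            sup = self.support
            if not sup or any(
                (not isinstance(s, numbers.Integral)) or s < 0 for s in sup
            ):
                raise ValueError("uniform_discrete needs a non-negative integer support")
            object.__setattr__(self, "support", tuple(int(s) for s in sup))
            object.__setattr__(self, "mean", float(np.mean(self.support)))
        if self.kind == "gaussian" and (self.sd is None or self.sd <= 0):
            raise ValueError("gaussian innovation needs a positive sd")
        if self.kind == "uniform_continuous" and (self.bound is None or self.bound <= 0):
            raise ValueError("uniform_continuous innovation needs a positive bound")
        if self.kind in AR_INNOVATIONS:
            object.__setattr__(self, "mean", 0.0)

    @classmethod
    def poisson(cls, mean: float) -> "InnovationSpec":
        return cls("poisson", mean=float(mean))

    @classmethod
    def geometric(cls, mean: float) -> "InnovationSpec":
        return cls("geometric", mean=float(mean))

    @classmethod
    def uniform_discrete(cls, support: Sequence[int]) -> "InnovationSpec":
        return cls("uniform_discrete", support=tuple(support))

    @classmethod
    def gaussian(cls, sd: float) -> "InnovationSpec":
        return cls("gaussian", sd=float(sd))

    @classmethod
    def uniform_continuous(cls, bound: float) -> "InnovationSpec":
        return cls("uniform_continuous", bound=float(bound))

    @property
    def is_count(self) -> bool:
        return self.kind in COUNT_INNOVATIONS

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "poisson":
            return rng.poisson(self.mean, size)
        if self.kind == "geometric":
            # numpy's geometric lives on {1, 2, ...}; shift to {0, 1, ...}
            p = 1.0 / (1.0 + self.mean)
            return rng.geometric(p, size) - 1
        if self.kind == "uniform_discrete":
            return rng.choice(np.asarray(self.support, dtype=np.int64), size)
        if self.kind == "gaussian":
            return rng.normal(0.0, self.sd, size)
        return rng.uniform(-self.bound, self.bound, size)


@dataclass(frozen=True)
class DGPConfig:
    """Full specification of a data-generating process.

    ``coefficients`` has one :class:`CoefficientSpec` per lag 1..p_max; absent
    lags are represented as ``CoefficientSpec.fixed(0)``.  ``intercept`` is the
    INARCH/AR constant term (must stay 0 for RCINAR, whose constant mean comes
    from the innovation mean ``lambda``).  Stationarity requires the coefficient
    means to sum below 1.
    """

    family: str
    p_max: int
    coefficients: Tuple[CoefficientSpec, ...]
    T: int
    innovation: Optional[InnovationSpec] = None
    intercept: float = 0.0
    burn_in: int = DEFAULT_BURN_IN

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.p_max < 1:
            raise ValueError("p_max must be >= 1")
        object.__setattr__(self, "coefficients", tuple(self.coefficients))
        if len(self.coefficients) != self.p_max:
            raise ValueError("need one CoefficientSpec per lag 1..p_max")
        if self.T < self.p_max + 2:
            raise ValueError(f"T must be at least p_max + 2 = {self.p_max + 2}")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        total = sum(c.mean for c in self.coefficients)
        if total >= 1.0:
            raise ValueError(
                f"non-stationary configuration: coefficient means sum to {total} >= 1"
            )
        if self.family == "rcinar":
            if self.innovation is None or not self.innovation.is_count:
                raise ValueError("rcinar requires a count innovation (poisson/geometric/uniform_discrete)")
            if self.intercept != 0.0:
                raise ValueError("rcinar has no separate intercept; use the innovation mean")
        elif self.family == "inarch":
            if self.intercept <= 0.0:
                raise ValueError("inarch requires intercept phi_0 > 0")
            if any(c.kind != "fixed" for c in self.coefficients):
                raise ValueError("inarch coefficients must be fixed constants")
            if any(c.mean < 0 for c in self.coefficients):
                raise ValueError("inarch coefficients must be non-negative")
        else:  # ar
            if self.innovation is None or self.innovation.is_count:
                raise ValueError("ar requires a mean-zero innovation (gaussian/uniform_continuous)")

    @property
    def coefficient_means(self) -> np.ndarray:
        return np.array([c.mean for c in self.coefficients])


def binomial_thinning(phi: float, y: int, rng: RngLike) -> int:
    """Binomial thinning ``phi ∘ y``: the sum of y i.i.d. Bernoulli(phi) trials.

    Returns a draw from Binomial(y, phi); always <= y, and 0 when y = 0 or
    phi = 0.
    """
    if not (0.0 <= phi < 1.0):
        raise ValueError(f"thinning probability must lie in [0, 1), got {phi}")
    if not isinstance(y, numbers.Integral):
        raise ValueError(f"thinning count must be an integer, got {y!r}")
    y = int(y)
    if y < 0:
        raise ValueError(f"thinning count must be non-negative, got {y}")
    return int(as_rng(rng).binomial(y, phi))


def _check_family(config: DGPConfig, family: str) -> None:
    if config.family != family:
        raise ValueError(f"config family is {config.family!r}, expected {family!r}")


def simulate_rcinar(config: DGPConfig, rng: RngLike) -> CountSeries:
    """Simulate an RCINAR(p) series.

    At each step every active lag j gets a fresh coefficient draw phi_j(t)
    (independent across t and across lags), each past count is thinned
    independently, and an innovation is added.  The all-zero start plus
    ``config.burn_in`` discarded steps give an approximately stationary sample.
    """
    _check_family(config, "rcinar")
    rng = as_rng(rng)
    p = config.p_max
    n = config.burn_in + config.T
    z = config.innovation.draw(rng, n)
    active = [j for j in range(1, p + 1) if not config.coefficients[j - 1].is_zero]
    # pre-draw the per-step coefficients for every active lag
    phis = {j: np.asarray(config.coefficients[j - 1].draw(rng, n)) for j in active}
    y = np.zeros(n + p, dtype=np.int64)
    binom = rng.binomial
    for t in range(n):
        base = t + p
        acc = int(z[t])
        for j in active:
            prev = y[base - j]
            if prev:
                acc += int(binom(prev, phis[j][t]))
        y[base] = acc
    return CountSeries(y[p + config.burn_in:].copy(), mode="integer")


def simulate_inarch(config: DGPConfig, rng: RngLike) -> CountSeries:
    """Simulate a Poisson INARCH(p) series: Y_t | past ~ Poisson(phi_0 + sum phi_j Y_{t-j})."""
    _check_family(config, "inarch")
    rng = as_rng(rng)
    p = config.p_max
    n = config.burn_in + config.T
    means = config.coefficient_means
    active = [j for j in range(1, p + 1) if means[j - 1] > 0]
    y = np.zeros(n + p, dtype=np.int64)
    poisson = rng.poisson
    for t in range(n):
        base = t + p
        lam = config.intercept
        for j in active:
            lam += means[j - 1] * y[base - j]
        y[base] = poisson(lam)
    return CountSeries(y[p + config.burn_in:].copy(), mode="integer")


def simulate_ar(config: DGPConfig, rng: RngLike) -> CountSeries:
    """Simulate a real-valued AR(p) series Y_t = phi_0 + sum phi_j Y_{t-j} + Z_t."""
    _check_family(config, "ar")
    rng = as_rng(rng)
    p = config.p_max
    n = config.burn_in + config.T
    z = config.innovation.draw(rng, n)
    means = config.coefficient_means
    active = [j for j in range(1, p + 1) if means[j - 1] != 0]
    y = np.zeros(n + p, dtype=float)
    for t in range(n):
        base = t + p
        acc = config.intercept + z[t]
        for j in active:
            acc += means[j - 1] * y[base - j]
        y[base] = acc
    return CountSeries(y[p + config.burn_in:].copy(), mode="real")


_SIMULATORS = {
    "rcinar": simulate_rcinar,
    "inarch": simulate_inarch,
    "ar": simulate_ar,
}


def simulate(config: DGPConfig, rng: RngLike) -> CountSeries:
    """Dispatch to the simulator for ``config.family``."""
    return _SIMULATORS[config.family](config, rng)
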