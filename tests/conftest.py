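import numpy as np
import pytest

from rcinar_select import (
    CoefficientSpec,
    DGPConfig,
    InnovationSpec,
    simulate,
)

FIXED_COEFFS = (
    CoefficientSpec.fixed(0.4),
    CoefficientSpec.fixed(0.0),
    CoefficientSpec.fixed(0.2),
)


@pytest.fixture(scope="session")
def fixed_rcinar_dgp():
    """The workhorse design: RCINAR(3), constant coefficients (0.4, 0, 0.2), Poisson(2)."""
    def make(T, **kw):
        return DGPConfig(
            family="rcinar",
            p_max=3,
            coefficients=FIXED_COEFFS,
            T=T,
            innovation=InnovationSpec.poisson(2.0),
            **kw,
        )
    return make


@pytest.fixture(scope="session")
def rcinar_series(fixed_rcinar_dgp):
    """One medium-length simulated series reused across read-only tests."""
    return simulate(fixed_rcinar_dgp(1000), np.random.default_rng(2024))


def mc_tolerance(f_hat: float, reps: int, f_ref: float, ref_reps: int = 1000) -> float:
    """3x the two-sample binomial SE for comparing a replicated frequency with a
    reference frequency that itself carries ref_reps-replicate noise."""
    var = f_hat * (1.0 - f_hat) / reps + f_ref * (1.0 - f_ref) / ref_reps
    return 3.0 * float(np.sqrt(var))
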