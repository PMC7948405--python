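import numpy as np
import pytest
from scipy.optimize import brentq

from allokin import ThermoContext


@pytest.fixture
def ctx():
    return ThermoContext()


@pytest.fixture
def bisection_bound():
    """Independent mass-action oracle: bound complex from root bracketing.

    Solves (E - x)(L - x) = K x for the bound concentration x on
    [0, min(E, L)] by Brent's method on the monotone residual, without the
    closed-form quadratic under test.
    """

    def solve(e_total: float, l_total: float, k: float) -> float:
        if e_total == 0 or l_total == 0:
            return 0.0

        def resid(x):
            return (e_total - x) * (l_total - x) - k * x

        hi = min(e_total, l_total)
        return brentq(resid, 0.0, hi, xtol=1e-16, rtol=1e-15)

    return solve


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
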