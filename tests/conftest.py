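import math

import numpy as np
import pytest

from dynconn.core import MultichannelSeries
from dynconn.synth import MVARSpec, simulate_mvar


def oscillator_spec(f: float, rate: float = 500.0, rho: float = 0.95,
                    m: int = 1) -> MVARSpec:
    """Independent damped AR(2) oscillators at frequency f, unit variance."""
    w = 2 * math.pi * f / rate
    a1, a2 = 2 * rho * math.cos(w), -rho**2
    gain = (1 - a2) / ((1 + a2) * ((1 - a2) ** 2 - a1**2))
    A = np.zeros((2, m, m))
    for i in range(m):
        A[0, i, i], A[1, i, i] = a1, a2
    return MVARSpec(A, np.eye(m) / gain)


def oscillator_series(f: float, n: int, seed: int, rate: float = 500.0,
                      rho: float = 0.95, m: int = 1) -> MultichannelSeries:
    return simulate_mvar(oscillator_spec(f, rate, rho, m), n, seed=seed,
                         rate=rate)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def white_series(rng):
    return MultichannelSeries(rng.standard_normal((3, 4000)), 500.0)
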