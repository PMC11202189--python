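import numpy as np
import pytest

from relkin import KineticParams, ReleaseSeries, SystemGeometry, mass_released

# Generating triples of the two study scenarios (low / high initial load)
LOW_TRIPLE = KineticParams(3.0, 808.0, 1.37)
HIGH_TRIPLE = KineticParams(147.0, 385.0, 9.0)


@pytest.fixture(params=["low", "high"])
def study_triple(request) -> KineticParams:
    return {"low": LOW_TRIPLE, "high": HIGH_TRIPLE}[request.param]


@pytest.fixture
def nominal_geometry() -> SystemGeometry:
    return SystemGeometry()  # d_i = 0.01 m, L = 0.01 m, h = 410 um, V = 0.015 dm3


def noiseless_series(p: KineticParams, n: int = 50, t_max: float = 2000.0) -> ReleaseSeries:
    t = np.linspace(0.0, t_max, n)
    return ReleaseSeries(t, mass_released(t, p))


@pytest.fixture
def low_series() -> ReleaseSeries:
    return noiseless_series(LOW_TRIPLE)


@pytest.fixture
def high_series() -> ReleaseSeries:
    return noiseless_series(HIGH_TRIPLE)
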