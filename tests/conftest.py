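import numpy as np
import pytest

from coevostat import ModelParameters, SystemState, make_single_peak


@pytest.fixture(scope="session")
def params():
    """Benchmark parameterisation."""
    return ModelParameters()


@pytest.fixture(scope="session")
def single_peak():
    return make_single_peak()


@pytest.fixture
def toy_state():
    """Small mixed community at an arbitrary non-equilibrium point."""
    return SystemState(
        t=0.0, R=1.8,
        host_bins=np.array([20, 35, 50], dtype=np.int64),
        host_density=np.array([2.0e4, 5.0e4, 1.0e5]),
        phage_bins=np.array([22, 50], dtype=np.int64),
        phage_density=np.array([3.0e5, 9.0e5]),
        rho=0.01,
    )
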