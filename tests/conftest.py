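import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import fibromap as fm

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom():
    """Small three-region phantom shared by round-trip tests."""
    return fm.make_phantom(fm.PhantomSpec(grid_shape=(10, 10, 4),
                                          n_regions=3, seed=7))


@pytest.fixture(scope="session")
def bvalues():
    return np.array(fm.B_VALUES)


@pytest.fixture(scope="session")
def echo_times():
    return np.array(fm.UTE_ECHOES_MS + fm.CONVENTIONAL_ECHOES_MS)
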