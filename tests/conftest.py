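import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ffcrelax.synthetic_data import default_field_grid, group_preset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def grid():
    return default_field_grid()


@pytest.fixture(scope="session")
def group1():
    return group_preset("I")


@pytest.fixture(scope="session")
def group2():
    return group_preset("II")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
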