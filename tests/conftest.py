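import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tcsfeedback import load_fixture

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def neg_params():
    """Printed example set with effectively negative feedback."""
    return load_fixture("negative_example")


@pytest.fixture(scope="session")
def pos_params():
    """Printed example set with effectively positive feedback."""
    return load_fixture("positive_example")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_states(rng, n, scale_low=-4, scale_high=1):
    """Random nonnegative states spanning realistic concentration decades."""
    return 10.0 ** rng.uniform(scale_low, scale_high, size=(n, 10))
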