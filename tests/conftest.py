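import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cvdcea import (
    default_registry,
    expand,
    generate_cohort_strata,
    generate_parameter_set,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def space(registry):
    return expand(registry)


@pytest.fixture(scope="session")
def params():
    return generate_parameter_set(1)


@pytest.fixture(scope="session")
def strata():
    return generate_cohort_strata(1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
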