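import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_regression(rng):
    """A 60-gene, 8-feature problem with 2 real effects and mild noise."""
    X = rng.normal(size=(60, 8))
    beta = np.zeros(8)
    beta[0], beta[3] = 1.5, -2.0
    y = X @ beta + rng.normal(size=60) * 0.5 + 3.0
    return X, y, beta
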