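import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_corr(rng):
    """A well-conditioned 6 x 6 sample correlation matrix with distinct entries."""
    x = rng.standard_normal((80, 6))
    return np.corrcoef(x, rowvar=False)
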