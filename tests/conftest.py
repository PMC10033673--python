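import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230322)


def lognormal_sample(rng, n=None, nu_range=(4.5, 6.0), theta_range=(0.2, 1.0)):
    """One log-normal trait sample with randomly drawn (nu, theta)."""
    if n is None:
        n = int(rng.integers(5, 51))
    nu = rng.uniform(*nu_range)
    theta = rng.uniform(*theta_range)
    return np.exp(rng.normal(nu, theta, size=n))


@pytest.fixture
def sample_factory(rng):
    def make(n=None, **kw):
        return lognormal_sample(rng, n=n, **kw)
    return make
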