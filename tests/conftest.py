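import numpy as np
import pytest

from curvefuse import PhantomSpec, analytic_fixtures, make_phantom_pair


@pytest.fixture(scope="session")
def fixtures():
    """Analytic closed-form images (constant, ramp, checkerboard, ...)."""
    return analytic_fixtures(64)


@pytest.fixture(scope="session")
def smooth_pair():
    """Noise-free co-registered phantom pair."""
    return make_phantom_pair(PhantomSpec(seed=1, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_pair():
    """Default phantom pair with acquisition noise."""
    return make_phantom_pair(PhantomSpec(seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
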