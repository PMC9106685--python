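import numpy as np
import pytest

from stereomotion import image_statistics as ist
from stereomotion import observers as obs


@pytest.fixture(scope="session")
def obs_dists():
    """Observer-resolution distribution set shared across the suite."""
    return obs.build_observer_distributions(n=1_000_000, seed=0)


@pytest.fixture(scope="session")
def small_dists():
    """Small fine-resolution distribution set for fast table checks."""
    return ist.build_distributions(n=100_000, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
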