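import numpy as np
import pytest

from fetalbrain.phantom import PhantomConfig, make_phantom


@pytest.fixture(scope="session")
def phantom48():
    """One mid-gestation 48-voxel phantom shared across tests."""
    return make_phantom(PhantomConfig(shape=(48, 48, 48), ga_weeks=27.0, seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    from fetalbrain.phantom import make_cohort

    return make_cohort(6, seed=11, shape=(48, 48, 48))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
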