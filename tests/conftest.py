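import numpy as np
import pytest

from neurofuse import phantom as ph


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """A small, fast cohort specification shared across tests."""
    return ph.PhantomSpec(
        n_asd=4, n_control=4, shape=(16, 16, 16), effect_size=2.0,
        n_frames=64, n_rois=4, noise_sd=0.1, seed=7,
    )
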