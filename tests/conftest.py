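import numpy as np
import pytest

from mesomotif.io_core import Movie
from mesomotif import synthetic


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def white_dff_movie():
    """White-noise dF/F0 movie factory: iid N(0, sd) percent values."""
    def make(n_frames=600, field=(16, 16), sd=0.05, seed=0):
        r = np.random.default_rng(seed)
        return Movie(r.normal(0.0, sd, (n_frames, *field)), is_dff=True)
    return make


@pytest.fixture(scope="session")
def template_16():
    return synthetic.template_from_kernel("forelimb", (16, 16))


@pytest.fixture(scope="session")
def template_32():
    return synthetic.template_from_kernel("forelimb", (32, 32))


@pytest.fixture(scope="session")
def template_64():
    return synthetic.template_from_kernel("forelimb", (64, 64))


@pytest.fixture(scope="session")
def small_session():
    """A small evoked session shared by evoked/variability tests."""
    return synthetic.simulate_evoked_session(
        n_subjects=3, n_trials_per_modality=4, n_blank_trials=2,
        beta=0.5, field=(16, 16), modalities=("forelimb",), seed=77)
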