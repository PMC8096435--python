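import numpy as np
import pytest

from embryopulse import piv, synthetic


@pytest.fixture(scope="session")
def presets():
    return synthetic.load_presets()


@pytest.fixture(scope="session")
def oscillating_movie():
    """A pulsating embryo movie (80 s period, supra-noise amplitude)."""
    spec = synthetic.SyntheticMovieSpec(
        image_size=(128, 128), embryo_radius=22.0, seed=7)
    return synthetic.make_movie(spec)


@pytest.fixture(scope="session")
def oscillating_field(oscillating_movie):
    """PIV field + in-embryo vector flags for the shared pulsating movie."""
    movie, truth = oscillating_movie
    field = piv.piv_two_pass(movie)
    keep = piv.vectors_in_mask(field, piv.mask_embryo(movie))
    return field, keep, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
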