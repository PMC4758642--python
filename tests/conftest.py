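import numpy as np
import pytest

from cordflux.core import Image
from cordflux.simdata import SimImageSpec, SimMovieSpec, VesicleSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_spec():
    """Noise-free image spec with well-separated spots."""
    return SimImageSpec(noise_sd=0.0, seed=7)


@pytest.fixture
def noisy_spec():
    return SimImageSpec(noise_sd=2.0, seed=7)


@pytest.fixture
def single_vesicle_spec():
    def make(velocity, frames=100, start=40.0, seed=0, **kw):
        return SimMovieSpec(
            frames=frames,
            vesicles=(VesicleSpec(start, velocity, **kw),),
            noise_sd=0.0,
            seed=seed,
        )
    return make


@pytest.fixture
def random_image(rng):
    def make(shape=(20, 20), scale=100.0):
        return Image(rng.uniform(0, scale, shape))
    return make
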