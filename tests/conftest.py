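import numpy as np
import pytest

from sptcorral.synthetic import (
    SimulationConfig,
    _stamp_integrated_gaussian,
    assign_puncta,
    make_pattern_layout,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def layout_4x4():
    return make_pattern_layout(4, 4, radius=2.0, spacing=5.0, pixel_size=0.1)


@pytest.fixture
def layout_4x4_puncta(layout_4x4):
    return assign_puncta(layout_4x4, np.random.default_rng(0))


@pytest.fixture
def sim_config():
    return SimulationConfig(rng_seed=0)


def render_single_spot(x, y, photons, psf_sigma, shape=(64, 64),
                       background=10.0, read_noise=2.0, seed=0):
    """Render one noisy emitter: Poisson shot noise over a flat background."""
    r = np.random.default_rng(seed)
    img = np.zeros(shape)
    _stamp_integrated_gaussian(img, x, y, photons, psf_sigma)
    frame = r.poisson(img + background).astype(float)
    if read_noise > 0:
        frame = frame + r.normal(0, read_noise, shape)
    return np.clip(frame, 0, None)
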