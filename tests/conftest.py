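import numpy as np
import pytest

from thermoreg import (
    Image,
    SceneParams,
    generate_scene,
    random_tps_warp,
    render_pair,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_image():
    """Horizontal intensity ramp: constant gradient pointing +x."""
    x = np.linspace(0, 1, 64)
    return Image(np.tile(x, (64, 1)))


@pytest.fixture
def square_image():
    """Bright axis-aligned square on a dark background."""
    px = np.zeros((96, 96))
    px[30:66, 30:66] = 1.0
    return Image(px)


@pytest.fixture
def scene0():
    return generate_scene(0, SceneParams())


@pytest.fixture
def synthetic_pair(scene0):
    """Longitudinal pair under a known smooth warp, with true landmarks."""
    warp = random_tps_warp(1, scene0.shape, max_displacement=15.0)
    src, tgt, lm_s, lm_t = render_pair(
        scene0, warp, noise_seed_source=2, noise_seed_target=3
    )
    return src, tgt, lm_s, lm_t, warp
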