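import numpy as np
import pytest

from stemdepth.synthetic_scene import SceneSpec, make_default_camera, render


@pytest.fixture(scope="session")
def default_cam():
    return make_default_camera()


@pytest.fixture(scope="session")
def default_scene():
    """The default synthetic scene: 25 mm stem at 0.6 m, 45-degree pitch."""
    return render(SceneSpec())


@pytest.fixture(scope="session")
def frontal_scene():
    """A fronto-parallel cylinder (vertical axis, no pitch), noiseless."""
    spec = SceneSpec(axis_direction=(0.0, 1.0, 0.0), color_noise_sd=0.0,
                     depth_noise_mm=0.0)
    return render(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_blob_mask(rng, shape=(36, 36), n_seeds=25, n_grow=60):
    """A random connected-ish blob raster for thinning/component oracles."""
    from scipy import ndimage

    mask = np.zeros(shape, dtype=bool)
    rr = rng.integers(2, shape[0] - 2, n_seeds)
    cc = rng.integers(2, shape[1] - 2, n_seeds)
    mask[rr, cc] = True
    for _ in range(3):
        mask = ndimage.binary_dilation(mask, np.ones((3, 3)))
    drop = rng.random(shape) < 0.1
    return (mask & ~drop)
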