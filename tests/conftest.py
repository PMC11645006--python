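import numpy as np
import pytest

from plantstress3d import (
    DEFAULT_GROUPS,
    CameraModel,
    SceneConfig,
    generate_scene,
    train_segmenter,
)

# small-scene geometry shared across the suite: 96x96 images, camera with
# k = 4 m so depth codes match the 0-255 convention
SMALL = 96


@pytest.fixture(scope="session")
def small_camera():
    return CameraModel(
        focal_length=250.0,
        principal_point=((SMALL - 1) / 2, (SMALL - 1) / 2),
        max_depth=4.0,
        image_size=(SMALL, SMALL),
    )


@pytest.fixture(scope="session")
def small_config(small_camera):
    return SceneConfig(
        image_width=SMALL,
        image_height=SMALL,
        leaves_per_plant=(4, 7),
        leaf_axis_lengths=((16.0, 24.0), (10.0, 15.0)),
        camera=small_camera,
    )


@pytest.fixture(scope="session")
def groups():
    return {g.name: g for g in DEFAULT_GROUPS}


@pytest.fixture(scope="session")
def small_scene(small_config, groups):
    return generate_scene(small_config, groups["C"], seed=11)


def make_toy_patches(n, seed, noise=0.02):
    """Linearly separable toy: green = plant, dark = background."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    x = np.zeros((n, 32, 32, 3))
    x[y == 1, :, :, 1] = 0.8
    x[y == 0, :, :, :] = 0.05
    x += rng.normal(0, noise, x.shape)
    return x, y


@pytest.fixture(scope="session")
def toy_segmenter():
    """A tiny segmenter trained to perfection on the toy colour family."""
    x, y = make_toy_patches(300, seed=5)
    return train_segmenter(x, y, seed=3, epochs=3)
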