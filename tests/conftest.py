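import numpy as np
import pytest

import foct


SMALL_GRID = (96, 64, 192)      # fast unit-test scale
HALF_GRID = (256, 128, 512)     # generator default


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, artifact-free scene: one straight bright tube."""
    return foct.SceneParams(
        grid_shape=SMALL_GRID, speckle_sigma=0.0,
        band_artifact_amplitude=0.0, blob_artifact_count=0,
        vessel_count=1, seed=1,
    )


@pytest.fixture(scope="session")
def clean_volume(clean_scene):
    return foct.generate_volume(clean_scene)


@pytest.fixture(scope="session")
def default_volume():
    """Default-condition scene at the generator's standard half-scale grid."""
    return foct.generate_volume(foct.SceneParams(grid_shape=HALF_GRID, seed=7))


@pytest.fixture(scope="session")
def small_default_volume():
    """Default noise/artifact conditions at the fast test grid."""
    return foct.generate_volume(foct.SceneParams(grid_shape=SMALL_GRID, seed=7))


@pytest.fixture(scope="session")
def tube_image():
    """Synthetic en-face image with one straight Gaussian-profile tube
    (sigma 30 um) on the half-scale pixel grid."""
    nx, ny = 128, 128
    spacing = (23.4375, 23.4375)
    y = (np.arange(ny) - ny / 2)[None, :] * spacing[1]
    data = 0.1 + 0.5 * np.exp(-(y**2) / (2 * 30.0**2)) * np.ones((nx, 1))
    return foct.EnFaceImage(data, spacing)


def rng(seed=0):
    return np.random.default_rng(seed)
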