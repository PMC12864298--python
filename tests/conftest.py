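import numpy as np
import pytest

from dryshift import raster_prep
from dryshift.synthetic_scene import (
    SyntheticSceneConfig,
    generate_label_map,
    render_scene,
)
from dryshift.types import SceneRaster


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return SyntheticSceneConfig(height_px=64, width_px=64, seed=0)


@pytest.fixture
def clean_config():
    """Noise-free configuration: optical equals class means, speckle off."""
    return SyntheticSceneConfig(
        height_px=64, width_px=64, optical_noise_sd=0.0, speckle=False, seed=0
    )


@pytest.fixture
def labeled_scene(small_config):
    labels = generate_label_map(small_config, seed=7)
    optical, sar = render_scene(labels, small_config, seed=11)
    return labels, optical, sar


@pytest.fixture
def scene_with_indices(labeled_scene):
    labels, optical, sar = labeled_scene
    return labels, raster_prep.compute_indices(optical), sar


def make_raster(grid, band_names=None, pixel_size_m=5.0, **kw):
    grid = np.asarray(grid, dtype=float)
    if grid.ndim == 2:
        grid = grid[:, :, None]
    names = band_names or [f"b{i}" for i in range(grid.shape[2])]
    return SceneRaster(grid=grid, band_names=names, pixel_size_m=pixel_size_m, **kw)
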