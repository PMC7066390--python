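import numpy as np
import pytest

from lymphoseg import GreyImage, generate_tile, rof_denoise
from lymphoseg.rof import RofParams


@pytest.fixture(scope="session")
def small_tile():
    """A small noisy 4-channel synthetic tile with ground truth."""
    return generate_tile(
        shape=(300, 300), n_nuclei=6, n_bcells=3, n_macrophages=2,
        n_artifacts=2, seed=7,
    )


@pytest.fixture(scope="session")
def clean_tile():
    """Noise-, gradient- and blur-free tile: piecewise constant per cell."""
    return generate_tile(
        shape=(300, 300), n_nuclei=6, n_bcells=3, n_macrophages=2,
        n_artifacts=2, seed=7,
        noise_sigma=0.0, gradient_amp=0.0, edge_sigma=0.0,
    )


@pytest.fixture(scope="session")
def dapi_cartoon(small_tile):
    """ROF cartoon of the small tile's DAPI channel (shared: it is costly)."""
    images, _ = small_tile
    return rof_denoise(images["DAPI"], RofParams(max_iter=300))


def draw_disk(shape, center, radius, value=200, canvas=None):
    """Test helper: paint a filled disk onto a fresh or given uint8 canvas."""
    img = np.zeros(shape, dtype=np.uint8) if canvas is None else canvas
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2] = value
    return img
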