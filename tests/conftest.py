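import numpy as np
import pytest

from ihcquant.pixels import PixelClassParams
from ihcquant.synthetic import TissueImageSpec, TMALayoutSpec, gen_tissue_image, gen_tma_image

WHITE = (255, 255, 255)
DAB_BROWN = (75, 175, 100)  # red-dominant stained sample pixel
HEMA_BLUE = (100, 100, 160)  # blue-dominant unstained sample pixel
LIGHT_TISSUE = (175, 175, 125)  # no channel below 125: unstained


@pytest.fixture
def params():
    return PixelClassParams()


@pytest.fixture
def tissue_image():
    """100x100 image: 50% tissue of which 20% stained, exact counts."""
    spec = TissueImageSpec(
        width=100, height=100, stain_fraction_target=0.2,
        tissue_fraction_target=0.5, seed=11,
    )
    img, labels = gen_tissue_image(spec)
    return img, labels, spec


@pytest.fixture
def tma_clean():
    """3x3 TMA, no jitter, no missing cores, no fragments."""
    spec = TMALayoutSpec(grid_rows=3, grid_cols=3, spacing=100, core_radius=30, seed=5)
    thumb, full, truth = gen_tma_image(spec)
    return thumb, full, truth, spec


def random_rgb_images(n, side, seed):
    rng = np.random.default_rng(seed)
    return [rng.integers(0, 256, size=(side, side, 3), dtype=np.uint8) for _ in range(n)]
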