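import numpy as np
import pytest

from changescope.image_metrics import ImageGeometry, LuminanceImage

PAPER_DEG_PER_PX = 18.6 / 481


@pytest.fixture
def paper_geom():
    return ImageGeometry.from_extent(481, 321, 18.6)


def small_geom(width: int, height: int) -> ImageGeometry:
    """Small grid that keeps the paper's pixel-to-degree scale."""
    return ImageGeometry(width, height, PAPER_DEG_PER_PX)


def random_image(seed: int, width: int = 8, height: int = 8, lo=50.0, hi=200.0) -> LuminanceImage:
    rng = np.random.default_rng(seed)
    vals = rng.uniform(lo, hi, size=(height, width))
    return LuminanceImage(vals, small_geom(width, height))
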