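import numpy as np
import pytest

from bgsal.abstraction import SuperpixelMap
from bgsal.pipeline import PipelineConfig
from bgsal.synthetic import make_suite

#: Reduced scale list used by slow integration tests so the whole suite
#: stays well inside the CI time budget; the library default is 8 scales.
FAST_SCALES = (50, 100, 150, 200)


@pytest.fixture(scope="session")
def suite():
    """The fixed 20-scene synthetic battery (seed 1)."""
    return make_suite(seed=1)


@pytest.fixture(scope="session")
def fast_config():
    return PipelineConfig(scales=FAST_SCALES)


@pytest.fixture
def uniform_image():
    return np.full((64, 64, 3), 0.5)


@pytest.fixture
def grid_spmap():
    """A 3x3 grid of 12x12-pixel superpixels on a 36x36 image."""
    labels = np.add.outer(np.arange(36) // 12 * 3, np.arange(36) // 12)
    return SuperpixelMap(labels=labels, k=9)


def make_grid_spmap(rows: int, cols: int, cell: int = 8) -> SuperpixelMap:
    h, w = rows * cell, cols * cell
    labels = np.add.outer(np.arange(h) // cell * cols, np.arange(w) // cell)
    return SuperpixelMap(labels=labels, k=rows * cols)
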