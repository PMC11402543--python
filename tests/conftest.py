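import numpy as np
import pytest

from gtvfusion import BinaryMask, VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_grid():
    return VoxelGrid(shape=(4, 8, 8), spacing_mm=(2.5, 1.0, 1.0))


@pytest.fixture
def iso_grid():
    return VoxelGrid(shape=(9, 9, 9), spacing_mm=(1.0, 1.0, 1.0))


def random_mask(grid, rng, density=0.3):
    return BinaryMask(grid, rng.random(grid.shape) < density)


def box_mask(grid, lo, hi):
    """Axis-aligned box [lo, hi) in index space."""
    values = np.zeros(grid.shape, dtype=bool)
    values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return BinaryMask(grid, values)
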