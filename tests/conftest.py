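import numpy as np
import pytest

from rehoconn.io import BoldSeries, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20150205)


@pytest.fixture
def small_grid():
    return VolumeGrid.centered((10, 10, 8), 3.0)


@pytest.fixture
def noise_series(rng, small_grid):
    """White-noise series on a small grid with a full-interior mask."""
    mask = np.zeros(small_grid.dims, dtype=bool)
    mask[1:-1, 1:-1, 1:-1] = True
    data = rng.standard_normal(small_grid.dims + (60,))
    return BoldSeries(grid=small_grid, tr_s=2.0, data=data, mask=mask)
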