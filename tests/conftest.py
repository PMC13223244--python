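import numpy as np
import pytest

from urban330.grid import GridLayer


def make_grid(values, cell_size=100.0, origin_x=0.0, origin_y=None, role=None, nodata=None):
    """Small helper: GridLayer from a 2-D array, north-up, origin at (0, top)."""
    values = np.asarray(values)
    if origin_y is None:
        origin_y = values.shape[0] * cell_size
    mask = np.zeros(values.shape, dtype=bool) if nodata is None else np.asarray(nodata, bool)
    return GridLayer(origin_x, origin_y, cell_size, values, mask, role)


@pytest.fixture
def flat_grid():
    """10x10 flat (all-zero heights) grid at 100 m."""
    return make_grid(np.zeros((10, 10)))
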