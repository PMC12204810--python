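import numpy as np
import pytest

from rangehood import GridTransform, RasterGrid

#: equal-area CRS used throughout the tests (World Cylindrical Equal Area)
CRS = "ESRI:54034"


def make_raster(values, cell=250.0, x0=0.0, y0=None, crs=CRS, nodata=-9999.0):
    """Raster helper: north-up square-pixel grid anchored at (x0, y0)."""
    values = np.asarray(values, dtype=float)
    if y0 is None:
        y0 = values.shape[0] * cell
    return RasterGrid(values, GridTransform(x0, y0, cell, -cell), crs, nodata)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
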