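"""Habitat masking of a binary suitability map.

The climatic suitability prediction (typically ~1 km resolution) is carried
to the finer habitat grid (250 m tree-cover cells), then every suitable cell
whose current habitat cover falls strictly below the deforestation tolerance
threshold is removed.  The result is a current-range estimate: climatically
suitable AND sufficiently forested.  Cells lost to missing habitat data are
tracked separately from cells lost to insufficient cover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import RasterGrid
from .projection import is_geographic

__all__ = ["MaskResult", "disaggregate_binary", "apply_dtt_mask", "range_area",
           "LOSS_RETAINED", "LOSS_BELOW_DTT", "LOSS_NODATA"]

# loss-raster codes
LOSS_RETAINED = 0.0
LOSS_BELOW_DTT = 1.0
LOSS_NODATA = 2.0


def disaggregate_binary(range_grid: RasterGrid, target: RasterGrid) -> RasterGrid:
    """Resample a binary range map onto the (finer) geometry of *target*.

    Every fine cell takes the value of the coarse cell containing its
    centre (nearest-neighbour); fine cells whose centres fall outside the
    coarse raster, or over a coarse nodata cell, become nodata.
    """
    if range_grid.crs != target.crs:
        raise ValueError(
            f"CRS mismatch: range is {range_grid.crs!r}, target grid is "
            f"{target.crs!r}; reproject upstream, no silent warping here"
        )
    rows = np.arange(target.n_rows)
    cols = np.arange(target.n_cols)
    cc, rr = np.meshgrid(cols, rows)
    x, y = target.transform.center_of(rr, cc)
    vals = range_grid.sample(x, y)
    vals = np.where(vals == range_grid.nodata, target.nodata, vals)
    return RasterGrid(vals, target.transform, target.crs, nodata=target.nodata)


@dataclass(frozen=True)
class MaskResult:
    """Masked binary range plus the categorical loss raster and tallies."""

    masked: RasterGrid
    loss: RasterGrid  # 0 retained, 1 removed below threshold, 2 removed nodata
    n_retained: int
    n_removed_below_dtt: int
    n_removed_nodata: int


def apply_dtt_mask(range_fine: RasterGrid, habitat: RasterGrid,
                   dtt: float) -> MaskResult:
    """Keep cells that are suitable AND have habitat cover >= *dtt*.

    The boundary is kept: a cell with cover exactly equal to the threshold
    survives.  Suitable cells over habitat nodata are removed but reported
    separately from below-threshold loss.
    """
    if not range_fine.same_grid(habitat):
        raise ValueError("range and habitat rasters must share grid geometry and CRS")
    suitable = range_fine.values == 1
    hab_valid = habitat.valid_mask()
    keep = suitable & hab_valid & (habitat.values >= dtt)
    below = suitable & hab_valid & (habitat.values < dtt)
    nod = suitable & ~hab_valid

    masked_vals = np.where(range_fine.values == range_fine.nodata,
                           range_fine.nodata, 0.0)
    masked_vals[keep] = 1.0
    loss_vals = np.full(range_fine.shape, LOSS_RETAINED)
    loss_vals[below] = LOSS_BELOW_DTT
    loss_vals[nod] = LOSS_NODATA
    return MaskResult(
        masked=range_fine.with_values(masked_vals),
        loss=range_fine.with_values(loss_vals, nodata=-1.0),
        n_retained=int(keep.sum()),
        n_removed_below_dtt=int(below.sum()),
        n_removed_nodata=int(nod.sum()),
    )


def range_area(range_grid: RasterGrid) -> float:
    """Area of the suitable cells in km², at native resolution.

    Requires the raster to live in an equal-area projected CRS so that
    cell count x cell area is meaningful.
    """
    if is_geographic(range_grid.crs):
        raise ValueError(
            f"raster CRS {range_grid.crs!r} is geographic; area needs an "
            "equal-area projected grid"
        )
    t = range_grid.transform
    cell_km2 = (t.px_w / 1000.0) * (abs(t.px_h) / 1000.0)
    return range_grid.suitable_count() * cell_km2
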