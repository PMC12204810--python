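"""Focal (moving-window) re-valuation of rasters — the "neighborhood" operator.

Occurrence coordinates often carry uncertainty larger than the pixel size of
remotely sensed habitat data (a museum georeference may be hundreds of
metres off, while tree-cover products resolve 250 m).  The neighborhood
operator replaces each pixel value with a statistic (by default the mean)
of the w x w window centred on it, so a pixel's value characterises the
area a record could plausibly have come from — while the raster keeps its
native resolution.  With the default 3 x 3 window on a 250 m grid, each
pixel summarises a 750 x 750 m neighborhood.

Statistics are computed in double precision.  Two missing-data policies are
offered: ``ignore_missing`` (the default) computes the statistic over the
valid in-window cells, so edge pixels average over their available
neighbours; ``propagate_missing`` yields nodata whenever any window member
(including out-of-bounds positions) is missing, eroding the border by
(w-1)/2 pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .grids import AnnualSeries, GridTransform, RasterGrid

__all__ = ["FocalConfig", "focal_statistic", "apply_focal_to_series",
           "window_from_distance"]

_STATISTICS = ("mean", "min", "max", "sum")
_POLICIES = ("ignore_missing", "propagate_missing")


@dataclass(frozen=True)
class FocalConfig:
    """Window size (odd pixels per side), statistic, and missing-data policy."""

    window: int = 3
    statistic: str = "mean"
    missing_policy: str = "ignore_missing"

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be an odd integer >= 1, got {self.window}")
        if self.statistic not in _STATISTICS:
            raise ValueError(f"statistic must be one of {_STATISTICS}, got {self.statistic!r}")
        if self.missing_policy not in _POLICIES:
            raise ValueError(f"missing_policy must be one of {_POLICIES}, got {self.missing_policy!r}")


def focal_statistic(raster: RasterGrid, config: FocalConfig) -> RasterGrid:
    """Apply the moving-window statistic; geometry and CRS are unchanged.

    A window with zero valid members yields nodata.  ``window=1`` is the
    identity for every statistic.
    """
    w = config.window
    if w > raster.n_rows and w > raster.n_cols:
        raise ValueError(
            f"window {w} exceeds both raster dimensions {raster.shape}"
        )
    if w == 1:
        return raster.with_values(raster.values.copy())

    half = w // 2
    vals = np.pad(raster.values.astype(float), half, constant_values=raster.nodata)
    valid = vals != raster.nodata

    win_vals = sliding_window_view(vals, (w, w))          # (R, C, w, w)
    win_valid = sliding_window_view(valid, (w, w))
    counts = win_valid.sum(axis=(2, 3))

    if config.statistic == "mean":
        sums = np.where(win_valid, win_vals, 0.0).sum(axis=(2, 3))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = sums / counts
    elif config.statistic == "sum":
        out = np.where(win_valid, win_vals, 0.0).sum(axis=(2, 3))
    elif config.statistic == "min":
        out = np.where(win_valid, win_vals, np.inf).min(axis=(2, 3))
    else:  # max
        out = np.where(win_valid, win_vals, -np.inf).max(axis=(2, 3))

    if config.missing_policy == "ignore_missing":
        missing = counts == 0
    else:
        missing = counts < w * w
    out = np.where(missing, raster.nodata, out)
    return raster.with_values(out)


def apply_focal_to_series(series: AnnualSeries, config: FocalConfig) -> AnnualSeries:
    """Focal-process every annual layer independently; years are preserved."""
    return AnnualSeries({year: focal_statistic(grid, config) for year, grid in series})


def window_from_distance(distance_m: float, transform: GridTransform) -> int:
    """Nearest odd pixel count spanning *distance_m* across the window —
    e.g. a 750 m neighborhood on a 250 m grid gives 3 (ties widen).
    """
    if distance_m < 0:
        raise ValueError("distance must be non-negative")
    ratio = distance_m / transform.px_w
    # round (ratio - 1) / 2 half-up so an exact even ratio widens the window
    k = int(np.floor((ratio - 1.0) / 2.0 + 0.5))
    return max(1, 2 * k + 1)
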