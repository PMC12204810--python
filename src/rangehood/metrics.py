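"""Extent of Occurrence, Area of Occupancy, and Red-List Criterion-B
threshold categorisation.

EOO is the area of the minimum convex polygon, computed two ways: around
the occurrence localities, and around the mapped suitable range (using the
full extents of suitable cells, so the hull contains the map).  AOO is
bracketed: the lower bound tallies the standard-grid cells that hold
documented records; the upper bound tallies grid cells overlapping the
(habitat-masked) range prediction, assuming the species occupies all of
them.  Both use a 2 x 2 km grid by convention.

Category output is threshold qualification only — the Criterion-B
subcriteria (severe fragmentation, number of locations, continuing decline)
are judgements outside the scope of area arithmetic, so no result here is
an IUCN listing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import MultiPoint, mapping

from .grids import GridSpec, RasterGrid
from .masking import range_area
from .occurrences import OccurrenceSet
from .projection import is_geographic, points_to_crs

__all__ = [
    "eoo_from_points",
    "eoo_from_range",
    "aoo_lower",
    "aoo_upper",
    "criterion_b_category",
    "MetricsReport",
    "build_report",
    "B1_THRESHOLDS_KM2",
    "B2_THRESHOLDS_KM2",
]

# Criterion-B area thresholds (km²): category -> strict upper bound
B1_THRESHOLDS_KM2 = {"CR": 100.0, "EN": 5000.0, "VU": 20000.0}     # EOO
B2_THRESHOLDS_KM2 = {"CR": 10.0, "EN": 500.0, "VU": 2000.0}        # AOO

_SEVERITY = {"CR": 3, "EN": 2, "VU": 1, "LC_by_thresholds": 0}


def eoo_from_points(records: OccurrenceSet, crs: str):
    """Minimum convex polygon around the active records, in km².

    Returns ``(area_km2, hull_geometry)``.  Degenerate hulls (one or two
    points, or all points collinear) have area 0 and return the degenerate
    geometry.
    """
    active = records.active()
    if not active:
        raise ValueError("EOO needs at least one active record")
    if is_geographic(crs):
        raise ValueError("EOO area requires an equal-area projected CRS")
    xy = points_to_crs([(r.lon, r.lat) for r in active], crs)
    hull = MultiPoint([tuple(p) for p in xy]).convex_hull
    return hull.area / 1e6, hull


def eoo_from_range(range_grid: RasterGrid):
    """Minimum convex polygon around the mapped suitable range, in km².

    The hull is taken over the four corners of every suitable cell, so it
    contains the full mapped range (cell centres would under-cover the rim
    by half a cell).  Returns ``(area_km2, hull_geometry)``.
    """
    if is_geographic(range_grid.crs):
        raise ValueError("EOO area requires an equal-area projected CRS")
    rows, cols = np.nonzero(range_grid.values == 1)
    if rows.size == 0:
        raise ValueError("range raster has no suitable cells")
    t = range_grid.transform
    corners = []
    for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
        x = t.x0 + (cols + dc) * t.px_w
        y = t.y0 + (rows + dr) * t.px_h
        corners.append(np.column_stack([x, y]))
    pts = np.unique(np.vstack(corners), axis=0)
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    return hull.area / 1e6, hull


def aoo_lower(records: OccurrenceSet, grid: GridSpec):
    """Lower-bound AOO: distinct standard-grid cells holding active records.

    Returns ``(area_km2, occupied_cells)`` where cells are (row, col) pairs
    of *grid*; several records in one cell count once.  Zero records give 0.
    """
    active = records.active()
    if not active:
        return 0.0, []
    xy = points_to_crs([(r.lon, r.lat) for r in active], grid.crs)
    row, col = grid.cell_of(xy[:, 0], xy[:, 1])
    cells = sorted({(int(r), int(c)) for r, c in zip(row, col)})
    return len(cells) * grid.cell_area_km2, cells


def aoo_upper(range_masked: RasterGrid, grid: GridSpec, rule: str = "any_overlap",
              fraction: float | None = None):
    """Upper-bound AOO: standard-grid cells covered by the range prediction.

    Every suitable fine-cell centre is assigned to the coarse cell that
    contains it.  Under ``any_overlap`` (default) a coarse cell counts when
    it receives at least one suitable centre; ``majority`` requires at least
    half of the fine centres falling in the cell to be suitable, and
    ``fraction`` requires the given *fraction*.  Returns
    ``(area_km2, occupied_cells)``.
    """
    if range_masked.crs != grid.crs:
        raise ValueError(
            f"range raster CRS {range_masked.crs!r} differs from AOO grid CRS {grid.crs!r}"
        )
    if rule not in ("any_overlap", "majority", "fraction"):
        raise ValueError(f"unknown rule {rule!r}")
    if rule == "fraction" and not (fraction is not None and 0 < fraction <= 1):
        raise ValueError("rule='fraction' needs 0 < fraction <= 1")
    thr = {"any_overlap": None, "majority": 0.5, "fraction": fraction}[rule]

    rows = np.arange(range_masked.n_rows)
    cols = np.arange(range_masked.n_cols)
    cc, rr = np.meshgrid(cols, rows)
    x, y = range_masked.transform.center_of(rr, cc)
    crow, ccol = grid.cell_of(x, y)
    suitable = (range_masked.values == 1).ravel()
    keys = np.column_stack([crow.ravel(), ccol.ravel()])

    if thr is None:
        occ = np.unique(keys[suitable], axis=0)
        cells = sorted(map(tuple, occ.tolist()))
    else:
        uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
        total = np.bincount(inverse, minlength=len(uniq))
        hits = np.bincount(inverse, weights=suitable.astype(float), minlength=len(uniq))
        ok = hits / total >= thr
        cells = sorted(map(tuple, uniq[ok].tolist()))
    return len(cells) * grid.cell_area_km2, cells


def criterion_b_category(eoo_km2: float, aoo_km2: float) -> dict:
    """Threshold-only Criterion-B categorisation from EOO (B1) and AOO (B2).

    Returns the per-criterion category, the more severe combined one, and an
    explicit note that subcriteria were not evaluated.  Never an IUCN
    listing — a category here only says which area thresholds the inputs
    cross.
    """
    if eoo_km2 < 0 or aoo_km2 < 0:
        raise ValueError("areas must be non-negative")

    def categorise(value: float, thresholds: dict[str, float]) -> str:
        for cat in ("CR", "EN", "VU"):
            if value < thresholds[cat]:
                return cat
        return "LC_by_thresholds"

    b1 = categorise(eoo_km2, B1_THRESHOLDS_KM2)
    b2 = categorise(aoo_km2, B2_THRESHOLDS_KM2)
    combined = b1 if _SEVERITY[b1] >= _SEVERITY[b2] else b2
    return {
        "B1": b1,
        "B2": b2,
        "combined": combined,
        "note": "thresholds only — subcriteria a/b not evaluated",
    }


@dataclass
class MetricsReport:
    """Conservation metrics for one post-processing method."""

    method: str  # "none" | "exact" | "neighborhood"
    n_records_active: int
    range_area_native_km2: float | None
    eoo_points_km2: float
    eoo_map_km2: float | None
    aoo_lower_km2: float
    aoo_upper_km2: float | None
    category_b: dict
    crs: str
    grid_cell_size_m: float
    grid_origin: tuple[float, float]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["grid_origin"] = list(self.grid_origin)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        d = json.loads(text)
        d["grid_origin"] = tuple(d["grid_origin"])
        return cls(**d)


def build_report(
    method: str,
    records: OccurrenceSet,
    grid: GridSpec,
    range_grid: RasterGrid | None = None,
    aoo_rule: str = "any_overlap",
) -> MetricsReport:
    """Assemble the metrics table row for one post-processing method.

    *records* should already reflect the method's habitat filtering;
    *range_grid* is the (masked) binary range on the habitat grid, or None
    for a records-only report.  All area arithmetic happens in ``grid.crs``;
    a range raster in a different CRS is rejected.
    """
    if range_grid is not None and range_grid.crs != grid.crs:
        raise ValueError(
            f"range raster CRS {range_grid.crs!r} != grid CRS {grid.crs!r}"
        )
    eoo_pts, _ = eoo_from_points(records, grid.crs)
    aoo_lo, _ = aoo_lower(records, grid)
    if range_grid is not None and range_grid.suitable_count() > 0:
        eoo_map, _ = eoo_from_range(range_grid)
        aoo_up, _ = aoo_upper(range_grid, grid, rule=aoo_rule)
        native = range_area(range_grid)
    else:
        eoo_map = aoo_up = native = None
    category = criterion_b_category(
        eoo_pts, aoo_up if aoo_up is not None else aoo_lo
    )
    return MetricsReport(
        method=method,
        n_records_active=records.n_active,
        range_area_native_km2=native,
        eoo_points_km2=eoo_pts,
        eoo_map_km2=eoo_map,
        aoo_lower_km2=aoo_lo,
        aoo_upper_km2=aoo_up,
        category_b=category,
        crs=grid.crs,
        grid_cell_size_m=grid.cell_size,
        grid_origin=(grid.origin_x, grid.origin_y),
    )


def hull_to_geojson(hulls: dict) -> str:
    """Serialise named hull geometries as a GeoJSON FeatureCollection."""
    features = [
        {"type": "Feature", "properties": {"name": name}, "geometry": mapping(geom)}
        for name, geom in hulls.items()
    ]
    return json.dumps({"type": "FeatureCollection", "features": features},
                      indent=2, sort_keys=True)
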