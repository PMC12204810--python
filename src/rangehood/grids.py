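"""Georeferenced raster grids and the grid-geometry contract.

A :class:`RasterGrid` is a single-band 2-D array plus the affine metadata
needed to place it on a map: origin, pixel size, CRS identifier, and a
nodata sentinel.  Row 0 is the northernmost row and pixel ``(row, col)``
spans the half-open box anchored at its north-west corner, matching the
GeoTIFF/GDAL convention.  A point lying exactly on a shared pixel edge
belongs to the pixel to its east/south, so every point maps to exactly one
pixel.

Rasters are stored on disk as ESRI ASCII grids (``.asc``) with a ``.prj``
sidecar carrying the CRS identifier.  The ASCII grid is a plain-text,
GDAL-readable single-band format; it restricts pixels to squares, which is
all this toolkit needs (habitat layers and suitability maps live on square
grids).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = ["GridTransform", "RasterGrid", "AnnualSeries", "GridSpec",
           "read_raster", "write_raster"]

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridTransform:
    """North-up affine transform: ``x = x0 + col*px_w``, ``y = y0 + row*px_h``.

    ``(x0, y0)`` is the outer corner of pixel (0, 0) — its north-west corner.
    ``px_w > 0``; ``px_h`` is negative for north-up grids (row index grows
    southward).
    """

    x0: float
    y0: float
    px_w: float
    px_h: float

    def __post_init__(self) -> None:
        for name in ("x0", "y0", "px_w", "px_h"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if not self.px_w > 0:
            raise ValueError(f"pixel width must be > 0, got {self.px_w}")
        if self.px_h == 0:
            raise ValueError("pixel height must be nonzero")

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map planar coordinates to (row, col) under the half-open rule.

        A point on a shared vertical edge falls in the pixel to its east;
        on a shared horizontal edge, the pixel to its south.
        """
        col = np.floor((np.asarray(x, dtype=float) - self.x0) / self.px_w)
        row = np.floor((np.asarray(y, dtype=float) - self.y0) / self.px_h)
        return row.astype(np.int64), col.astype(np.int64)

    def center_of(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.x0 + (np.asarray(col, dtype=float) + 0.5) * self.px_w
        y = self.y0 + (np.asarray(row, dtype=float) + 0.5) * self.px_h
        return x, y

    def corner_of(self, row: float, col: float) -> tuple[float, float]:
        return self.x0 + col * self.px_w, self.y0 + row * self.px_h


@dataclass
class RasterGrid:
    """Single-band georeferenced raster (fractional cover 0–100 or binary 0/1)."""

    values: np.ndarray
    transform: GridTransform
    crs: str
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError(f"raster must be a 2-D array of at least 1x1, got shape {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.transform == other.transform
            and self.crs == other.crs
        )

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            transform=self.transform,
            crs=self.crs,
            nodata=self.nodata if nodata is None else nodata,
        )

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Values at planar points; points outside the extent read as nodata."""
        row, col = self.transform.cell_of(x, y)
        inside = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        out = np.full(np.broadcast(row, col).shape, self.nodata, dtype=float)
        out[inside] = self.values[row[inside], col[inside]]
        return out

    def suitable_count(self) -> int:
        """Number of cells equal to 1 (for binary rasters)."""
        return int(np.count_nonzero(self.values == 1))


class AnnualSeries:
    """Year-indexed stack of rasters sharing one grid geometry.

    Emulates an annual percent-tree-cover product (one 0–100% layer per
    year on a fixed grid).
    """

    def __init__(self, layers: Mapping[int, RasterGrid]):
        if not layers:
            raise ValueError("AnnualSeries needs at least one layer")
        self._layers = {int(y): g for y, g in sorted(layers.items())}
        ref = next(iter(self._layers.values()))
        for year, grid in self._layers.items():
            if not grid.same_grid(ref) or grid.nodata != ref.nodata:
                raise ValueError(f"layer for year {year} does not share the series grid geometry")

    @property
    def years(self) -> list[int]:
        return list(self._layers)

    def __contains__(self, year: int) -> bool:
        return int(year) in self._layers

    def __getitem__(self, year: int) -> RasterGrid:
        return self._layers[int(year)]

    def __iter__(self) -> Iterator[tuple[int, RasterGrid]]:
        return iter(self._layers.items())

    def __len__(self) -> int:
        return len(self._layers)

    @property
    def grid(self) -> RasterGrid:
        """A representative layer carrying the shared geometry."""
        return next(iter(self._layers.values()))

    def latest_year(self) -> int:
        return max(self._layers)

    def nearest_year(self, year: int) -> int:
        return min(self._layers, key=lambda y: (abs(y - year), y))


@dataclass(frozen=True)
class GridSpec:
    """Regular square grid for occupancy tallies (default the 2 km AOO grid).

    Cells are half-open with the same east/south tie-break as raster pixels:
    ``col = floor((x - origin_x)/cell_size)``,
    ``row = floor((origin_y - y)/cell_size)`` with ``origin_y`` the top edge,
    so every planar point belongs to exactly one cell.
    """

    cell_size: float = 2000.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs: str = "ESRI:54034"

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.cell_size)
        row = np.floor((self.origin_y - np.asarray(y, dtype=float)) / self.cell_size)
        # origin_y - y puts the point on a top-open interval; a point exactly on
        # a horizontal grid line lands in the cell to its south, as for pixels.
        return row.astype(np.int64), col.astype(np.int64)

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write *grid* as an ESRI ASCII grid plus a ``.prj`` CRS sidecar.

    Values are written with 17 significant digits, so float64 payloads
    round-trip bit-exactly.
    """
    path = Path(path)
    t = grid.transform
    if abs(abs(t.px_h) - t.px_w) > 1e-9:
        raise ValueError("ASCII grid requires square pixels")
    if t.px_h > 0:
        raise ValueError("expected a north-up raster (negative pixel height)")
    yll = t.y0 + grid.n_rows * t.px_h
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {float(t.x0)!r}\n")
        fh.write(f"yllcorner {float(yll)!r}\n")
        fh.write(f"cellsize {float(t.px_w)!r}\n")
        fh.write(f"NODATA_value {float(grid.nodata)!r}\n")
        for row in grid.values:
            fh.write(" ".join(format(v, ".17g") for v in row))
            fh.write("\n")
    path.with_suffix(".prj").write_text(grid.crs + "\n", encoding="utf-8")


def read_raster(path: str | Path, crs: str | None = None) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_raster` (or GDAL).

    Parameters
    ----------
    path : the ``.asc`` file
    crs : CRS identifier override; if omitted, the ``.prj`` sidecar is
        required — a raster without a CRS is rejected rather than silently
        assumed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    header: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not parts[0].replace("_", "").isalpha():
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(pos)
        body = np.loadtxt(fh, dtype=float, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: malformed ASCII grid header (missing {key})")
    if "xllcorner" not in header or "yllcorner" not in header:
        raise ValueError(f"{path}: only corner-registered grids are supported")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if body.shape != (nrows, ncols):
        raise ValueError(f"{path}: body shape {body.shape} does not match header ({nrows}, {ncols})")
    size = header["cellsize"]
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    if crs is None:
        prj = path.with_suffix(".prj")
        if not prj.exists():
            raise ValueError(
                f"{path}: no CRS given and no .prj sidecar found; a raster "
                "without a coordinate reference is ambiguous"
            )
        crs = prj.read_text(encoding="utf-8").strip()
    transform = GridTransform(
        x0=header["xllcorner"],
        y0=header["yllcorner"] + nrows * size,
        px_w=size,
        px_h=-size,
    )
    return RasterGrid(values=body, transform=transform, crs=crs, nodata=nodata)
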