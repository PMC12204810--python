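"""Equal-area map projections for range-area arithmetic.

Area metrics (range area, EOO, AOO) must be computed in an equal-area
projected coordinate system; the default is World Cylindrical Equal Area
(``ESRI:54034``), the projection conventionally used for Red-List area
reporting.  The forward/inverse transforms are the ellipsoidal normal
cylindrical equal-area equations on WGS84: the northing is proportional to
the authalic quantity ``q(lat)``, and the inverse recovers geodetic latitude
from authalic latitude via the standard trigonometric series.

Supported CRS identifiers
-------------------------
``"EPSG:4326"``
    Geographic lon/lat degrees (not projected; area ops reject it).
``"ESRI:54034"``
    World Cylindrical Equal Area, WGS84, central meridian 0, standard
    parallel 0.  Units: metres.
``"cea:lon_0=<deg>"`` / ``"cea:lon_0=<deg>,lat_ts=<deg>"``
    Cylindrical equal area with a custom central meridian (and optionally a
    standard parallel), useful as a local equal-area CRS for small study
    regions and tests.  Units: metres.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "is_projected",
    "is_geographic",
    "parse_cea",
    "project_points",
    "inverse_project_points",
    "points_to_crs",
]

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_E = math.sqrt(_E2)


def _q(sin_lat: np.ndarray) -> np.ndarray:
    """Authalic quantity q for geodetic latitude (Snyder 3-12)."""
    es = _E * sin_lat
    return (1.0 - _E2) * (
        sin_lat / (1.0 - _E2 * sin_lat**2)
        - (1.0 / (2.0 * _E)) * np.log((1.0 - es) / (1.0 + es))
    )


_QP = float(_q(np.asarray(1.0)))  # q at the pole

# Authalic -> geodetic latitude series coefficients (Snyder 3-18).
_C2 = _E2 / 3.0 + 31.0 * _E2**2 / 180.0 + 517.0 * _E2**3 / 5040.0
_C4 = 23.0 * _E2**2 / 360.0 + 251.0 * _E2**3 / 3780.0
_C6 = 761.0 * _E2**3 / 45360.0


def is_projected(crs: str) -> bool:
    """True if *crs* has linear (metre) units."""
    c = crs.strip()
    return c.upper() == "ESRI:54034" or c.lower().startswith("cea:") or c.lower() == "cea"


def is_geographic(crs: str) -> bool:
    """True for lon/lat degree CRSs."""
    return crs.strip().upper() in ("EPSG:4326", "WGS84", "CRS84")


def parse_cea(crs: str) -> tuple[float, float]:
    """Return (lon_0, lat_ts) in degrees for a supported projected CRS.

    Raises ``ValueError`` for geographic or unrecognised identifiers.
    """
    c = crs.strip()
    if c.upper() == "ESRI:54034":
        return 0.0, 0.0
    low = c.lower()
    if low == "cea":
        return 0.0, 0.0
    if low.startswith("cea:"):
        lon_0, lat_ts = 0.0, 0.0
        for part in low[4:].split(","):
            if not part:
                continue
            key, _, val = part.partition("=")
            if key.strip() == "lon_0":
                lon_0 = float(val)
            elif key.strip() == "lat_ts":
                lat_ts = float(val)
            else:
                raise ValueError(f"unknown CEA parameter {key!r} in CRS {crs!r}")
        return lon_0, lat_ts
    raise ValueError(
        f"CRS {crs!r} is not a supported projected CRS "
        "(expected ESRI:54034 or cea:lon_0=...,lat_ts=...)"
    )


def project_points(
    points: Iterable[Sequence[float]] | np.ndarray, crs: str
) -> np.ndarray:
    """Project (lon, lat) degree pairs to planar metres in *crs*.

    Parameters
    ----------
    points : iterable of (lon, lat) pairs
    crs : projected CRS identifier (see module docstring)

    Returns
    -------
    (n, 2) float array of (x, y) in metres.

    Raises
    ------
    ValueError
        If *crs* is geographic (an area computation downstream would be
        meaningless) or unrecognised.
    """
    lon_0, lat_ts = parse_cea(crs)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    lon = np.radians(pts[:, 0])
    lat = np.radians(pts[:, 1])
    ts = math.radians(lat_ts)
    k0 = math.cos(ts) / math.sqrt(1.0 - _E2 * math.sin(ts) ** 2)
    dlon = lon - math.radians(lon_0)
    # wrap to (-pi, pi]
    dlon = np.mod(dlon + np.pi, 2.0 * np.pi) - np.pi
    x = _A * k0 * dlon
    y = _A * _q(np.sin(lat)) / (2.0 * k0)
    return np.column_stack([x, y])


def inverse_project_points(
    xy: Iterable[Sequence[float]] | np.ndarray, crs: str
) -> np.ndarray:
    """Inverse of :func:`project_points`; returns (lon, lat) degrees."""
    lon_0, lat_ts = parse_cea(crs)
    pts = np.atleast_2d(np.asarray(xy, dtype=float))
    ts = math.radians(lat_ts)
    k0 = math.cos(ts) / math.sqrt(1.0 - _E2 * math.sin(ts) ** 2)
    lon = np.degrees(pts[:, 0] / (_A * k0)) + lon_0
    q = 2.0 * k0 * pts[:, 1] / _A
    beta = np.arcsin(np.clip(q / _QP, -1.0, 1.0))
    lat = (
        beta
        + _C2 * np.sin(2.0 * beta)
        + _C4 * np.sin(4.0 * beta)
        + _C6 * np.sin(6.0 * beta)
    )
    return np.column_stack([lon, np.degrees(lat)])


def points_to_crs(
    lonlat: Iterable[Sequence[float]] | np.ndarray, crs: str
) -> np.ndarray:
    """Express (lon, lat) degree pairs in *crs* (projected or geographic)."""
    if is_geographic(crs):
        return np.atleast_2d(np.asarray(lonlat, dtype=float)).copy()
    return project_points(lonlat, crs)
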