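"""Synthetic landscapes, annual cover series, suitability maps and
occurrence sets with known ground truth.

The generator emulates the structure of the real inputs — an annual
percent-tree-cover product on a fine square grid, a coarser binary
climatic-suitability map, and occurrence records sampled only where cover
meets a known true tolerance theta — so every pipeline stage can be tested
against truth without downloading anything.

Model
-----
* Cover for the first year is spatially autocorrelated: white noise
  smoothed with a Gaussian kernel of scale ``autocorr_length_m``,
  min–max rescaled to [0, 100] and quantised to integer percent (the same
  bin width as the tree-cover product it stands in for).
* Deforestation: a contiguous random subset of the landscape (the top
  ``defor_fraction`` quantile of a second smoothed field) loses
  ``deforestation_rate`` percent-points per year, clipped at 0.
* Suitability: a smoothed latent surface on a ``coarsening``-times coarser
  grid, suitable where it exceeds its median (suitable fraction ~ 0.5).
* Occurrences: each record draws a year uniformly, then a true location
  uniform over the fine cells that are suitable AND have cover >= theta in
  that year; the reported location adds isotropic Gaussian jitter of sd
  ``jitter_sd_m`` (georeferencing error), 0 by default.

All outputs are pure functions of the config (seed included).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import AnnualSeries, GridTransform, RasterGrid
from .masking import disaggregate_binary
from .occurrences import OccurrenceRecord, OccurrenceSet
from .projection import inverse_project_points, project_points

__all__ = ["LandscapeConfig", "generate_cover_series", "generate_suitability",
           "sample_occurrences"]

#: quantisation step of the generated cover layers, in percent
COVER_BIN_WIDTH = 1.0


@dataclass(frozen=True)
class LandscapeConfig:
    """Study conditions for one synthetic landscape."""

    seed: int
    n_rows: int = 100
    n_cols: int = 120
    cell_size_m: float = 250.0
    autocorr_length_m: float = 1000.0
    n_years: int = 20
    start_year: int = 2000
    deforestation_rate: float = 1.5      # percent-points per year in the loss zone
    defor_fraction: float = 0.25         # fraction of landscape subject to loss
    true_tolerance_theta: float = 30.0   # percent cover
    jitter_sd_m: float = 0.0             # georeferencing error sd
    n_occurrences: int = 57
    lon_center: float = -97.0            # landscape placement (degrees)
    lat_center: float = 19.0
    crs: str = "ESRI:54034"

    def __post_init__(self) -> None:
        if min(self.n_rows, self.n_cols, self.n_years, self.cell_size_m,
               self.autocorr_length_m) <= 0:
            raise ValueError("landscape dimensions and scales must be positive")
        if not (0.0 < self.true_tolerance_theta < 100.0):
            raise ValueError("true_tolerance_theta must be in (0, 100)")
        if self.jitter_sd_m < 0 or self.n_occurrences < 0:
            raise ValueError("jitter_sd_m and n_occurrences must be non-negative")

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))

    def transform(self) -> GridTransform:
        cx, cy = project_points([(self.lon_center, self.lat_center)], self.crs)[0]
        return GridTransform(
            x0=cx - self.n_cols * self.cell_size_m / 2.0,
            y0=cy + self.n_rows * self.cell_size_m / 2.0,
            px_w=self.cell_size_m,
            px_h=-self.cell_size_m,
        )


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma_cells: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    field = gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    lo, hi = field.min(), field.max()
    return (field - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def generate_cover_series(config: LandscapeConfig) -> tuple[AnnualSeries, dict]:
    """Annual fractional-cover layers plus a ground-truth record."""
    rng = np.random.default_rng([config.seed, 0])
    shape = (config.n_rows, config.n_cols)
    sigma = config.autocorr_length_m / config.cell_size_m
    base = _smooth_field(rng, shape, sigma) * 100.0
    zone_field = _smooth_field(rng, shape, sigma)
    zone = zone_field >= np.quantile(zone_field, 1.0 - config.defor_fraction)

    transform = config.transform()
    layers = {}
    for i, year in enumerate(config.years):
        vals = base - np.where(zone, config.deforestation_rate * i, 0.0)
        vals = np.round(np.clip(vals, 0.0, 100.0) / COVER_BIN_WIDTH) * COVER_BIN_WIDTH
        layers[year] = RasterGrid(vals, transform, config.crs)
    truth = {
        "theta": config.true_tolerance_theta,
        "bin_width": COVER_BIN_WIDTH,
        "deforestation_zone_fraction": float(zone.mean()),
        "config": asdict(config),
    }
    return AnnualSeries(layers), truth


def generate_suitability(config: LandscapeConfig, coarsening: int = 4) -> RasterGrid:
    """Binary suitability map on a grid *coarsening* x coarser than the cover grid.

    Suitable where a smoothed latent surface exceeds its median, so roughly
    half the landscape is suitable.
    """
    if coarsening < 1:
        raise ValueError("coarsening must be >= 1")
    rng = np.random.default_rng([config.seed, 1])
    n_rows = config.n_rows // coarsening
    n_cols = config.n_cols // coarsening
    sigma = config.autocorr_length_m / (config.cell_size_m * coarsening)
    latent = _smooth_field(rng, (n_rows, n_cols), max(sigma, 0.5))
    suitable = (latent > np.median(latent)).astype(float)
    fine = config.transform()
    transform = GridTransform(
        x0=fine.x0, y0=fine.y0,
        px_w=config.cell_size_m * coarsening,
        px_h=-config.cell_size_m * coarsening,
    )
    return RasterGrid(suitable, transform, config.crs)


def sample_occurrences(
    config: LandscapeConfig,
    series: AnnualSeries,
    suitability: RasterGrid,
) -> tuple[OccurrenceSet, dict]:
    """Occurrence records placed where cover >= theta inside suitable area.

    Reported coordinates are the true location plus isotropic Gaussian
    jitter of sd ``jitter_sd_m`` (0 keeps them exact).  The truth record
    stores true locations, years and theta.
    """
    rng = np.random.default_rng([config.seed, 2])
    fine = series.grid
    suit_fine = disaggregate_binary(suitability, fine)
    suit_mask = suit_fine.values == 1

    eligible_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def eligible(year: int) -> tuple[np.ndarray, np.ndarray]:
        if year not in eligible_cache:
            mask = suit_mask & (series[year].values >= config.true_tolerance_theta)
            eligible_cache[year] = np.nonzero(mask)
        return eligible_cache[year]

    years = series.years
    records, truth_records = [], []
    t = fine.transform
    for i in range(config.n_occurrences):
        year = int(years[rng.integers(len(years))])
        rows, cols = eligible(year)
        if rows.size == 0:
            raise ValueError(
                f"no cells with cover >= {config.true_tolerance_theta} inside "
                f"the suitable area for year {year}; cannot place occurrences"
            )
        k = int(rng.integers(rows.size))
        # true location uniform within the chosen fine cell
        x = t.x0 + (cols[k] + rng.random()) * t.px_w
        y = t.y0 + (rows[k] + rng.random()) * t.px_h
        if config.jitter_sd_m > 0:
            dx, dy = rng.normal(0.0, config.jitter_sd_m, size=2)
        else:
            dx = dy = 0.0
        lon, lat = inverse_project_points([(x + dx, y + dy)], config.crs)[0]
        rid = f"occ_{i:04d}"
        records.append(OccurrenceRecord(rid, float(lon), float(lat), year))
        truth_records.append({
            "record_id": rid,
            "true_x": float(x), "true_y": float(y),
            "jitter": [float(dx), float(dy)],
            "year": year,
            "true_cover": float(series[year].values[rows[k], cols[k]]),
        })
    truth = {
        "theta": config.true_tolerance_theta,
        "bin_width": COVER_BIN_WIDTH,
        "records": truth_records,
        "config": asdict(config),
    }
    return OccurrenceSet(records), truth
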