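# Methods

## Scope and data model

The package post-processes a *finished* binary suitability prediction; SDM
fitting itself (algorithm choice, thresholding of the continuous
prediction) happens upstream and its output arrives as a single-band
binary raster. Three inputs share one coordinate world: an annual series
of fractional habitat-cover rasters on a fine square grid (the stand-in
for a 250 m percent-tree-cover product), the coarser binary suitability
raster in the same CRS, and an occurrence table in geographic lon/lat.
Inputs must arrive on consistent grids — the package never warps rasters
between CRSs, it only disaggregates the coarse binary map onto the fine
grid by centre-point assignment.

Grid conventions are fixed once: row 0 is the northernmost row, a pixel
spans the half-open box anchored at its north-west corner, and a point
exactly on a shared edge belongs to the pixel to its east/south. The same
rule applies to the occupancy grid used for AOO, so every point maps to
exactly one cell with no tie ambiguity.

Rasters are stored as ESRI ASCII grids with a `.prj` sidecar holding the
CRS identifier. The format is plain text and restricted to square pixels,
which covers every grid this workflow uses; values are written with 17
significant digits so float payloads round-trip bit-exactly. A raster
without a CRS is rejected rather than assumed.

## Projection and areas

All area metrics are computed in an equal-area projected CRS, by default
World Cylindrical Equal Area on WGS84 (`ESRI:54034`); a custom-meridian
variant (`cea:lon_0=...`) serves as a local equal-area CRS for small study
regions. The forward transform is the ellipsoidal normal cylindrical
equal-area projection (x proportional to longitude, y to the authalic
quantity q(φ)/2); the inverse recovers geodetic latitude through the
standard three-term authalic-latitude series, giving round-trip errors
below 1e-6 degrees. The projected area of a lon/lat quadrilateral matches
direct numerical integration of the WGS84 area element to nine significant
digits (tested), which is what makes cell-count × cell-area arithmetic
legitimate.

## The neighborhood operator

`focal_statistic` replaces each pixel with a statistic (mean, min, max,
sum) of the w × w window centred on it, with w odd so the window is
symmetric. Accumulation is in double precision regardless of input
storage. Two missing-data policies:

- `ignore_missing` (default): the statistic runs over the valid in-window
  cells, so edge pixels use their available neighbours and the layer
  border is not eroded. A window with zero valid members yields nodata.
- `propagate_missing`: any missing member — nodata or out-of-bounds —
  yields nodata, eroding the border by (w−1)/2 pixels. Offered for
  strictness.

The default was chosen because eroding the border would silently discard
occurrence records near the raster edge; it matches the common
"remove-missing" idiom of focal workflows. A helper converts a coordinate
uncertainty distance to the nearest odd pixel count (750 m on a 250 m grid
gives w = 3), with ties widening the window.

## Threshold estimation

Records are first restricted to the years the cover series spans
(boundaries inclusive); records without a year are flagged, not deleted —
every status change in an `OccurrenceSet` is append-only and audited, and
record counts are conserved through every stage. Each active record is
then matched to the layer of its collection year (strict by default; an
optional nearest-year fallback logs its substitution) and its pixel value
extracted; records outside the raster or on nodata read as dropped, not
as errors. Matched values are stably sorted ascending and the DTT is the
minimum value among records not dropped.

Aberrant-record identification is deliberately *not* automated: in real
assessments the lowest-ranked records are inspected against satellite
imagery and natural-history knowledge. The API therefore takes explicit
`drop_ids`, with `drop_count=k` as a scripted convenience that drops the k
lowest entries. Drops remove entries, not values: when two records tie at
the minimum, dropping one leaves the threshold unchanged. The threshold is
monotone non-decreasing in the number of drops (tested). No spatial
thinning is applied before threshold estimation — tolerance estimation
wants the maximum number of data points and is not bias-sensitive the way
model fitting is; a seeded randomised-restart great-circle thinner is
provided separately for reproducing modeling-stage record counts.

## Masking and metrics

Masking happens on the fine habitat grid: the binary range is
disaggregated by assigning each fine-cell centre the value of the coarse
cell containing it, then a cell survives iff it is suitable AND its
current-year habitat (raw layer for an exact threshold, focal-processed
for a neighborhood one) is ≥ the DTT. The boundary is kept — "remove below
threshold" means strictly below. Suitable cells over habitat nodata are
removed but tallied separately from below-threshold loss, and the loss
raster encodes {0 retained, 1 below threshold, 2 nodata}.

EOO from points is the convex hull of the projected active records
(degenerate hulls return area 0); EOO from a range map takes the hull over
the four corners of every suitable cell, since a hull built on centres
would under-cover the rim by half a cell. AOO lower counts distinct
occupancy-grid cells holding records; AOO upper assigns every suitable
fine-cell centre to its coarse cell and counts cells with ≥1 hit
(`any_overlap`, the default reading of "cells corresponding to the range
prediction"), with `majority` and `fraction≥f` rules for sensitivity
analysis. The occupancy grid defaults to 2000 m cells anchored at (0, 0)
of the equal-area CRS; the origin is configurable and always recorded in
the report, because shifting the grid lines changes the counts. Category
output reports which Criterion-B area thresholds the inputs cross (B1 on
EOO, B2 on AOO, combined as the more severe) and explicitly disclaims the
unevaluated subcriteria.

## Synthetic study conditions

The generator's defaults are the package's fixed study conditions, chosen
once: a 100 × 120 grid of 250 m cells (a 25 × 30 km landscape), 20 annual
layers (years 2000–2019), Gaussian-smoothed white noise with a 1000 m
autocorrelation length min–max rescaled to [0, 100] and quantised to
integer percent (bin width 1, like the tree-cover product it emulates),
deforestation of 1.5 percent-points/year confined to the top-quartile
patch of a second smoothed field, a suitability map on a 4× coarser grid
(suitable above the latent median, fraction ≈ 0.5), a true tolerance
θ = 30%, and 57 occurrence records (the sample size typical of the
assessments this workflow serves). Jitter defaults to 0; uncertainty
experiments use sd = 750 m, and the "fragmented" configuration shortens
the autocorrelation length to 400 m, the regime where a small coordinate
error crosses habitat boundaries. All generators are pure functions of
(config, seed) via independent `default_rng([seed, k])` streams.

What the generator does *not* emulate: sensor artifacts and compositing
noise, real deforestation's road/frontier spatial process, sampling bias
toward accessible places, and taxonomic error. Passing tests therefore
demonstrate the estimators' arithmetic and their qualitative behaviour
under coordinate error — not performance on any particular real
landscape.

## Numerical choices and degenerate inputs

- Focal means are computed as masked sum / count in float64; oracle
  agreement is asserted to 1e-9.
- Matched-value ranking is a stable sort, so ties keep input order and
  rankings are reproducible.
- Dropping all records, ranking an empty list, EOO with zero active
  records or an empty range, and geographic CRSs in area computations all
  raise immediately with the offending quantity named.
- The thinner breaks equal-size ties across restarts lexicographically by
  record id, making the heuristic deterministic for a given seed.
- Pipeline outputs (JSON with sorted keys, text rasters) are byte-stable
  across reruns with identical inputs and config.

## Problem sizes

Tests and the reproduction script run entirely on generated data at the
default landscape size; the heaviest computation — 100 independent
landscape simulations for the directional-bias concordance — completes in
a few seconds, and the whole reproduction script in well under a minute.

## Known limitations

- No raster warping: cover and suitability must share a CRS beforehand.
- The ASCII-grid backend stores square pixels only and no compression;
  very large real rasters would be better served by a GeoTIFF backend
  behind the same `RasterGrid` type.
- Supported CRSs are geographic WGS84 and the cylindrical equal-area
  family; other equal-area projections would need a new entry in the
  projection module.
- The Criterion-B output is threshold qualification only; subcriteria
  (fragmentation, locations, decline) need judgement the package does not
  attempt.
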