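# rangehood

Habitat-aware refinement of species range maps for conservation
assessment, built around a **neighborhood** (focal-window) treatment of
fine-resolution remotely sensed habitat data.

## The problem

A species distribution model (SDM) predicts where the climate suits a
species, but climate alone overestimates the *current* range: places that
have lost their habitat (for a forest-dwelling species, their tree cover)
are no longer occupied. A standard refinement matches each occurrence
record to the habitat layer of its collection year, reads off the habitat
value, and takes the minimum value at which the species was still recorded
— the **deforestation tolerance threshold (DTT)** — then removes from the
range map every cell whose current cover falls below that threshold.

The catch is coordinate uncertainty. Tree-cover products resolve 250 m,
while a museum georeference may be off by several hundred metres. An
occurrence can then land on a single unrepresentative pixel (the edge of a
town, a road cutting a forest) and drag the estimated tolerance far below
what the species actually needs. The neighborhood approach re-values each
pixel as the mean (or min/max/sum) of the *w* × *w* window centred on it —
with *w* = 3 on a 250 m grid, a 750 × 750 m neighborhood — so pixel values
describe the area a record plausibly came from, while the raster keeps its
native resolution:

```
cover_nbh[i, j] = (1 / |W|) * sum over (k, l) in W(i, j) of cover[k, l]
```

with `W(i, j)` the valid cells of the window centred on `(i, j)`.

From the masked range and the vetted records the package computes the IUCN
Criterion-B geometry: **EOO** (area of the minimum convex polygon, around
either the occurrences or the mapped range), **AOO** lower/upper bounds on
the standard 2 × 2 km grid, and the Criterion-B area-threshold category
(B1: EOO < 100 / 5,000 / 20,000 km²; B2: AOO < 10 / 500 / 2,000 km² for
CR / EN / VU) — thresholds only, never a listing, since the subcriteria are
out of scope. All areas are computed in an equal-area projection (World
Cylindrical Equal Area by default).

A synthetic-data generator produces autocorrelated cover series with a
deforestation trend, coarse binary suitability maps, and occurrence sets
placed only where cover ≥ a known true tolerance θ, with optional Gaussian
coordinate jitter — so every stage is testable against ground truth.

## Worked example

```python
from rangehood.experiments import estimate_dtts, fragmented_config

config = fragmented_config(seed=7, jitter_sd_m=750.0)   # true tolerance 30%
results = estimate_dtts(config, drop_count=1)
for method, res in results.items():
    print(method, res.threshold)
```

prints (see `examples/02_dtt_estimation.py`):

```
true tolerance: 30% cover
        exact: DTT = 8.0%  (lowest ranked values: 8.0, 8.0, 11.0; dropped ['occ_0019'])
 neighborhood: DTT = 11.6%  (lowest ranked values: 11.2, 11.6, 17.9; dropped ['occ_0019'])
```

Both methods underestimate the true 30% tolerance because 750 m of
coordinate error lands some records on low-cover pixels, but the exact
method is hit hardest: a single bad pixel sets its minimum, while the
neighborhood mean dilutes the error. Across 100 such simulated landscapes
the exact threshold sits at or below the neighborhood one in >90% of runs
— the directional signature of georeferencing error that motivates the
neighborhood treatment.

The other scripts in `examples/` show focal smoothing on a hand-built
raster, masking + metrics, and the file-driven pipeline. The same pipeline
is scriptable from the shell:

```bash
rangehood simulate --seed 11 --out-dir sim/
rangehood run --config analysis.yaml
```

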