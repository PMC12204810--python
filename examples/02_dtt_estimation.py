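"""Deforestation tolerance thresholds from temporally matched records.

Generates a synthetic landscape whose occurrences were placed only where
cover >= 30% (the known truth), adds 750 m georeferencing error, and
estimates the tolerance threshold two ways: from the exact pixel values and
from the 3x3 neighborhood means.  Dropping the single lowest record per
method mirrors the aberrant-record inspection step of a real assessment.
"""

from rangehood.experiments import estimate_dtts, fragmented_config

config = fragmented_config(seed=7, jitter_sd_m=750.0)
results = estimate_dtts(config, drop_count=1)

print(f"true tolerance: {config.true_tolerance_theta:.0f}% cover")
for method, res in results.items():
    low3 = ", ".join(f"{m.cover_value:.1f}" for m in res.ranked[:3])
    print(f"{method:>13}: DTT = {res.threshold:.1f}%  "
          f"(lowest ranked values: {low3}; dropped {list(res.dropped_ids)})")

print("\nCoordinate error drags records onto unrepresentative low-cover "
      "pixels, so the exact method reads out a threshold well below the "
      "truth; the neighborhood mean absorbs part of that error and lands "
      "closer to (though still below) the true tolerance.")
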