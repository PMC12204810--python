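"""Temporal matching of occurrences to annual habitat layers and
deforestation-tolerance-threshold (DTT) estimation.

The DTT is the lowest habitat-cover percentage at which the species is
inferred to persist: each occurrence is matched to the cover layer of its
collection year, the cover value at its coordinates is extracted (from the
raw layer for the *exact* method, or from the neighborhood-processed layer),
the values are ranked, suspect low-ranking records are dropped after
inspection, and the minimum surviving value is the threshold.

Record dropping is never automated here: identifying an aberrant record
takes imagery inspection and natural-history judgement, so the API accepts
an explicit list of record ids (with a ``drop_count`` convenience that drops
the k lowest entries), and everything dropped is kept in the result ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grids import AnnualSeries, RasterGrid
from .occurrences import OccurrenceSet, Status
from .projection import points_to_crs

__all__ = [
    "MatchedValue",
    "DTTResult",
    "filter_by_year_range",
    "extract_matched_values",
    "rank_matched_values",
    "select_dtt",
    "filter_records_by_habitat",
]


@dataclass(frozen=True)
class MatchedValue:
    """One occurrence's habitat-cover value for its collection year."""

    record_id: str
    year_used: int
    method: str  # "exact" | "neighborhood"
    cover_value: float


@dataclass(frozen=True)
class DTTResult:
    """Ranked matched values, the drop ledger, and the selected threshold."""

    method: str
    ranked: tuple[MatchedValue, ...]
    dropped_ids: tuple[str, ...]
    threshold: float

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "threshold": self.threshold,
            "dropped_ids": list(self.dropped_ids),
            "ranked": [
                {
                    "record_id": m.record_id,
                    "year_used": m.year_used,
                    "cover_value": m.cover_value,
                    "dropped": m.record_id in self.dropped_ids,
                }
                for m in self.ranked
            ],
        }


def filter_by_year_range(records: OccurrenceSet, min_year: int,
                         max_year: int) -> OccurrenceSet:
    """Keep active only the records collected within ``[min_year, max_year]``.

    Records without a collection year are marked ``dropped_no_year``;
    out-of-window records ``dropped_out_of_range``.  Boundary years are
    inside the window.
    """
    if min_year > max_year:
        raise ValueError(f"min_year {min_year} > max_year {max_year}")
    updates = {}
    for r in records.active():
        if r.year is None:
            updates[r.record_id] = Status.DROPPED_NO_YEAR
        elif not (min_year <= r.year <= max_year):
            updates[r.record_id] = Status.DROPPED_OUT_OF_RANGE
    return records.with_status(updates, f"year filter [{min_year}, {max_year}]")


def extract_matched_values(
    records: OccurrenceSet,
    series: AnnualSeries,
    method: str = "exact",
    year_policy: str = "strict",
) -> tuple[list[MatchedValue], OccurrenceSet]:
    """Extract each active record's cover value from its collection-year layer.

    *series* must already be the layer stack appropriate for *method* — the
    raw annual layers for ``"exact"``, the focal-processed ones for
    ``"neighborhood"``; *method* only labels the output.

    Records landing outside the raster or on a nodata pixel are marked
    ``dropped_nodata`` (not an error); records still lacking a year are
    marked ``dropped_no_year``.  A record whose year has no layer raises
    under ``year_policy="strict"``; ``"nearest"`` substitutes the closest
    available year (logged in the audit trail via the returned set).

    Returns the matched values and the updated occurrence set.
    """
    if method not in ("exact", "neighborhood"):
        raise ValueError(f"method must be 'exact' or 'neighborhood', got {method!r}")
    if year_policy not in ("strict", "nearest"):
        raise ValueError(f"year_policy must be 'strict' or 'nearest', got {year_policy!r}")

    crs = series.grid.crs
    updates: dict[str, Status] = {}
    matched: list[MatchedValue] = []
    for r in records.active():
        if r.year is None:
            updates[r.record_id] = Status.DROPPED_NO_YEAR
            continue
        if r.year in series:
            year_used = r.year
        elif year_policy == "nearest":
            year_used = series.nearest_year(r.year)
        else:
            raise KeyError(
                f"record {r.record_id!r}: no habitat layer for year {r.year} "
                f"(series covers {min(series.years)}-{max(series.years)})"
            )
        layer = series[year_used]
        xy = points_to_crs([(r.lon, r.lat)], crs)
        value = float(layer.sample(xy[:, 0], xy[:, 1])[0])
        if value == layer.nodata:
            updates[r.record_id] = Status.DROPPED_NODATA
            continue
        matched.append(MatchedValue(r.record_id, year_used, method, value))
    occ = records.with_status(updates, f"matched-value extraction ({method})")
    return matched, occ


def rank_matched_values(values: Sequence[MatchedValue]) -> list[MatchedValue]:
    """Stable ascending sort by cover value (ties keep input order)."""
    if not values:
        raise ValueError("cannot rank an empty list of matched values")
    return sorted(values, key=lambda m: m.cover_value)


def select_dtt(
    ranked: Sequence[MatchedValue],
    drop_ids: Sequence[str] = (),
    drop_count: int = 0,
) -> DTTResult:
    """Choose the tolerance threshold: the minimum cover value among records
    not dropped.

    ``drop_ids`` names records judged aberrant (e.g. after imagery
    inspection); ``drop_count=k`` additionally drops the k lowest-ranked
    entries.  Entries — not distinct values — are dropped, so when two
    records tie at the minimum, dropping one of them leaves the threshold
    unchanged.
    """
    if not ranked:
        raise ValueError("cannot select a threshold from an empty ranking")
    ranked = rank_matched_values(ranked)
    ids = [m.record_id for m in ranked]
    unknown = sorted(set(drop_ids) - set(ids))
    if unknown:
        raise ValueError(f"drop_ids not present in ranking: {', '.join(unknown)}")
    if drop_count < 0:
        raise ValueError("drop_count must be >= 0")
    dropped = set(drop_ids)
    to_drop = drop_count
    for m in ranked:
        if to_drop == 0:
            break
        if m.record_id not in dropped:
            dropped.add(m.record_id)
            to_drop -= 1
    survivors = [m for m in ranked if m.record_id not in dropped]
    if not survivors:
        raise ValueError("all records dropped; no threshold can be selected")
    # ordered ledger: dropped ids in rank order
    dropped_ordered = tuple(m.record_id for m in ranked if m.record_id in dropped)
    return DTTResult(
        method=ranked[0].method,
        ranked=tuple(ranked),
        dropped_ids=dropped_ordered,
        threshold=survivors[0].cover_value,
    )


def filter_records_by_habitat(
    records: OccurrenceSet, current_layer: RasterGrid, dtt: float
) -> OccurrenceSet:
    """Drop active records whose current habitat cover is strictly below *dtt*.

    Mirrors the masking rule: cover >= dtt is retained (boundary kept).
    *current_layer* should be the most recent habitat layer, raw for an
    exact-method threshold or focal-processed for a neighborhood one.
    Records on nodata pixels are marked ``dropped_nodata``.
    """
    updates: dict[str, Status] = {}
    for r in records.active():
        xy = points_to_crs([(r.lon, r.lat)], current_layer.crs)
        value = float(current_layer.sample(xy[:, 0], xy[:, 1])[0])
        if value == current_layer.nodata:
            updates[r.record_id] = Status.DROPPED_NODATA
        elif value < dtt:
            updates[r.record_id] = Status.DROPPED_BELOW_DTT
    return records.with_status(updates, f"habitat filter (cover < {dtt})")
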