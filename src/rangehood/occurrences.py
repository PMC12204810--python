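"""Occurrence records with an append-only audit trail.

Every record keeps its original row forever; pipeline stages never delete,
they flip ``status`` and append a reason to the set's audit log.  This makes
the record-dropping decisions of a range assessment (year filtering,
aberrant-value removal, habitat filtering) fully reconstructible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = ["Status", "OccurrenceRecord", "OccurrenceSet", "read_occurrences",
           "write_occurrences"]


class Status(str, Enum):
    ACTIVE = "active"
    DROPPED_ABERRANT = "dropped_aberrant"
    DROPPED_BELOW_DTT = "dropped_below_dtt"
    DROPPED_NO_YEAR = "dropped_no_year"
    DROPPED_NODATA = "dropped_nodata"
    DROPPED_OUT_OF_RANGE = "dropped_out_of_range"  # collection year outside the analysis window


@dataclass(frozen=True)
class OccurrenceRecord:
    record_id: str
    lon: float
    lat: float
    year: int | None = None
    coord_uncertainty_m: float | None = None
    status: Status = Status.ACTIVE

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"record {self.record_id!r}: longitude {self.lon} outside [-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"record {self.record_id!r}: latitude {self.lat} outside [-90, 90]")


@dataclass(frozen=True)
class AuditEntry:
    record_id: str
    old_status: Status
    new_status: Status
    reason: str


class OccurrenceSet:
    """Ordered collection of occurrence records plus the audit log.

    Conservation invariant: the number of records never changes across
    pipeline stages; ``n_active + n_dropped == n_total`` always.
    """

    def __init__(self, records: Iterable[OccurrenceRecord],
                 audit: Sequence[AuditEntry] = ()):
        self._records = list(records)
        ids = [r.record_id for r in self._records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate record ids: {', '.join(dupes)}")
        self._audit = list(audit)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[OccurrenceRecord]:
        return iter(self._records)

    def __getitem__(self, record_id: str) -> OccurrenceRecord:
        for r in self._records:
            if r.record_id == record_id:
                return r
        raise KeyError(record_id)

    @property
    def records(self) -> list[OccurrenceRecord]:
        return list(self._records)

    @property
    def audit(self) -> list[AuditEntry]:
        return list(self._audit)

    def active(self) -> list[OccurrenceRecord]:
        return [r for r in self._records if r.status is Status.ACTIVE]

    @property
    def n_active(self) -> int:
        return len(self.active())

    def status_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self._records:
            counts[r.status.value] = counts.get(r.status.value, 0) + 1
        return counts

    def with_status(self, updates: Mapping[str, Status], reason: str) -> "OccurrenceSet":
        """Return a new set with *updates* applied; original is untouched."""
        known = {r.record_id for r in self._records}
        unknown = sorted(set(updates) - known)
        if unknown:
            raise KeyError(f"unknown record ids: {', '.join(unknown)}")
        new_records, new_audit = [], list(self._audit)
        for r in self._records:
            if r.record_id in updates and r.status is not updates[r.record_id]:
                new_status = updates[r.record_id]
                new_audit.append(AuditEntry(r.record_id, r.status, new_status, reason))
                r = replace(r, status=new_status)
            new_records.append(r)
        return OccurrenceSet(new_records, new_audit)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "record_id": [r.record_id for r in self._records],
                "lon": [r.lon for r in self._records],
                "lat": [r.lat for r in self._records],
                "year": [r.year for r in self._records],
                "coord_uncertainty_m": [r.coord_uncertainty_m for r in self._records],
                "status": [r.status.value for r in self._records],
            }
        )


# Darwin-Core-flavoured column aliases, checked in order.
_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "record_id": ("record_id", "id", "recordid", "catalognumber", "occurrenceid"),
    "lon": ("lon", "longitude", "decimallongitude", "x"),
    "lat": ("lat", "latitude", "decimallatitude", "y"),
    "year": ("year", "collection_year", "yearcollected"),
    "coord_uncertainty_m": ("coord_uncertainty_m", "coordinateuncertaintyinmeters",
                            "uncertainty_m"),
}


def _resolve_columns(columns: Sequence[str],
                     column_map: Mapping[str, str] | None) -> dict[str, str | None]:
    lower = {c.lower(): c for c in columns}
    resolved: dict[str, str | None] = {}
    for field_name, aliases in _COLUMN_ALIASES.items():
        if column_map and field_name in column_map:
            wanted = column_map[field_name]
            if wanted not in columns:
                raise ValueError(f"column {wanted!r} (mapped to {field_name}) not in CSV header")
            resolved[field_name] = wanted
            continue
        resolved[field_name] = next((lower[a] for a in aliases if a in lower), None)
    for required in ("record_id", "lon", "lat"):
        if resolved[required] is None:
            raise ValueError(
                f"could not find a column for {required!r}; header was {list(columns)}"
            )
    return resolved


def read_occurrences(path: str | Path,
                     column_map: Mapping[str, str] | None = None) -> OccurrenceSet:
    """Load an occurrence CSV; all records start with status ``active``.

    The CSV needs id, longitude and latitude columns (Darwin-Core names such
    as ``decimalLongitude`` are auto-recognised; *column_map* overrides).
    Year and coordinate uncertainty are optional per record and retained as
    missing when absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"occurrence file not found: {path}")
    df = pd.read_csv(path)
    cols = _resolve_columns(list(df.columns), column_map)
    records = []
    for i, row in df.iterrows():
        rid = str(row[cols["record_id"]])
        try:
            lon = float(row[cols["lon"]])
            lat = float(row[cols["lat"]])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {i} (id {rid!r}): unparseable coordinates") from exc
        if math.isnan(lon) or math.isnan(lat):
            raise ValueError(f"row {i} (id {rid!r}): missing coordinates")
        year = None
        if cols["year"] is not None:
            raw = row[cols["year"]]
            if pd.notna(raw):
                year = int(raw)
        unc = None
        if cols["coord_uncertainty_m"] is not None:
            raw = row[cols["coord_uncertainty_m"]]
            if pd.notna(raw):
                unc = float(raw)
        try:
            records.append(OccurrenceRecord(rid, lon, lat, year, unc))
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return OccurrenceSet(records)


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    occ.to_frame().to_csv(path, index=False)
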