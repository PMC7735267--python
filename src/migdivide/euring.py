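"""Filtering of ringing-recovery records to directed southward migrations.

A recovery pairs a ringing encounter with a later re-encounter of the same
bird.  Records are retained when they plausibly represent a directed
movement from the Austrian breeding region towards the wintering grounds:

1. first encounter inside the breeding box (8-20 degrees E,
   46.6-48.7 degrees N) during the breeding season (15 May - 15 Aug);
2. re-encounter during migration/wintering (1 Oct - 1 May, wrapping the
   year end);
3. a southward movement: rhumb bearing in [100, 270] degrees (inclusive)
   over at least 500 km great-circle distance.

Seasonal windows are evaluated on month-day only, since ringing years vary.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .geodesy import GeoPoint, great_circle_distance, rhumb_bearing

#: Audit order; a record failing several criteria is counted once,
#: under the first failed criterion in this order.
CRITERIA = ("breeding_box", "breeding_window", "recovery_window", "bearing", "distance")


@dataclass(frozen=True)
class Encounter:
    date: dt.date
    point: GeoPoint


@dataclass(frozen=True)
class RecoveryRecord:
    """One ringing encounter paired with one later re-encounter."""

    ring_id: str
    first: Encounter
    second: Encounter

    def __post_init__(self) -> None:
        if self.second.date <= self.first.date:
            raise ValueError(f"record {self.ring_id}: re-encounter must postdate ringing")


@dataclass(frozen=True)
class FilterCriteria:
    lon_min: float = 8.0
    lon_max: float = 20.0
    lat_min: float = 46.6
    lat_max: float = 48.7
    breeding_window: tuple[tuple[int, int], tuple[int, int]] = ((5, 15), (8, 15))
    recovery_window: tuple[tuple[int, int], tuple[int, int]] = ((10, 1), (5, 1))
    bearing_min: float = 100.0
    bearing_max: float = 270.0
    min_distance_km: float = 500.0


def _in_md_window(date: dt.date, window: tuple[tuple[int, int], tuple[int, int]]) -> bool:
    """Inclusive month-day window membership, wrapping the year end."""
    start, end = window
    md = (date.month, date.day)
    if start <= end:
        return start <= md <= end
    return md >= start or md <= end


def passes_filter(record: RecoveryRecord,
                  criteria: FilterCriteria | None = None) -> tuple[bool, list[str]]:
    """Evaluate one record; returns (passed, list of failed criteria)."""
    c = criteria or FilterCriteria()
    reasons = []
    p1, p2 = record.first.point, record.second.point
    if not (c.lon_min <= p1.lon <= c.lon_max and c.lat_min <= p1.lat <= c.lat_max):
        reasons.append("breeding_box")
    if not _in_md_window(record.first.date, c.breeding_window):
        reasons.append("breeding_window")
    if not _in_md_window(record.second.date, c.recovery_window):
        reasons.append("recovery_window")
    if p1.lat == p2.lat and p1.lon == p2.lon:
        reasons.append("bearing")
        reasons.append("distance")
        return False, reasons
    if not c.bearing_min <= rhumb_bearing(p1, p2) <= c.bearing_max:
        reasons.append("bearing")
    if great_circle_distance(p1, p2) < c.min_distance_km:
        reasons.append("distance")
    return not reasons, reasons


def filter_recoveries(records: Sequence[RecoveryRecord],
                      criteria: FilterCriteria | None = None,
                      ) -> tuple[list[RecoveryRecord], pd.DataFrame]:
    """Apply the filter to a batch; returns retained records and an audit table.

    A ring with several re-encounters appears as several records; it is
    retained if any of them passes.  The audit table has one row per input
    record (ring_id, passed, failed criteria, primary failure); the count
    of passes plus primary-failure counts equals the input size, so no
    record is double-counted.
    """
    rows = []
    verdict_by_ring: dict[str, bool] = {}
    for rec in records:
        ok, reasons = passes_filter(rec, criteria)
        primary = next((cr for cr in CRITERIA if cr in reasons), None)
        rows.append({
            "ring_id": rec.ring_id,
            "passed": ok,
            "failed_criteria": ";".join(reasons),
            "primary_failure": primary or "",
        })
        verdict_by_ring[rec.ring_id] = verdict_by_ring.get(rec.ring_id, False) or ok
    audit = pd.DataFrame(rows, columns=["ring_id", "passed", "failed_criteria",
                                        "primary_failure"])
    retained = [rec for rec, row in zip(records, rows)
                if verdict_by_ring[rec.ring_id] and row["passed"]]
    return retained, audit


def audit_counts(audit: pd.DataFrame) -> dict[str, int]:
    """Failure counts per criterion (primary failures) plus passes."""
    counts = {cr: 0 for cr in CRITERIA}
    counts["passed"] = int(audit["passed"].sum())
    for primary in audit.loc[~audit["passed"], "primary_failure"]:
        counts[primary] += 1
    return counts
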