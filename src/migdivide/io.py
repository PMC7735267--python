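"""CSV schemas shared by the pipeline stages.

Bird summary tables
    bird_id, year, sex, region, breed_lat, breed_lon, winter_lat,
    winter_lon, phenotype, direction_deg, distance_km

Track tables (long format, one row per daily fix)
    bird_id, season, date, lat, lon, spread_km

Recovery tables (minimal EURING-2000-style mapping, one row per record)
    ring_id, date1, lat1, lon1, date2, lat2, lon2
"""

from __future__ import annotations

import datetime as dt
from typing import Sequence

import pandas as pd

from .euring import Encounter, RecoveryRecord
from .geodesy import GeoPoint
from .timing import TrackSeries

BIRD_COLUMNS = ["bird_id", "year", "sex", "region", "breed_lat", "breed_lon",
                "winter_lat", "winter_lon", "phenotype", "direction_deg",
                "distance_km"]
TRACK_COLUMNS = ["bird_id", "season", "date", "lat", "lon", "spread_km"]
RECOVERY_COLUMNS = ["ring_id", "date1", "lat1", "lon1", "date2", "lat2", "lon2"]


class SchemaError(ValueError):
    """A CSV did not match the expected schema (message names the problem row)."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_bird_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["bird_id", "breed_lat", "breed_lon",
                          "winter_lat", "winter_lon"], path)
    for i, row in df.iterrows():
        for col in ("breed_lat", "breed_lon", "winter_lat", "winter_lon"):
            v = row[col]
            if pd.isna(v):
                raise SchemaError(f"{path}: row {i + 2}: missing {col}")
        if not -90 <= row["breed_lat"] <= 90 or not -90 <= row["winter_lat"] <= 90:
            raise SchemaError(f"{path}: row {i + 2}: latitude out of range")
    return df


def write_bird_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in BIRD_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


def read_tracks(path) -> list[TrackSeries]:
    df = pd.read_csv(path, parse_dates=["date"])
    _require_columns(df, ["bird_id", "season", "date", "lat", "lon"], path)
    tracks = []
    for (bird, season), grp in df.groupby(["bird_id", "season"], sort=True):
        grp = grp.sort_values("date")
        spread = grp["spread_km"].to_numpy() if "spread_km" in grp else None
        try:
            tracks.append(TrackSeries(
                bird_id=str(bird), season=str(season),
                dates=pd.DatetimeIndex(grp["date"]),
                lats=grp["lat"].to_numpy(), lons=grp["lon"].to_numpy(),
                spread_km=spread))
        except ValueError as exc:
            raise SchemaError(f"{path}: track {bird}/{season}: {exc}") from exc
    return tracks


def write_tracks(tracks: Sequence[TrackSeries], path) -> None:
    frames = []
    for tr in tracks:
        frames.append(pd.DataFrame({
            "bird_id": tr.bird_id, "season": tr.season,
            "date": tr.dates.strftime("%Y-%m-%d"),
            "lat": tr.lats, "lon": tr.lons,
            "spread_km": 0.0 if tr.spread_km is None else tr.spread_km,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_recoveries(path) -> list[RecoveryRecord]:
    df = pd.read_csv(path)
    _require_columns(df, RECOVERY_COLUMNS, path)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(RecoveryRecord(
                ring_id=str(row["ring_id"]),
                first=Encounter(dt.date.fromisoformat(str(row["date1"])),
                                GeoPoint(float(row["lat1"]), float(row["lon1"]))),
                second=Encounter(dt.date.fromisoformat(str(row["date2"])),
                                 GeoPoint(float(row["lat2"]), float(row["lon2"])))))
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def write_recoveries(records: Sequence[RecoveryRecord], path) -> None:
    pd.DataFrame([{
        "ring_id": r.ring_id,
        "date1": r.first.date.isoformat(), "lat1": r.first.point.lat,
        "lon1": r.first.point.lon,
        "date2": r.second.date.isoformat(), "lat2": r.second.point.lat,
        "lon2": r.second.point.lon,
    } for r in records], columns=RECOVERY_COLUMNS).to_csv(path, index=False)
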