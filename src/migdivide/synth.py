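"""Seeded synthetic cohorts, tracks, arrivals and recovery records.

The generators emulate the statistical structure of a geolocator study of
a central-European migratory divide: breeding sites along an east-west
Austrian transect (46.6-48.7 N), autumn migration directions following a
sharp sigmoid cline (centre 14.0 E, width 0.36 degrees of longitude, about
27 km at the transect latitude) with individual scatter of 20 degrees,
geolocator-like daily tracks whose latitude noise inflates near the
equinoxes, per-phenotype spring arrival distributions, and EURING-style
ringing recoveries.  Every generator is a pure function of (config, seed);
ground truth (generating parameters, true crossing dates, expected filter
verdicts) is returned alongside the data so downstream estimators can be
tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cline import ClineParams, cline_mean
from .euring import Encounter, FilterCriteria, RecoveryRecord
from .geodesy import GeoPoint, gc_interpolate, great_circle_distance, rhumb_destination
from .phenotyping import ClassificationRule, classify_winter
from .timing import TrackSeries, days_from_equinox

#: Observed divide phenotype shares (22 S, 11 SE, 7 SW and 1 NW of 41 tracks).
DIVIDE_PROPORTIONS = {"S": 22 / 41, "SE": 11 / 41, "SW": 7 / 41, "NW": 1 / 41}

DEFAULT_CLINE = ClineParams(center=14.0, width=0.36,
                            mu_left=245.0, mu_right=150.0, sigma=20.0)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for the synthetic divide cohort.

    The cline parameters, transect extent, phenotype-specific migration
    distances and arrival shifts reproduce the conditions of the tracked
    divide population; track noise reflects geolocation error (longitude
    more precise than latitude, latitude unreliable near equinoxes).
    """

    rng_seed: int = 0
    n_birds: int = 160
    lat_range: tuple[float, float] = (46.6, 48.7)
    lon_range: tuple[float, float] = (12.0, 16.0)
    cline: ClineParams = DEFAULT_CLINE
    #: fraction of birds drawn from a Gaussian around the divide centre
    #: (denser sampling near the contact zone), remainder uniform.
    center_sampling_frac: float = 0.5
    center_sampling_sd: float = 0.4
    #: zone labels for grouping: divide = centre +- this many degrees.
    divide_halfwidth_deg: float = 0.5
    #: great-circle migration distance (mean, sd) km per phenotype.
    distance_model: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        "SW": (1865.0, 400.0), "S": (1600.0, 400.0),
        "SE": (1865.0, 400.0), "NW": (940.0, 360.0)})
    min_distance_km: float = 600.0
    #: spring arrival day-of-year means per phenotype (S arrives 8.9 d and
    #: NW 9.8 d before the SW/SE baseline of 10 April).
    arrival_means: Mapping[str, float] = field(default_factory=lambda: {
        "SW": 100.0, "SE": 100.0, "S": 100.0 - 8.9, "NW": 100.0 - 9.8})
    arrival_sd: float = 6.0
    #: spring migration start day-of-year means (S starts 14.6 d early).
    spring_start_means: Mapping[str, float] = field(default_factory=lambda: {
        "SW": 74.0, "SE": 74.0, "S": 74.0 - 14.6, "NW": 74.0 - 9.8})
    spring_start_sd: float = 7.0
    #: daily position noise, degrees.
    track_lon_sd: float = 0.5
    track_lat_sd: float = 1.5
    equinox_lat_factor: float = 3.0
    equinox_window_days: float = 7.0
    #: daily travel speed (mean, sd) km/day while migrating.
    speed_mean: float = 120.0
    speed_sd: float = 30.0
    years: tuple[int, ...] = (2016, 2017, 2018, 2019)


def generate_divide_cohort(cfg: SimConfig | None = None,
                           rule: ClassificationRule | None = None) -> pd.DataFrame:
    """Synthetic bird-summary table for the divide transect.

    Breeding longitudes mix uniform coverage with denser sampling near the
    cline centre; each bird's autumn direction is the cline mean at its
    longitude plus Normal(0, sigma) scatter, its wintering site the rhumb
    destination at a phenotype-typical distance, and its phenotype the
    winter-location classification of that site.  ``zone`` labels
    (west/divide/east) support the grouped cline fit.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_birds
    from_center = rng.random(n) < cfg.center_sampling_frac
    lons = np.where(
        from_center,
        np.clip(rng.normal(cfg.cline.center, cfg.center_sampling_sd, n), *cfg.lon_range),
        rng.uniform(*cfg.lon_range, n))
    lats = rng.uniform(*cfg.lat_range, n)
    directions = cline_mean(lons, cfg.cline.center, cfg.cline.width,
                            cfg.cline.mu_left, cfg.cline.mu_right)
    directions = directions + rng.normal(0.0, cfg.cline.sigma, n)
    rows = []
    for i in range(n):
        breeding = GeoPoint(float(lats[i]), float(lons[i]))
        # distance model chosen by the direction-implied strategy
        strategy = "SW" if directions[i] >= 210 else ("SE" if directions[i] <= 165 else "S")
        mean_d, sd_d = cfg.distance_model[strategy]
        dist = max(cfg.min_distance_km, rng.normal(mean_d, sd_d))
        wintering = rhumb_destination(breeding, float(directions[i]), dist)
        zone = ("west" if lons[i] < cfg.cline.center - cfg.divide_halfwidth_deg
                else "east" if lons[i] > cfg.cline.center + cfg.divide_halfwidth_deg
                else "divide")
        rows.append({
            "bird_id": f"B{i:04d}",
            "year": int(rng.choice(cfg.years)),
            "sex": "M",
            "region": "divide_transect",
            "breed_lat": breeding.lat,
            "breed_lon": breeding.lon,
            "winter_lat": wintering.lat,
            "winter_lon": wintering.lon,
            "phenotype": classify_winter(wintering, rule),
            "direction_deg": float(directions[i]) % 360.0,
            "direction_true_deg": float(directions[i]),
            "distance_km": great_circle_distance(breeding, wintering),
            "zone": zone,
        })
    return pd.DataFrame(rows)


def generate_tracks(cohort: pd.DataFrame, cfg: SimConfig | None = None,
                    fractions: Sequence[float] = (0.30, 0.50, 0.70),
                    ) -> tuple[list[TrackSeries], pd.DataFrame]:
    """Noisy daily autumn tracks plus the true threshold-crossing dates.

    Each bird departs in early autumn, sits a few days at the breeding
    site, travels along the great circle at a drawn daily speed, then sits
    at the wintering site.  Gaussian position noise is added with latitude
    error inflated within a week of an equinox.  The returned truth table
    holds the noiseless crossing date of each route fraction.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.rng_seed + 1)
    tracks: list[TrackSeries] = []
    truth_rows = []
    for row in cohort.itertuples(index=False):
        breeding = GeoPoint(row.breed_lat, row.breed_lon)
        wintering = GeoPoint(row.winter_lat, row.winter_lon)
        total = great_circle_distance(breeding, wintering)
        # autumn departure peaks from mid-September into early October
        depart = pd.Timestamp(year=int(row.year), month=9, day=15) + pd.Timedelta(
            days=float(rng.uniform(0, 25)))
        pre, post = 3, 10
        cum = [0.0]
        while cum[-1] < total:
            cum.append(cum[-1] + max(10.0, rng.normal(cfg.speed_mean, cfg.speed_sd)))
        frac_per_day = np.concatenate([
            np.zeros(pre), np.minimum(np.array(cum) / total, 1.0), np.ones(post)])
        dates = pd.date_range(depart - pd.Timedelta(days=pre), periods=frac_per_day.size,
                              freq="D")
        lat_true = np.empty(frac_per_day.size)
        lon_true = np.empty(frac_per_day.size)
        for j, f in enumerate(frac_per_day):
            p = gc_interpolate(breeding, wintering, float(f))
            lat_true[j], lon_true[j] = p.lat, p.lon
        lat_sd = np.full(frac_per_day.size, cfg.track_lat_sd)
        near_eq = np.array([days_from_equinox(d) <= cfg.equinox_window_days for d in dates])
        lat_sd[near_eq] *= cfg.equinox_lat_factor
        lats = np.clip(lat_true + rng.normal(0.0, lat_sd), -90.0, 90.0)
        lons = lon_true + rng.normal(0.0, cfg.track_lon_sd, frac_per_day.size)
        tracks.append(TrackSeries(bird_id=row.bird_id, season="autumn",
                                  dates=pd.DatetimeIndex(dates), lats=lats, lons=lons))
        # noiseless crossing dates: linear interpolation of the daily fractions
        day0 = dates[0]
        truth = {"bird_id": row.bird_id}
        t_days = np.arange(frac_per_day.size, dtype=float)
        for f in fractions:
            idx = int(np.searchsorted(frac_per_day, f))
            if frac_per_day[idx] == f:
                t_cross = t_days[idx]
            else:
                g0, g1 = frac_per_day[idx - 1], frac_per_day[idx]
                t_cross = t_days[idx - 1] + (f - g0) / (g1 - g0)
            truth[f"t{int(round(f * 100))}_true"] = day0 + pd.Timedelta(days=float(t_cross))
        truth_rows.append(truth)
    return tracks, pd.DataFrame(truth_rows)


def generate_arrivals(cohort: pd.DataFrame, cfg: SimConfig | None = None,
                      ) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Per-bird spring arrival and spring start dates (day-of-year).

    Gaussian per-phenotype models; the generating means and SDs are
    returned as ground truth so contrast estimators can be checked for
    recovery of the configured shifts.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.rng_seed + 2)
    arrival = np.array([rng.normal(cfg.arrival_means[p], cfg.arrival_sd)
                        for p in cohort["phenotype"]])
    spring_start = np.array([rng.normal(cfg.spring_start_means[p], cfg.spring_start_sd)
                             for p in cohort["phenotype"]])
    out = cohort.copy()
    out["arrival_doy"] = arrival
    out["spring_start_doy"] = spring_start
    truth = {
        "arrival_means": dict(cfg.arrival_means),
        "arrival_sd": {"sd": cfg.arrival_sd},
        "spring_start_means": dict(cfg.spring_start_means),
        "spring_start_sd": {"sd": cfg.spring_start_sd},
    }
    return out, truth


def generate_timing_cohort(counts: Mapping[str, int],
                           shifts: Mapping[str, float],
                           sd: float,
                           response: str = "arrival_doy",
                           baseline_doy: float = 100.0,
                           seed: int = 0,
                           years: Sequence[int] = (2016, 2017, 2018, 2019),
                           ) -> pd.DataFrame:
    """Minimal cohort for timing-model recovery experiments.

    Phenotype group sizes are fixed by ``counts``; the response is
    Normal(baseline + shift[phenotype], sd).  Breeding coordinates, year
    and sex are drawn with zero true effect on the response, so the only
    structure the contrast model should find is the configured shift.
    """
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for phen in sorted(counts):
        for _ in range(counts[phen]):
            rows.append({
                "bird_id": f"T{i:04d}",
                "phenotype": phen,
                "breed_lat": rng.uniform(46.6, 48.7),
                "breed_lon": rng.uniform(8.0, 20.0),
                "year": int(rng.choice(list(years))),
                "sex": rng.choice(["M", "F"]),
                response: rng.normal(baseline_doy + shifts.get(phen, 0.0), sd),
            })
            i += 1
    return pd.DataFrame(rows)


def generate_recoveries(cfg: SimConfig | None = None,
                        n_random: int = 20,
                        criteria: FilterCriteria | None = None,
                        ) -> tuple[list[RecoveryRecord], pd.DataFrame]:
    """Stratified EURING-like recovery records with expected verdicts.

    One clean pass plus one record violating each filter criterion in
    isolation, then ``n_random`` randomised records (jittered around the
    passing template) whose expected verdicts are computed directly from
    the construction.  Returns (records, table of expected verdicts).
    """
    import datetime as dt

    cfg = cfg or SimConfig()
    c = criteria or FilterCriteria()
    rng = np.random.default_rng(cfg.rng_seed + 3)

    def rec(ring, d1, p1, d2, p2):
        return RecoveryRecord(ring_id=ring, first=Encounter(d1, p1),
                              second=Encounter(d2, p2))

    base_first = (dt.date(2001, 6, 10), GeoPoint(47.5, 14.0))
    base_second = (dt.date(2001, 12, 1), GeoPoint(41.5, 14.0))  # ~667 km due S
    strata = [
        ("pass", rec("R000", *base_first, *base_second), True),
        ("breeding_box", rec("R001", base_first[0], GeoPoint(50.5, 14.0),
                             *base_second), False),
        ("breeding_window", rec("R002", dt.date(2001, 9, 1), base_first[1],
                                *base_second), False),
        ("recovery_window", rec("R003", *base_first,
                                dt.date(2002, 6, 15), base_second[1]), False),
        ("bearing", rec("R004", *base_first,
                        dt.date(2001, 12, 1), GeoPoint(53.5, 14.0)), False),
        ("distance", rec("R005", *base_first,
                         dt.date(2001, 12, 1), GeoPoint(44.9, 14.0)), False),
    ]
    records = [s[1] for s in strata]
    rows = [{"ring_id": s[1].ring_id, "stratum": s[0], "expected_pass": s[2]}
            for s in strata]
    # randomised records: each criterion is independently violated or not,
    # and the record is built so its verdict follows from that construction.
    for i in range(n_random):
        violate = {cr: bool(rng.random() < 0.3) for cr in
                   ("breeding_box", "breeding_window", "recovery_window",
                    "bearing", "distance")}
        lat1 = (c.lat_max + rng.uniform(0.5, 2.0) if violate["breeding_box"]
                else rng.uniform(c.lat_min + 0.05, c.lat_max - 0.05))
        lon1 = rng.uniform(c.lon_min + 0.5, c.lon_max - 0.5)
        d1 = (dt.date(2001, 9, int(rng.integers(1, 28))) if violate["breeding_window"]
              else dt.date(2001, 6, int(rng.integers(1, 28))))
        d2 = (dt.date(2002, 7, int(rng.integers(1, 28))) if violate["recovery_window"]
              else dt.date(2001, 12, int(rng.integers(1, 28))))
        # due-south (or due-north) displacement keeps the bearing exactly on
        # 180 (or 0) degrees, so bearing and distance decouple cleanly.
        dlat = rng.uniform(6.0, 9.0) if not violate["distance"] else rng.uniform(0.5, 2.0)
        lat2 = lat1 + dlat if violate["bearing"] else lat1 - dlat
        r = rec(f"R{100 + i}", d1, GeoPoint(lat1, lon1), d2, GeoPoint(lat2, lon1))
        records.append(r)
        rows.append({"ring_id": r.ring_id, "stratum": "random",
                     "expected_pass": not any(violate.values())})
    return records, pd.DataFrame(rows)


def tracks_to_geojson(tracks: Sequence[TrackSeries]) -> dict:
    """GeoJSON FeatureCollection of LineStrings for visual inspection."""
    features = []
    for tr in tracks:
        features.append({
            "type": "Feature",
            "properties": {"bird_id": tr.bird_id, "season": tr.season,
                           "start": str(tr.dates[0].date()),
                           "end": str(tr.dates[-1].date())},
            "geometry": {
                "type": "LineString",
                "coordinates": [[round(float(lo), 5), round(float(la), 5)]
                                for lo, la in zip(tr.lons, tr.lats)],
            },
        })
    return {"type": "FeatureCollection", "features": features}
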