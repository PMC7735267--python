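"""Migration timing from daily position series, and timing contrast models.

A bird's progress along its migration is measured against the great-circle
route between its summer and winter sites.  Perpendicular threshold lines
at 30%, 50% and 70% of the route mark early, middle and late migration;
the date a track crosses each line is estimated by projecting every daily
position onto the route axis.  Position uncertainty, when supplied as a
per-sample spread, is propagated by a seeded ensemble of perturbed tracks
and the 0.50-quantile crossing time is reported.

Downstream, ordinary least-squares models contrast timing variables
between migratory phenotypes (SW vs SE; intermediate S vs the SW/SE mean;
NW vs SW), with nuisance covariates removed by backward elimination at
p > 0.10.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .geodesy import (
    GeoPoint,
    gc_along_track_fraction,
    gc_initial_bearing,
    gc_interpolate,
    great_circle_distance,
)

logger = logging.getLogger(__name__)

#: Fixed equinox dates (month, day), UTC.
SPRING_EQUINOX = (3, 20)
AUTUMN_EQUINOX = (9, 22)


@dataclass(frozen=True)
class TrackSeries:
    """Dated position estimates for one bird and season.

    ``spread_km`` is an optional per-sample position SD (km) carried from
    the geolocation step; dates must be strictly increasing.
    """

    bird_id: str
    season: str  # "autumn" or "spring"
    dates: pd.DatetimeIndex
    lats: np.ndarray
    lons: np.ndarray
    spread_km: np.ndarray | None = None

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        lats = np.asarray(self.lats, dtype=float)
        lons = np.asarray(self.lons, dtype=float)
        if len(dates) < 2:
            raise ValueError("a track needs at least 2 samples")
        if not (len(dates) == lats.size == lons.size):
            raise ValueError("dates, lats and lons must have equal length")
        if not dates.is_monotonic_increasing or dates.has_duplicates:
            raise ValueError("track dates must be strictly increasing")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "lats", lats)
        object.__setattr__(self, "lons", lons)
        if self.spread_km is not None:
            spread = np.asarray(self.spread_km, dtype=float)
            if spread.size != lats.size:
                raise ValueError("spread_km length mismatch")
            object.__setattr__(self, "spread_km", spread)

    @property
    def last_fix_date(self) -> pd.Timestamp:
        return self.dates[-1]

    def __len__(self) -> int:
        return len(self.dates)


@dataclass(frozen=True)
class ThresholdLine:
    """A line perpendicular to the great-circle route at a route fraction."""

    fraction: float
    anchor: GeoPoint
    perpendicular_azimuth: float
    route_start: GeoPoint
    route_end: GeoPoint

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("threshold fraction must be strictly inside (0, 1)")


@dataclass(frozen=True)
class CrossingEstimate:
    """Crossing time of one threshold; ``time`` is None when estimation fails."""

    time: pd.Timestamp | None
    flags: tuple[str, ...] = ()


def build_thresholds(breeding: GeoPoint, wintering: GeoPoint,
                     fractions: Sequence[float] = (0.30, 0.50, 0.70)) -> list[ThresholdLine]:
    """Threshold lines perpendicular to the breeding->wintering great circle."""
    if breeding.lat == wintering.lat and breeding.lon == wintering.lon:
        raise ValueError("route endpoints coincide")
    lines = []
    for f in fractions:
        anchor = gc_interpolate(breeding, wintering, f)
        az = gc_initial_bearing(anchor, wintering)
        lines.append(ThresholdLine(fraction=f, anchor=anchor,
                                   perpendicular_azimuth=(az + 90.0) % 360.0,
                                   route_start=breeding, route_end=wintering))
    return lines


def _interp_crossing(times: np.ndarray, g: np.ndarray) -> tuple[float | None, str | None]:
    """First crossing time of g(t)=0, or (None, reason) on failure.

    ``times`` in float days; a sample exactly on the line counts as a
    crossing.  More than two crossings (the track wobbles across the line)
    or none at all is a failed estimate.
    """
    signs = np.sign(g)
    crossings = []
    for i in range(len(g) - 1):
        if signs[i] == 0:
            crossings.append(times[i])
        elif signs[i] * signs[i + 1] < 0:
            frac = -g[i] / (g[i + 1] - g[i])
            crossings.append(times[i] + frac * (times[i + 1] - times[i]))
    if signs[-1] == 0:
        crossings.append(times[-1])
    if not crossings:
        return None, "no-transit"
    if len(crossings) > 2:
        return None, "multi-transit"
    return crossings[0], None


_KM_PER_DEG = 111.195


def _weighted_fractions(dates: pd.DatetimeIndex, lats: np.ndarray, lons: np.ndarray,
                        start: GeoPoint, end: GeoPoint,
                        lat_sd_deg: float, lon_sd_deg: float,
                        equinox_lat_factor: float) -> np.ndarray:
    """Along-route fraction per sample, weighting longitude over latitude.

    Each sample is first projected onto the great circle (exact geodesic
    foot point); the along-route position is then corrected by the
    generalized-least-squares projection of the cross-track residual,
    using the anisotropic position error of light-level geolocation
    (longitude roughly three times more precise than latitude, latitude
    further degraded near the equinoxes).  With isotropic error SDs the
    correction vanishes and this reduces to the plain projection; on a
    noiseless on-route track it is exact regardless of the weights.
    """
    route_km = great_circle_distance(start, end)
    near_eq = np.array([days_from_equinox(d) <= 7.0 for d in dates])
    out = np.empty(lats.size)
    for i, (la, lo) in enumerate(zip(lats, lons)):
        f = gc_along_track_fraction(start, end, GeoPoint(la, lo))
        foot = gc_interpolate(start, end, f)
        step = gc_interpolate(start, end, f + 1e-4)
        if step.lat == foot.lat and step.lon == foot.lon:
            out[i] = f
            continue
        theta = math.radians(gc_initial_bearing(foot, step))
        u_n, u_e = math.cos(theta), math.sin(theta)
        d_n = (la - foot.lat) * _KM_PER_DEG
        d_e = (((lo - foot.lon + 180.0) % 360.0) - 180.0) * _KM_PER_DEG * math.cos(
            math.radians(foot.lat))
        s_n = lat_sd_deg * (equinox_lat_factor if near_eq[i] else 1.0) * _KM_PER_DEG
        s_e = lon_sd_deg * _KM_PER_DEG * math.cos(math.radians(foot.lat))
        w_n, w_e = 1.0 / s_n ** 2, 1.0 / s_e ** 2
        correction_km = (u_n * w_n * d_n + u_e * w_e * d_e) / (
            u_n ** 2 * w_n + u_e ** 2 * w_e)
        out[i] = f + correction_km / route_km
    return out


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    return pd.Series(values).rolling(window, center=True,
                                     min_periods=1).median().to_numpy()


def crossing_time(track: TrackSeries, line: ThresholdLine,
                  quantile: float = 0.50,
                  n_draws: int = 200,
                  seed: int = 0,
                  lat_sd_deg: float = 1.5,
                  lon_sd_deg: float = 0.5,
                  equinox_lat_factor: float = 3.0,
                  smooth_window: int = 3) -> CrossingEstimate:
    """Date at which a track crosses a route-fraction threshold line.

    Each daily position is projected onto the great-circle route to a
    signed along-route fraction, down-weighting the latitude component by
    the standard geolocation error anisotropy (``lat_sd_deg`` vs
    ``lon_sd_deg``, with latitude degraded by ``equinox_lat_factor``
    within a week of an equinox).  The fraction series is stabilised with
    a short centred rolling median (``smooth_window`` days) and crossing
    events are the sign changes of (fraction - line.fraction), linearly
    interpolated in time.  Tracks that never cross, or cross more than
    twice, yield a failed estimate with a flag (mirroring unusable
    threshold calculations near the route endpoints).  With per-sample
    position spread, the estimate is the ``quantile`` (default median) of
    crossing times over ``n_draws`` seeded perturbed tracks; it fails if
    more than half the draws do.
    """
    times = (track.dates - track.dates[0]) / pd.Timedelta(days=1)
    times = np.asarray(times, dtype=float)

    def series_of(lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
        fr = _weighted_fractions(track.dates, lats, lons,
                                 line.route_start, line.route_end,
                                 lat_sd_deg, lon_sd_deg, equinox_lat_factor)
        return _smooth(fr, smooth_window) - line.fraction

    has_spread = track.spread_km is not None and np.any(track.spread_km > 0)
    if not has_spread:
        t, reason = _interp_crossing(times, series_of(track.lats, track.lons))
        if t is None:
            return CrossingEstimate(time=None, flags=(reason,))
        return CrossingEstimate(time=track.dates[0] + pd.Timedelta(days=float(t)))

    rng = np.random.default_rng(seed)
    deg_sd = track.spread_km / _KM_PER_DEG
    hits = []
    flags: set[str] = set()
    for _ in range(n_draws):
        lats = np.clip(track.lats + rng.normal(0.0, deg_sd), -90.0, 90.0)
        lons = track.lons + rng.normal(0.0, deg_sd / np.cos(np.radians(np.clip(track.lats, -89.0, 89.0))))
        t, reason = _interp_crossing(times, series_of(lats, lons))
        if t is None:
            flags.add(reason)
        else:
            hits.append(t)
    if len(hits) <= n_draws / 2:
        return CrossingEstimate(time=None, flags=tuple(sorted(flags)) or ("no-transit",))
    t = float(np.quantile(hits, quantile))
    return CrossingEstimate(time=track.dates[0] + pd.Timedelta(days=t),
                            flags=tuple(sorted(flags)))


def migration_duration(t30: pd.Timestamp, t70: pd.Timestamp) -> float:
    """Days from the 30% to the 70% crossing, floored at one day."""
    if t30 is None or t70 is None:
        raise ValueError("both crossing dates are required")
    gap = (pd.Timestamp(t70) - pd.Timestamp(t30)) / pd.Timedelta(days=1)
    if gap < 0:
        raise ValueError("t70 precedes t30")
    return max(1.0, float(gap))


def migration_speed(distance_km: float, duration_days: float) -> float:
    """Mean migration speed in km/day (duration already floored at 1)."""
    if duration_days < 1:
        raise ValueError("duration must be >= 1 day (apply the floor first)")
    return distance_km / duration_days


def _nearest_equinox(date: pd.Timestamp) -> pd.Timestamp:
    date = pd.Timestamp(date)
    candidates = [
        pd.Timestamp(year=y, month=m, day=d)
        for y in (date.year - 1, date.year, date.year + 1)
        for (m, d) in (SPRING_EQUINOX, AUTUMN_EQUINOX)
    ]
    return min(candidates, key=lambda c: abs(c - date))


def days_from_equinox(date: pd.Timestamp) -> float:
    """Absolute days between a date and the nearest equinox (Mar 20/Sep 22)."""
    date = pd.Timestamp(date)
    return abs((date - _nearest_equinox(date)) / pd.Timedelta(days=1))


def equinox_filter(movement_date: pd.Timestamp, route_bearing: float,
                   window_days: float = 7.0, ns_tolerance_deg: float = 15.0) -> bool:
    """True if a timing estimate should be kept, False if dropped.

    Latitude (hence north-south timing) is unreliable near the equinoxes,
    so movements within ``window_days`` of an equinox along a route within
    ``ns_tolerance_deg`` of due north or south are discarded.
    """
    near_equinox = days_from_equinox(movement_date) <= window_days
    dev_ns = min(abs((route_bearing % 360.0) - b) % 360.0 for b in (0.0, 180.0, 360.0))
    dev_ns = min(dev_ns, 360.0 - dev_ns)
    return not (near_equinox and dev_ns <= ns_tolerance_deg)


def truncate_late_winter(track: TrackSeries,
                         window_days: float = 21.0) -> tuple[TrackSeries, bool]:
    """Drop post-1-January fixes from tags that died near the spring equinox.

    If the last fix falls within ``window_days`` (either side) of the
    spring equinox of its year, samples after 1 January of that year are
    removed.  Returns the (possibly shortened) track and a truncation flag.
    Idempotent: a truncated track is unchanged by a second application.
    """
    last = track.last_fix_date
    equinox = pd.Timestamp(year=last.year, month=SPRING_EQUINOX[0], day=SPRING_EQUINOX[1])
    if abs((last - equinox) / pd.Timedelta(days=1)) > window_days:
        return track, False
    jan1 = pd.Timestamp(year=last.year, month=1, day=1)
    keep = track.dates <= jan1
    if keep.all():
        return track, False
    if keep.sum() < 2:
        raise ValueError("truncation would leave fewer than 2 samples")
    return TrackSeries(
        bird_id=track.bird_id, season=track.season,
        dates=track.dates[keep], lats=track.lats[keep], lons=track.lons[keep],
        spread_km=None if track.spread_km is None else track.spread_km[keep],
    ), True


def dedupe_repeat_tracks(table: pd.DataFrame, seed: int = 0,
                         id_col: str = "bird_id") -> pd.DataFrame:
    """Keep one uniformly chosen row per bird (reproducible given *seed*)."""
    rng = np.random.default_rng(seed)
    picks = []
    for _, idx in table.groupby(id_col, sort=True).indices.items():
        picks.append(idx[rng.integers(len(idx))])
    return table.iloc[sorted(picks)].reset_index(drop=True)


COMPARISON_GROUPS = {
    "SWvsSE": ("SW", "SE"),
    "SvsSWSE": ("S", "SW", "SE"),
    "NWvsSW": ("NW", "SW"),
}


@dataclass(frozen=True)
class TimingModelSpec:
    """One phenotype contrast plus its candidate nuisance covariates.

    ``comparison`` selects both the phenotype subset and the reported
    contrast: SW - SE, S - mean(SW, SE), or NW - SW (negative estimates
    mean the first-named group is earlier).  Sex enters only the NW-vs-SW
    comparison (divide birds are all male).  Covariates with p above
    ``drop_threshold`` are removed one at a time, largest p first; the
    phenotype factor is never dropped.  Responses named in
    ``log_responses`` (duration, speed) are log-transformed and their
    contrast reported also as a ratio.
    """

    comparison: str
    responses: tuple[str, ...] = ("arrival_doy",)
    covariates: tuple[str, ...] = ("breed_lat", "breed_lon", "year")
    log_responses: tuple[str, ...] = ()
    drop_threshold: float = 0.10

    def __post_init__(self) -> None:
        if self.comparison not in COMPARISON_GROUPS:
            raise ValueError(f"unknown comparison {self.comparison!r}")
        if "sex" in self.covariates and self.comparison != "NWvsSW":
            raise ValueError("sex enters only the NW-vs-SW comparison")


def _design(table: pd.DataFrame, covariates: Sequence[str],
            levels: Sequence[str]) -> pd.DataFrame:
    cols = {"Intercept": np.ones(len(table))}
    for lev in levels[1:]:
        cols[f"phen[{lev}]"] = (table["phenotype"] == lev).astype(float).to_numpy()
    for cov in covariates:
        if cov == "sex":
            cols["sex[M]"] = (table["sex"] == "M").astype(float).to_numpy()
        else:
            v = table[cov].astype(float).to_numpy()
            cols[cov] = v - v.mean()
    return pd.DataFrame(cols, index=table.index)


def _contrast_vector(names: Sequence[str], comparison: str,
                     levels: Sequence[str]) -> np.ndarray:
    vec = np.zeros(len(names))

    def coef(lev: str) -> np.ndarray:
        out = np.zeros(len(names))
        if lev != levels[0]:
            out[list(names).index(f"phen[{lev}]")] = 1.0
        return out

    if comparison == "SWvsSE":
        vec = coef("SW") - coef("SE")
    elif comparison == "NWvsSW":
        vec = coef("NW") - coef("SW")
    else:  # S minus the SW/SE mean
        vec = coef("S") - 0.5 * (coef("SW") + coef("SE"))
    return vec


def fit_timing_model(table: pd.DataFrame, spec: TimingModelSpec) -> pd.DataFrame:
    """Fit one OLS timing model per response and report the phenotype contrast.

    Returns a DataFrame with one row per response: estimate, SE, t, df
    (residual df of the final model), p, 95% CI, the retained covariates,
    and for log responses the back-transformed ratio.

    Raises
    ------
    ValueError
        If a compared phenotype group has fewer than 2 birds, or the
        design is rank deficient (collinear terms are named).
    """
    levels = COMPARISON_GROUPS[spec.comparison]
    sub = table[table["phenotype"].isin(levels)].copy()
    counts = sub["phenotype"].value_counts()
    for lev in levels:
        if counts.get(lev, 0) < 2:
            raise ValueError(f"phenotype group {lev!r} has fewer than 2 birds")
    rows = []
    for resp in spec.responses:
        y = sub[resp].astype(float).to_numpy()
        logged = resp in spec.log_responses
        if logged:
            if np.any(y <= 0):
                raise ValueError(f"response {resp!r} must be positive for a log transform")
            y = np.log(y)
        covs = list(spec.covariates)
        while True:
            X = _design(sub, covs, levels)
            rank = np.linalg.matrix_rank(X.to_numpy())
            if rank < X.shape[1]:
                raise ValueError(f"rank-deficient design; check terms {list(X.columns)}")
            fit = sm.OLS(y, X).fit()
            cov_p = {c: fit.pvalues[name]
                     for c in covs
                     for name in (("sex[M]" if c == "sex" else c),)}
            droppable = {c: p for c, p in cov_p.items() if p > spec.drop_threshold}
            if not droppable:
                break
            worst = max(droppable, key=droppable.get)
            logger.debug("dropping covariate %s (p=%.3f) from %s model",
                         worst, droppable[worst], resp)
            covs.remove(worst)
        vec = _contrast_vector(X.columns, spec.comparison, levels)
        tt = fit.t_test(vec)
        est = float(np.ravel(tt.effect)[0])
        ci = tt.conf_int(alpha=0.05)
        rows.append({
            "response": resp,
            "comparison": spec.comparison,
            "estimate": est,
            "se": float(np.ravel(tt.sd)[0]),
            "t": float(np.ravel(tt.tvalue)[0]),
            "df": float(fit.df_resid),
            "p": float(np.ravel(tt.pvalue)[0]),
            "ci_low": float(np.ravel(ci)[0]),
            "ci_high": float(np.ravel(ci)[1]),
            "ratio": float(np.exp(est)) if logged else np.nan,
            "retained_covariates": ",".join(covs),
        })
    return pd.DataFrame(rows)
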