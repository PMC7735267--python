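"""Spherical geodesy and circular statistics.

All positions are WGS84-style decimal degrees on a sphere of radius
6371.0088 km (the IUGG mean Earth radius); for geolocator-scale position
error the sphere/ellipsoid difference is irrelevant.  Bearings are degrees
clockwise from true north in [0, 360).

Two families of paths are used downstream:

* **rhumb lines** (loxodromes, constant compass bearing) summarise a bird's
  migration direction between its breeding and wintering sites;
* **great circles** (shortest paths) define the reference axis along which
  migration progress is measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0088
#: Length of one degree of arc on the sphere (2*pi*R/360).
KM_PER_DEG = 2.0 * math.pi * EARTH_RADIUS_KM / 360.0


def normalize_lon(lon: float) -> float:
    """Normalize a longitude to (-180, 180]."""
    lon = math.fmod(lon, 360.0)
    if lon <= -180.0:
        lon += 360.0
    elif lon > 180.0:
        lon -= 360.0
    return lon


def normalize_bearing(deg: float) -> float:
    """Normalize a bearing to [0, 360)."""
    out = deg % 360.0
    # a tiny negative input can round to exactly 360.0 after the modulo
    return 0.0 if out == 360.0 else out


@dataclass(frozen=True)
class GeoPoint:
    """A point on the sphere, decimal degrees, east/north positive."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not math.isfinite(self.lon):
            raise ValueError(f"longitude {self.lon} is not finite")
        object.__setattr__(self, "lon", normalize_lon(self.lon))


def _mercator_lat(phi_rad: float) -> float:
    """Mercator-projected (isometric) latitude."""
    return math.log(math.tan(math.pi / 4.0 + phi_rad / 2.0))


def rhumb_bearing(origin: GeoPoint, dest: GeoPoint) -> float:
    """Constant bearing of the rhumb line from *origin* to *dest*.

    The longitudinal difference is taken on the shorter arc, so routes
    never wrap the long way around the antimeridian.

    Raises
    ------
    ValueError
        If the two points coincide (the direction is undefined).
    """
    if origin.lat == dest.lat and origin.lon == dest.lon:
        raise ValueError("rhumb bearing undefined for identical points")
    phi1 = math.radians(origin.lat)
    phi2 = math.radians(dest.lat)
    dlon = math.radians(normalize_lon(dest.lon - origin.lon))
    dpsi = _mercator_lat(phi2) - _mercator_lat(phi1)
    theta = math.atan2(dlon, dpsi)
    return normalize_bearing(math.degrees(theta))


def rhumb_distance(origin: GeoPoint, dest: GeoPoint) -> float:
    """Length in km of the rhumb line from *origin* to *dest*."""
    phi1 = math.radians(origin.lat)
    phi2 = math.radians(dest.lat)
    dphi = phi2 - phi1
    dlon = abs(math.radians(normalize_lon(dest.lon - origin.lon)))
    dpsi = _mercator_lat(phi2) - _mercator_lat(phi1)
    if abs(dpsi) > 1e-12:
        q = dphi / dpsi
    else:
        q = math.cos(phi1)
    return EARTH_RADIUS_KM * math.hypot(dphi, q * dlon)


def rhumb_destination(origin: GeoPoint, bearing: float, distance_km: float) -> GeoPoint:
    """Point reached by following a constant *bearing* for *distance_km*.

    Inverse of :func:`rhumb_bearing`: the bearing from *origin* to the
    returned point equals *bearing* (round trip accurate to ~1e-6 degrees).

    Raises
    ------
    ValueError
        If *distance_km* is negative or the path would cross a pole.
    """
    if distance_km < 0:
        raise ValueError("distance must be >= 0")
    if distance_km == 0:
        return origin
    theta = math.radians(normalize_bearing(bearing))
    delta = distance_km / EARTH_RADIUS_KM
    phi1 = math.radians(origin.lat)
    dphi = delta * math.cos(theta)
    phi2 = phi1 + dphi
    if abs(phi2) > math.pi / 2.0 + 1e-12:
        raise ValueError("rhumb path crosses a pole; destination undefined")
    phi2 = max(-math.pi / 2.0, min(math.pi / 2.0, phi2))
    dpsi = _mercator_lat(phi2) - _mercator_lat(phi1)
    if abs(dpsi) > 1e-12:
        q = dphi / dpsi
    else:
        q = math.cos(phi1)
    dlon = delta * math.sin(theta) / q
    lon2 = normalize_lon(origin.lon + math.degrees(dlon))
    return GeoPoint(math.degrees(phi2), lon2)


def great_circle_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Haversine great-circle distance in km."""
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dphi = phi2 - phi1
    dlam = math.radians(normalize_lon(b.lon - a.lon))
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def gc_initial_bearing(a: GeoPoint, b: GeoPoint) -> float:
    """Initial (forward) azimuth of the great circle from *a* to *b*."""
    if a.lat == b.lat and a.lon == b.lon:
        raise ValueError("bearing undefined for identical points")
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dlam = math.radians(normalize_lon(b.lon - a.lon))
    y = math.sin(dlam) * math.cos(phi2)
    x = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlam)
    return normalize_bearing(math.degrees(math.atan2(y, x)))


def gc_interpolate(a: GeoPoint, b: GeoPoint, fraction: float) -> GeoPoint:
    """Point at *fraction* of the way along the great circle from *a* to *b*.

    Spherical linear interpolation; fraction 0 gives *a*, 1 gives *b*.
    """
    if a.lat == b.lat and a.lon == b.lon:
        return a
    delta = great_circle_distance(a, b) / EARTH_RADIUS_KM
    sd = math.sin(delta)
    wa = math.sin((1.0 - fraction) * delta) / sd
    wb = math.sin(fraction * delta) / sd
    phi1, lam1 = math.radians(a.lat), math.radians(a.lon)
    phi2, lam2 = math.radians(b.lat), math.radians(b.lon)
    x = wa * math.cos(phi1) * math.cos(lam1) + wb * math.cos(phi2) * math.cos(lam2)
    y = wa * math.cos(phi1) * math.sin(lam1) + wb * math.cos(phi2) * math.sin(lam2)
    z = wa * math.sin(phi1) + wb * math.sin(phi2)
    return GeoPoint(math.degrees(math.atan2(z, math.hypot(x, y))), math.degrees(math.atan2(y, x)))


def gc_along_track_fraction(start: GeoPoint, end: GeoPoint, p: GeoPoint) -> float:
    """Signed along-route progress of *p* projected onto the route start->end.

    Returns the along-track distance of the projection of *p* onto the
    great circle through *start* and *end*, as a fraction of the route
    length: 0 at the start, 1 at the end, negative behind the start,
    above 1 beyond the end.
    """
    route_len = great_circle_distance(start, end) / EARTH_RADIUS_KM
    if route_len == 0:
        raise ValueError("route endpoints coincide")
    if p.lat == start.lat and p.lon == start.lon:
        return 0.0
    d13 = great_circle_distance(start, p) / EARTH_RADIUS_KM
    t13 = math.radians(gc_initial_bearing(start, p))
    t12 = math.radians(gc_initial_bearing(start, end))
    dxt = math.asin(max(-1.0, min(1.0, math.sin(d13) * math.sin(t13 - t12))))
    cos_ratio = math.cos(d13) / math.cos(dxt)
    dat = math.acos(max(-1.0, min(1.0, cos_ratio)))
    sign = 1.0 if math.cos(t13 - t12) >= 0 else -1.0
    return sign * dat / route_len


def _to_radians(directions: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(directions) if not isinstance(directions, np.ndarray) else directions,
                     dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one direction")
    return np.radians(arr)


def circular_mean(directions: Sequence[float]) -> float:
    """Circular mean direction in degrees [0, 360)."""
    rad = _to_radians(directions)
    return normalize_bearing(math.degrees(math.atan2(np.sin(rad).mean(), np.cos(rad).mean())))


def mean_resultant_length(directions: Sequence[float]) -> float:
    rad = _to_radians(directions)
    return float(np.hypot(np.sin(rad).mean(), np.cos(rad).mean()))


def circular_variance(directions: Sequence[float]) -> float:
    """Circular variance 1 - Rbar, in [0, 1]."""
    return 1.0 - mean_resultant_length(directions)


def circular_correlation(a: Sequence[float], b: Sequence[float]) -> float:
    """Fisher-Lee circular correlation between two angular samples.

    ``sum_{i<j} sin(a_i - a_j) sin(b_i - b_j)`` normalised by the root
    product of the two marginal sums of squares; in [-1, 1].

    Raises
    ------
    ValueError
        On unequal lengths, fewer than 3 pairs, or an angularly constant
        sample (the coefficient is then undefined).
    """
    ar = _to_radians(a)
    br = _to_radians(b)
    if ar.size != br.size:
        raise ValueError("samples must have equal length")
    if ar.size < 3:
        raise ValueError("need at least 3 pairs")
    # sin(x_i - x_j) as outer-product matrices; only the i<j triangle matters
    # but the full antisymmetric matrices give the same sums halved.
    sa = np.sin(ar[:, None] - ar[None, :])
    sb = np.sin(br[:, None] - br[None, :])
    num = float((sa * sb).sum()) / 2.0
    da = float((sa ** 2).sum()) / 2.0
    db = float((sb ** 2).sum()) / 2.0
    if da <= 0 or db <= 0:
        raise ValueError("circular correlation undefined for a constant sample")
    return num / math.sqrt(da * db)


def angular_deviation(directions: Sequence[float], reference: float | None = None) -> np.ndarray:
    """Signed angular deviations (degrees in (-180, 180]) from a reference.

    Default reference is the sample's circular mean.
    """
    arr = np.asarray(directions, dtype=float)
    if reference is None:
        reference = circular_mean(arr)
    dev = (arr - reference + 180.0) % 360.0 - 180.0
    return dev
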