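"""Maximum-likelihood fitting of a sigmoid geographic cline.

The migratory divide is characterised by fitting a hyperbolic-tangent
cline to mean migration direction as a function of breeding longitude:

    mu(x) = mu_left + (mu_right - mu_left) * (1 + tanh(2 (x - c) / w)) / 2

with centre ``c`` (the inflection longitude) and width ``w`` (the inverse
of the maximum slope, i.e. the distance over which the tangent at the
centre spans the two asymptotes).  Group mean directions are modelled as
Normal(mu(x_i), sigma / sqrt(n_i)) with a single global trait SD sigma.
Direction is treated as a linear trait in degrees: the observed range
(roughly 130-290 degrees) stays far from the 0/360 wrap, so circular
likelihoods are unnecessary (documented limitation).

For fixed (c, w) the remaining parameters (mu_left, mu_right, sigma) have
a closed-form weighted-least-squares maximum, so the optimisation is a
cheap 2-D bounded search with multiple starts, and two-log-likelihood
support intervals come from explicit profile likelihoods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .geodesy import KM_PER_DEG

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupedTraitPoint:
    """Mean trait of one group of birds at one transect position."""

    position: float  # degrees longitude
    mean_trait: float  # degrees
    n: int
    sd_trait: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")


@dataclass(frozen=True)
class ClineParams:
    """Sigmoid cline parameters (degrees longitude / degrees of direction)."""

    center: float
    width: float
    mu_left: float
    mu_right: float
    sigma: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("cline width must be > 0")
        if self.sigma <= 0:
            raise ValueError("trait SD must be > 0")


@dataclass(frozen=True)
class SupportInterval:
    """Profile-likelihood support interval; open ends are flagged."""

    lower: float
    upper: float
    lower_open: bool = False
    upper_open: bool = False

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


@dataclass(frozen=True)
class ClineFit:
    params: ClineParams
    loglik: float
    support_center: SupportInterval | None = None
    support_width: SupportInterval | None = None
    width_identifiable: bool = True


def make_groups(positions: Sequence[float],
                traits: Sequence[float],
                zones: Sequence[str],
                min_size: int = 2,
                zone_order: Sequence[str] = ("west", "divide", "east")) -> list[GroupedTraitPoint]:
    """Partition individuals into contiguous longitude groups within zones.

    Within each zone, individuals sorted by longitude are split into
    ``floor(n / min_size)`` contiguous groups with sizes as equal as
    possible; when sizes differ, the larger groups sit at the eastern
    (right) end.  Grouping zones separately keeps densely sampled divide
    birds from being pooled with the sparse tails.  A zone with fewer than
    ``min_size`` individuals yields a single (undersized) group with a
    warning.

    Group position is the mean longitude, trait the mean direction, and
    sd the sample SD (0 for groups of identical values or n=1).
    """
    pos = np.asarray(positions, dtype=float)
    tr = np.asarray(traits, dtype=float)
    zn = np.asarray(zones)
    if not (pos.size == tr.size == zn.size):
        raise ValueError("positions, traits and zones must have equal length")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    groups: list[GroupedTraitPoint] = []
    for zone in zone_order:
        mask = zn == zone
        n = int(mask.sum())
        if n == 0:
            continue
        order = np.argsort(pos[mask], kind="stable")
        zp = pos[mask][order]
        zt = tr[mask][order]
        if n < min_size:
            logger.warning("zone %r has %d < %d individuals; single undersized group",
                           zone, n, min_size)
            n_groups = 1
        else:
            n_groups = n // min_size
        base, rem = divmod(n, n_groups)
        sizes = [base] * (n_groups - rem) + [base + 1] * rem
        start = 0
        for size in sizes:
            sl = slice(start, start + size)
            sd = float(np.std(zt[sl], ddof=1)) if size > 1 else 0.0
            groups.append(GroupedTraitPoint(
                position=float(zp[sl].mean()),
                mean_trait=float(zt[sl].mean()),
                n=size,
                sd_trait=sd,
            ))
            start += size
    return sorted(groups, key=lambda g: g.position)


def cline_mean(x, center: float, width: float, mu_left: float, mu_right: float):
    """Expected trait value at transect position(s) *x*."""
    x = np.asarray(x, dtype=float)
    s = 0.5 * (1.0 + np.tanh(2.0 * (x - center) / width))
    out = mu_left + (mu_right - mu_left) * s
    return float(out) if out.ndim == 0 else out


def cline_mean_params(x, p: ClineParams):
    return cline_mean(x, p.center, p.width, p.mu_left, p.mu_right)


def _profile_loglik(c: float, w: float, x: np.ndarray, y: np.ndarray,
                    n: np.ndarray) -> tuple[float, float, float, float]:
    """Max log-likelihood over (mu_left, mu_right, sigma) at fixed (c, w).

    mu(x) is linear in the asymptotes, so the weighted-LS solution is
    closed form; the ML sigma^2 follows from the weighted residuals.
    Returns (loglik, mu_left, mu_right, sigma).
    """
    s = 0.5 * (1.0 + np.tanh(2.0 * (x - c) / w))
    X = np.column_stack([1.0 - s, s])
    wts = n.astype(float)
    xtwx = X.T @ (X * wts[:, None])
    xtwy = X.T @ (wts * y)
    try:
        beta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(X * np.sqrt(wts)[:, None],
                                   y * np.sqrt(wts), rcond=None)
    resid = y - X @ beta
    g = x.size
    sigma2 = float((wts * resid ** 2).sum()) / g
    sigma2 = max(sigma2, 1e-12)
    ll = -0.5 * (g * math.log(2.0 * math.pi * sigma2) - float(np.log(wts).sum()) + g)
    return ll, float(beta[0]), float(beta[1]), math.sqrt(sigma2)


def _default_bounds(x: np.ndarray) -> tuple[tuple[float, float], tuple[float, float]]:
    lo, hi = float(x.min()), float(x.max())
    span = max(hi - lo, 1e-6)
    return (lo, hi), (0.005 * span, 3.0 * span)


def fit_cline(groups: Sequence[GroupedTraitPoint],
              center_bounds: tuple[float, float] | None = None,
              width_bounds: tuple[float, float] | None = None,
              n_starts: int = 5,
              seed: int = 0,
              support: bool = True,
              drop: float = 2.0,
              profile_points: int = 101) -> ClineFit:
    """Fit the sigmoid cline to grouped trait data by maximum likelihood.

    A 2-D bounded quasi-Newton search over (centre, width) with
    ``n_starts`` seeded starting points; the asymptotes and trait SD are
    profiled out in closed form at every evaluation.  When ``support`` is
    true, two-log-likelihood support intervals for centre and width are
    computed from explicit profile likelihoods.

    Raises
    ------
    ValueError
        With fewer than 4 groups or all groups at one position.
    """
    if len(groups) < 4:
        raise ValueError("cline fitting needs at least 4 groups")
    x = np.array([g.position for g in groups], dtype=float)
    y = np.array([g.mean_trait for g in groups], dtype=float)
    n = np.array([g.n for g in groups], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all groups at one position; cline not identifiable")
    cb, wb = _default_bounds(x)
    if center_bounds is not None:
        cb = center_bounds
    if width_bounds is not None:
        wb = width_bounds

    def neg_ll(theta):
        return -_profile_loglik(theta[0], theta[1], x, y, n)[0]

    rng = np.random.default_rng(seed)
    starts = [np.array([0.5 * (cb[0] + cb[1]),
                        math.sqrt(wb[0] * wb[1])])]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.array([rng.uniform(*cb),
                                math.exp(rng.uniform(math.log(wb[0]), math.log(wb[1])))]))
    best = None
    for s0 in starts:
        res = minimize(neg_ll, s0, method="L-BFGS-B", bounds=[cb, wb])
        if best is None or res.fun < best.fun:
            best = res
    c_hat, w_hat = float(best.x[0]), float(best.x[1])
    ll, mu_l, mu_r, sigma = _profile_loglik(c_hat, w_hat, x, y, n)
    params = ClineParams(center=c_hat, width=max(w_hat, 1e-12),
                         mu_left=mu_l, mu_right=mu_r, sigma=max(sigma, 1e-9))
    width_ok = abs(mu_r - mu_l) > 2.0 * sigma / math.sqrt(float(n.mean()))
    if not width_ok:
        logger.warning("asymptotes nearly equal (|%.2f - %.2f| vs sigma %.2f); "
                       "width not identifiable", mu_l, mu_r, sigma)

    sc = sw = None
    if support:
        c_grid = np.linspace(cb[0], cb[1], profile_points)
        c_prof = np.array([
            -minimize_scalar(lambda w, cc=cc: -_profile_loglik(cc, w, x, y, n)[0],
                             bounds=wb, method="bounded").fun
            for cc in c_grid])
        sc = support_interval(c_grid, c_prof, drop=drop)
        w_grid = np.exp(np.linspace(math.log(wb[0]), math.log(wb[1]), profile_points))
        w_prof = np.array([
            -minimize_scalar(lambda c, ww=ww: -_profile_loglik(c, ww, x, y, n)[0],
                             bounds=cb, method="bounded").fun
            for ww in w_grid])
        sw = support_interval(w_grid, w_prof, drop=drop)
    return ClineFit(params=params, loglik=ll, support_center=sc,
                    support_width=sw, width_identifiable=width_ok)


def support_interval(positions: Sequence[float], loglik: Sequence[float],
                     drop: float = 2.0) -> SupportInterval:
    """Smallest interval holding every parameter value within *drop* of the max.

    Endpoints between grid points are found by linear interpolation of the
    profile.  A profile maximised at a boundary yields an open-ended
    interval on that side (flagged).
    """
    pos = np.asarray(positions, dtype=float)
    ll = np.asarray(loglik, dtype=float)
    if pos.size != ll.size or pos.size < 2:
        raise ValueError("profile needs >= 2 (position, loglik) pairs")
    order = np.argsort(pos)
    pos, ll = pos[order], ll[order]
    threshold = ll.max() - drop
    above = ll >= threshold
    idx = np.flatnonzero(above)
    first, last = idx[0], idx[-1]

    if first == 0:
        lower, lower_open = float(pos[0]), True
    else:
        f = (threshold - ll[first - 1]) / (ll[first] - ll[first - 1])
        lower, lower_open = float(pos[first - 1] + f * (pos[first] - pos[first - 1])), False
    if last == pos.size - 1:
        upper, upper_open = float(pos[-1]), True
    else:
        f = (threshold - ll[last + 1]) / (ll[last] - ll[last + 1])
        upper, upper_open = float(pos[last + 1] - f * (pos[last + 1] - pos[last])), False
    return SupportInterval(lower=lower, upper=upper,
                           lower_open=lower_open, upper_open=upper_open)


def lon_width_to_km(width_deg: float, transect_lat: float) -> float:
    """Convert a longitudinal width in degrees to km at a transect latitude."""
    if not -90.0 < transect_lat < 90.0:
        raise ValueError("transect latitude must be strictly between the poles")
    return width_deg * KM_PER_DEG * math.cos(math.radians(transect_lat))
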