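"""Migratory phenotype classification and per-bird summaries.

Tracked birds are assigned one of four migratory phenotypes from their
wintering location: southwest (SW), intermediate south (S), southeast (SE),
or northwest (NW, the novel British-wintering strategy).  The module also
provides the variance comparisons (Brown-Forsythe Levene tests with
Benjamini-Hochberg correction) and the repeatability (intraclass
correlation) of per-bird traits across repeated tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geodesy import GeoPoint, angular_deviation, great_circle_distance, rhumb_bearing

logger = logging.getLogger(__name__)

PHENOTYPES = ("SW", "S", "SE", "NW")


@dataclass(frozen=True)
class ClassificationRule:
    """Longitude/latitude cut-offs mapping a wintering site to a phenotype.

    Birds wintering north of ``lat_split`` are called SW west of
    ``west_cut_north`` (5 degrees E); for the longer routes south of the
    split the westerly cut drops to ``west_cut_south`` (0 degrees).  East of
    ``east_cut`` is SE, in between is S.  Wintering at or north of
    ``nw_lat_min`` marks the NW (British-wintering) phenotype.
    """

    lat_split: float = 37.5
    west_cut_north: float = 5.0
    west_cut_south: float = 0.0
    east_cut: float = 20.0
    nw_lat_min: float = 45.0

    def __post_init__(self) -> None:
        if self.west_cut_north >= self.east_cut or self.west_cut_south >= self.east_cut:
            raise ValueError("west cuts must lie west of the east cut")


@dataclass(frozen=True)
class BirdSummary:
    """One tracked bird-year: breeding/wintering endpoints plus metadata."""

    bird_id: str
    year: int
    sex: str  # "M", "F" or "unknown"
    breeding: GeoPoint
    wintering: GeoPoint
    region: str = ""


def classify_winter(w: GeoPoint, rule: ClassificationRule | None = None) -> str:
    """Phenotype label for a wintering location.

    Boundary longitudes (exactly on a cut) are assigned to S: the
    intermediate interval is treated as closed.
    """
    rule = rule or ClassificationRule()
    if w.lat >= rule.nw_lat_min:
        return "NW"
    west_cut = rule.west_cut_north if w.lat >= rule.lat_split else rule.west_cut_south
    if w.lon < west_cut:
        return "SW"
    if w.lon > rule.east_cut:
        return "SE"
    return "S"


def autumn_direction(b: BirdSummary) -> float:
    """Autumn migration direction: rhumb bearing breeding -> wintering."""
    return rhumb_bearing(b.breeding, b.wintering)


def migration_distance(b: BirdSummary) -> float:
    """Great-circle distance breeding -> wintering in km."""
    return great_circle_distance(b.breeding, b.wintering)


def summarize_birds(birds: Sequence[BirdSummary],
                    rule: ClassificationRule | None = None) -> pd.DataFrame:
    """Per-bird-year summary table: endpoints, phenotype, direction, distance."""
    rows = []
    for b in birds:
        rows.append({
            "bird_id": b.bird_id,
            "year": b.year,
            "sex": b.sex,
            "region": b.region,
            "breed_lat": b.breeding.lat,
            "breed_lon": b.breeding.lon,
            "winter_lat": b.wintering.lat,
            "winter_lon": b.wintering.lon,
            "phenotype": classify_winter(b.wintering, rule),
            "direction_deg": autumn_direction(b),
            "distance_km": migration_distance(b),
        })
    return pd.DataFrame(rows)


def levene_by_site(directions_by_site: Mapping[str, Sequence[float]],
                   min_n: int = 5,
                   pairs: Sequence[tuple[str, str]] | None = None,
                   use_angular_deviation: bool = True) -> pd.DataFrame:
    """Pairwise Brown-Forsythe tests of equal direction spread among sites.

    Each site's directions are reduced to signed angular deviations from
    the site's circular mean (set ``use_angular_deviation=False`` to test
    raw degrees), then compared with Levene's test centred on the median
    (the Brown-Forsythe variant).  P-values are Benjamini-Hochberg adjusted
    across all comparisons.  Sites with fewer than ``min_n`` birds are
    excluded with a log notice.

    Returns a DataFrame with columns site_a, site_b, F, df1, df2, p, p_adj.
    """
    usable: dict[str, np.ndarray] = {}
    for site, vals in directions_by_site.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < min_n:
            logger.info("site %s excluded from Levene tests (n=%d < %d)",
                        site, arr.size, min_n)
            continue
        usable[site] = arr
    if pairs is None:
        pairs = list(combinations(sorted(usable), 2))
    rows = []
    for a, b in pairs:
        if a not in usable or b not in usable:
            continue
        xa, xb = usable[a], usable[b]
        if use_angular_deviation:
            xa = angular_deviation(xa)
            xb = angular_deviation(xb)
        f, p = stats.levene(xa, xb, center="median")
        rows.append({"site_a": a, "site_b": b, "F": float(f),
                     "df1": 1, "df2": xa.size + xb.size - 2, "p": float(p)})
    out = pd.DataFrame(rows, columns=["site_a", "site_b", "F", "df1", "df2", "p"])
    if len(out):
        out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


def _anova_components(groups: Sequence[np.ndarray]) -> tuple[float, float, float]:
    """One-way ANOVA variance components (sigma2_id, sigma2_res, grand mean)."""
    k = len(groups)
    ns = np.array([g.size for g in groups], dtype=float)
    n_total = ns.sum()
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, groups)))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ms_between = ss_between / (k - 1)
    df_within = n_total - k
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    # weighted group size for unbalanced designs
    n0 = (n_total - (ns ** 2).sum() / n_total) / (k - 1)
    sigma2_id = max(0.0, (ms_between - ms_within) / n0)
    return sigma2_id, ms_within, float(grand)


def repeatability(values_by_bird: Mapping[str, Sequence[float]],
                  n_boot: int = 1000,
                  seed: int = 0,
                  ci_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """ANOVA-based repeatability R with a parametric-bootstrap CI.

    R is the intraclass correlation sigma2_id / (sigma2_id + sigma2_res)
    from one-way ANOVA variance components, with a negative between-bird
    component truncated at zero.  The CI is the percentile interval of R
    over ``n_boot`` parametric resamples from the fitted components.

    Raises
    ------
    ValueError
        With fewer than two birds, or no bird measured more than once.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_bird.values()]
    if len(groups) < 2:
        raise ValueError("repeatability needs at least two birds")
    if all(g.size < 2 for g in groups):
        raise ValueError("repeatability undefined without repeated measures")
    sigma2_id, sigma2_res, grand = _anova_components(groups)
    denom = sigma2_id + sigma2_res
    r = sigma2_id / denom if denom > 0 else 0.0

    rng = np.random.default_rng(seed)
    ns = [g.size for g in groups]
    boots = np.empty(n_boot)
    for i in range(n_boot):
        sim = [rng.normal(grand + rng.normal(0.0, np.sqrt(sigma2_id)),
                          np.sqrt(sigma2_res), size=n) for n in ns]
        s_id, s_res, _ = _anova_components(sim)
        d = s_id + s_res
        boots[i] = s_id / d if d > 0 else 0.0
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(r), (float(lo), float(hi))
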