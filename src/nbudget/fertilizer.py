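"""Allocation of synthetic N fertilizer between cropland and grassland.

Total fertilizer consumption is a country-level statistic; how much of it
reaches cropland versus permanent grassland must be inferred from sparse
survey data.  The central quantity is the rate ratio R_PG/R_C (average
application rate on permanent grassland over that on cropland).  Given the
ratio and the land areas, the share applied to cropland is

    share_C = Q_C / (Q_C + Q_PG) = (1 + (R_PG/R_C) * A_PG/A_C)^-1,

independent of total consumption.  When surveys only distinguish total
grassland (PG+TG) from non-grass cropland (C-TG), the ratio is recovered
assuming the temporary-grassland rate is k times the permanent-grassland
rate; as a last resort a single category rate is combined with total
consumption.  Ratio point estimates are gap-filled by linear interpolation
and constant extrapolation, and consumption is then allocated so that
Q_C + Q_PG equals total consumption bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import PanelSeries, quantity_gg

log = logging.getLogger(__name__)

LAND_CATEGORIES = (
    "C",
    "PG",
    "TG",
    "C-TG",
    "PG+TG",
    "PGf",
    "TGf",
    "PGf+TGf",
    "total",
)

#: Relative tolerance of the Q = R*A consistency screen.
QRA_TOL = 0.005


@dataclass
class FertObservation:
    """One survey record: rate R (kg N/ha/yr), quantity Q (Gg N/yr), area A
    (kha) for a land category; any subset of R, Q, A may be present."""

    country: str
    year: int
    land_category: str
    R: float | None = None
    Q: float | None = None
    A: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.land_category not in LAND_CATEGORIES:
            raise ValueError(f"unknown land category {self.land_category!r}")

    def consistent(self, tol: float = QRA_TOL) -> bool:
        """When R, Q, A are all present, check Q = R*A within ``tol``."""
        if self.R is None or self.Q is None or self.A is None:
            return True
        implied = quantity_gg(self.R, self.A)
        if self.Q == 0.0:
            return implied == 0.0
        return abs(self.Q - implied) / abs(self.Q) <= tol


def area_weighted_rate(crop_rates: Sequence[tuple[float, float]]) -> float:
    """Area-weighted average rate from (R, A) pairs: sum(R*A)/sum(A)."""
    if not crop_rates:
        raise ValueError("area_weighted_rate: empty list")
    if any(a <= 0 for _, a in crop_rates):
        raise ValueError("area_weighted_rate: nonpositive area")
    num = sum(r * a for r, a in crop_rates)
    den = sum(a for _, a in crop_rates)
    return num / den


def renormalize_fertilized(r_f: float, a_f: float, a_total: float) -> float:
    """Average rate on the whole category from a fertilized-subset rate:
    R = R_f * A_f / A_total (conserves the applied quantity)."""
    if a_total <= 0:
        raise ValueError("renormalize_fertilized: nonpositive total area")
    if a_f > a_total:
        raise ValueError(
            f"fertilized area {a_f} exceeds category area {a_total}"
        )
    return r_f * a_f / a_total


def share_to_cropland(rate_ratio: float, a_pg: float, a_c: float) -> float:
    """Share of synthetic N applied to cropland from the rate ratio."""
    if a_c <= 0:
        raise ValueError("share_to_cropland: cropland area must be positive")
    if rate_ratio < 0:
        raise ValueError("share_to_cropland: negative rate ratio")
    return 1.0 / (1.0 + rate_ratio * a_pg / a_c)


def rate_ratio_from_total_grass(
    r_pg_plus_tg: float,
    r_c_minus_tg: float,
    a_pg: float,
    a_tg: float,
    a_c: float,
    a_c_minus_tg: float,
    a_pg_plus_tg: float,
    k: float = 1.0,
) -> float:
    """R_PG/R_C from total-grassland and non-grass-cropland rates.

    Assumes R_TG = k * R_PG.  With m = A_PG+TG / (A_PG + k*A_TG):

        R_PG/R_C = ( R_C-TG/(m*R_PG+TG) * A_C-TG/A_C + k*A_TG/A_C )^-1
    """
    if k <= 0:
        raise ValueError("k must be positive")
    denom_m = a_pg + k * a_tg
    if denom_m <= 0 or a_c <= 0 or r_pg_plus_tg <= 0:
        raise ValueError("rate_ratio_from_total_grass: zero denominator")
    m = a_pg_plus_tg / denom_m
    inv = (r_c_minus_tg / (m * r_pg_plus_tg)) * (a_c_minus_tg / a_c) + k * a_tg / a_c
    if inv <= 0:
        raise ValueError("rate_ratio_from_total_grass: nonpositive denominator")
    return 1.0 / inv


def rate_ratio_last_resort(
    r_x: float, a_x: float, a_tot: float, q_tot: float
) -> float:
    """R_x / R_complement from one category rate and total consumption:

        R_x/R_~x = R_x * (A_tot - A_x) / (Q_tot - R_x * A_x)

    with quantities in Gg N/yr, areas kha, rates kg N/ha/yr.
    """
    if a_tot <= a_x:
        raise ValueError("rate_ratio_last_resort: A_tot must exceed A_x")
    q_x = quantity_gg(r_x, a_x)
    denom = q_tot - q_x
    if denom <= 0:
        raise ValueError(
            "rate_ratio_last_resort: implied complement quantity nonpositive"
        )
    if r_x == 0.0:
        return 0.0
    # both numerator and denominator converted to rate on the complement area
    r_complement = denom * 1000.0 / (a_tot - a_x)
    return r_x / r_complement


@dataclass
class RateRatioSeries:
    """Gap-filled R_PG/R_C series with per-year provenance."""

    country: str
    values: pd.Series
    provenance: pd.Series  # eq2-direct | eq5 | eq6 | interpolated | extrapolated
    k: float = 1.0

    def __post_init__(self) -> None:
        neg = self.values.dropna() < 0
        if neg.any():
            raise ValueError("rate ratio series contains negative values")


def build_rate_ratio_series(
    points: Sequence[tuple[int, float]] | Sequence[tuple[int, float, str]],
    years: Iterable[int],
    country: str = "",
    k: float = 1.0,
) -> RateRatioSeries:
    """Interpolate/extrapolate rate-ratio point estimates over the grid.

    Multiple estimates in one year are averaged first.  Interior gaps are
    filled linearly, edges constantly; provenance records how each year's
    value arose.
    """
    idx = pd.Index(sorted(int(y) for y in years), name="year")
    if not points:
        raise ValueError("build_rate_ratio_series: empty point list")
    by_year: dict[int, list[float]] = {}
    prov_in: dict[int, str] = {}
    for p in points:
        year, ratio = int(p[0]), float(p[1])
        tag = p[2] if len(p) > 2 else "eq2-direct"
        if ratio < 0:
            raise ValueError(f"negative rate ratio {ratio} in {year}")
        by_year.setdefault(year, []).append(ratio)
        prov_in[year] = tag
    vals = pd.Series(np.nan, index=idx)
    prov = pd.Series("", index=idx, dtype=object)
    for year, estimates in by_year.items():
        if year in idx:
            vals.loc[year] = sum(estimates) / len(estimates)
            prov.loc[year] = prov_in[year]
    observed = vals.notna()
    filled = vals.interpolate(method="index", limit_area="inside")
    interior = filled.notna() & ~observed
    filled = filled.ffill().bfill()
    edges = filled.notna() & ~observed & ~interior
    prov[interior] = "interpolated"
    prov[edges] = "extrapolated"
    return RateRatioSeries(country, filled, prov, k=k)


def zero_pg_series(years: Iterable[int], country: str = "") -> RateRatioSeries:
    """Rate-ratio series for countries with no fertilization of permanent
    grassland: identically zero, share_C = 1."""
    idx = pd.Index(sorted(int(y) for y in years), name="year")
    return RateRatioSeries(
        country,
        pd.Series(0.0, index=idx),
        pd.Series("zero-PG", index=idx, dtype=object),
    )


def allocate_quantities(q_tot: float, share_c: float) -> tuple[float, float]:
    """Split total consumption: Q_C = share*Q_tot, Q_PG the exact remainder."""
    if not (0.0 <= share_c <= 1.0):
        raise ValueError(f"share {share_c} outside [0, 1]")
    q_c = share_c * q_tot
    return q_c, q_tot - q_c


def screen_observations(
    observations: Iterable[FertObservation], tol: float = QRA_TOL
) -> tuple[list[FertObservation], list[FertObservation]]:
    """Partition observations into (kept, excluded) by the Q = R*A screen;
    exclusions are logged with the offending record."""
    kept, excluded = [], []
    for obs in observations:
        if obs.consistent(tol):
            kept.append(obs)
        else:
            excluded.append(obs)
            log.warning(
                "excluded inconsistent fertilizer observation %s/%s %s "
                "(Q=%s, R*A/1000=%s)",
                obs.country,
                obs.year,
                obs.land_category,
                obs.Q,
                quantity_gg(obs.R, obs.A),
            )
    return kept, excluded


def estimate_rate_ratio(
    observations: Sequence[FertObservation],
    *,
    a_pg: float,
    a_tg: float,
    a_c: float,
    q_tot: float | None = None,
    k: float = 1.0,
) -> tuple[float, str] | None:
    """Best rate-ratio estimate for one country-year from its observations.

    Preference order: direct R_PG/R_C (Eq. of the share); total-grass vs
    non-grass rates with the k assumption; a single category rate with
    total consumption as last resort.  Fertilized-subset records (PGf) are
    first renormalized to the full category.  Returns (ratio, provenance)
    or None when no estimate is possible.
    """
    rates: dict[str, float] = {}
    for obs in observations:
        cat = obs.land_category
        if cat == "PGf" and obs.R is not None and obs.A is not None and a_pg > 0:
            rates.setdefault("PG", renormalize_fertilized(obs.R, obs.A, a_pg))
        elif cat == "PGf+TGf" and obs.R is not None and obs.A is not None:
            total = a_pg + a_tg
            if total > 0:
                rates.setdefault("PG+TG", renormalize_fertilized(obs.R, obs.A, total))
        elif obs.R is not None:
            rates.setdefault(cat, obs.R)
        elif obs.Q is not None and obs.A is not None and obs.A > 0:
            rates.setdefault(cat, obs.Q * 1000.0 / obs.A)
    if "PG" in rates and "C" in rates and rates["C"] > 0:
        return rates["PG"] / rates["C"], "eq2-direct"
    if "PG+TG" in rates and "C-TG" in rates:
        ratio = rate_ratio_from_total_grass(
            rates["PG+TG"],
            rates["C-TG"],
            a_pg=a_pg,
            a_tg=a_tg,
            a_c=a_c,
            a_c_minus_tg=a_c - a_tg,
            a_pg_plus_tg=a_pg + a_tg,
            k=k,
        )
        return ratio, "eq5"
    if q_tot is not None and "PG" in rates:
        a_tot = a_c + a_pg
        ratio = rate_ratio_last_resort(rates["PG"], a_pg, a_tot, q_tot)
        return ratio, "eq6"
    return None
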