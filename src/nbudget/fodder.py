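"""Fodder-crop harvests: humidity harmonization, reference yields, trend.

Fodder harvests are reported on mixed humidity bases: national humidity
(0-88% water), the EU standard for plants harvested green (65% water), hay
basis (85% dry matter), or dry matter itself.  Fodder roots lack humidity
values entirely and are assumed 16% dry matter.  All yields are first
harmonized to dry matter, then a per-country-and-crop reference yield is
estimated for 2010 as the mean of a selected set of observations, and a
linear trend anchors the 1961 yield at 75% of the 2010 value, continuing
with the same slope to 2019.  Temporary grassland (G1000) statistics count
only the mechanical harvest, so its yields are inflated by 20% to account
for grazing.  N harvest is then area x DM yield x N content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Default dry-matter fractions per basis.
EU_STANDARD_WATER = 0.65  # plants harvested green, EU standard humidity
HAY_DM = 0.85
FODDER_ROOT_DM = 0.16

TREND_BASE_YEAR = 1961
TREND_REF_YEAR = 2010
TREND_ANCHOR = 0.75  # 1961 yields are 75% of the 2010 yields
GRAZING_INFLATION = 1.20  # G1000 mechanical-harvest yields inflated by 20%


@dataclass(frozen=True)
class HumidityBasis:
    """Humidity basis of a reported yield or production value."""

    kind: str  # national_percent | eu_standard | dry_matter | hay | fodder_root_default
    water_fraction: float | None = None  # only for national_percent

    def dm_fraction(self) -> float:
        if self.kind == "dry_matter":
            return 1.0
        if self.kind == "eu_standard":
            return 1.0 - EU_STANDARD_WATER
        if self.kind == "hay":
            return HAY_DM
        if self.kind == "fodder_root_default":
            return FODDER_ROOT_DM
        if self.kind == "national_percent":
            if self.water_fraction is None:
                raise ValueError("national_percent basis requires water_fraction")
            if not (0.0 <= self.water_fraction < 1.0):
                raise ValueError(
                    f"water fraction {self.water_fraction} outside [0, 1)"
                )
            return 1.0 - self.water_fraction
        raise ValueError(f"unknown humidity basis {self.kind!r}")

    @classmethod
    def parse(cls, spec: str) -> "HumidityBasis":
        """Parse 'dry_matter', 'eu_standard', 'hay', 'fodder_root_default',
        or 'national:<water %>' (e.g. 'national:80')."""
        if spec.startswith("national:"):
            return cls("national_percent", float(spec.split(":", 1)[1]) / 100.0)
        return cls(spec)


def to_dry_matter(value: float, basis: HumidityBasis) -> float:
    """Convert a yield or production value to dry-matter basis."""
    return value * basis.dm_fraction()


@dataclass
class YieldModel:
    """Linear dry-matter yield trend anchored at a 2010 reference yield.

    ``y2010`` is in t DM/ha (numerically equal to Gg DM/kha).  The grazing
    inflation applies only to temporary grassland (G1000).
    """

    crop: str
    country: str
    y2010: float
    anchor: float = TREND_ANCHOR
    inflation: float = GRAZING_INFLATION
    base_year: int = TREND_BASE_YEAR
    ref_year: int = TREND_REF_YEAR
    inflate: bool | None = None  # default: crop == "G1000"

    def __post_init__(self) -> None:
        if self.y2010 <= 0:
            raise ValueError(f"y2010 must be positive, got {self.y2010}")
        if not (0.0 < self.anchor <= 1.0):
            raise ValueError(f"anchor {self.anchor} outside (0, 1]")
        if self.inflation < 1.0:
            raise ValueError(f"inflation {self.inflation} below 1")
        if self.inflate is None:
            self.inflate = self.crop == "G1000"


def yield_at(model: YieldModel, year: int) -> float:
    """Evaluate the yield trend in a year (affine in year; exactly
    interpolates (base_year, anchor*y2010) and (ref_year, y2010))."""
    span = model.ref_year - model.base_year
    frac = model.anchor + (1.0 - model.anchor) * (year - model.base_year) / span
    y = model.y2010 * frac
    if model.inflate:
        y = y * model.inflation
    return y


def fodder_n_harvest(area_kha: float, dm_yield: float, n_content: float) -> float:
    """N harvest in Gg N from area (kha), DM yield (Gg DM/kha), N content (%)."""
    return area_kha * dm_yield * n_content / 100.0


@dataclass
class YieldObservation:
    """One reported fodder yield with its declared humidity basis."""

    country: str
    crop: str
    year: int
    value: float
    basis: HumidityBasis


def reference_yield(
    observations: Sequence[YieldObservation],
    picks: Sequence[tuple[int, str]] | None = None,
) -> float:
    """Unweighted mean of the selected DM-converted yield observations.

    ``picks`` optionally restricts the selection to (year, basis kind)
    pairs; by default all observations are used.
    """
    selected = list(observations)
    if picks is not None:
        pickset = {(int(y), b) for y, b in picks}
        selected = [o for o in selected if (o.year, o.basis.kind) in pickset]
    if not selected:
        raise ValueError("reference_yield: no observations selected")
    dm = [to_dry_matter(o.value, o.basis) for o in selected]
    return sum(dm) / len(dm)


def production_weighted_yield(
    yields: Mapping[str, float], productions: Mapping[str, float]
) -> float:
    """Production-weighted average yield (e.g. G9000 from G9100/G9900)."""
    total = sum(productions.values())
    if total <= 0:
        raise ValueError("production weights sum to zero")
    return sum(yields[k] * productions[k] for k in yields) / total


def donor_yield(
    donors: Sequence[YieldModel],
    target_country: str,
    crop: str,
    kind: str = "average",
) -> YieldModel:
    """Fill a missing reference yield from neighboring-country models.

    ``kind`` 'single' copies the lone donor; 'average' takes the unweighted
    mean of donor 2010 reference yields.
    """
    if not donors:
        raise ValueError("donor_yield: empty donor list")
    if kind == "single":
        if len(donors) != 1:
            raise ValueError("donor_yield kind 'single' requires exactly one donor")
        y = donors[0].y2010
    elif kind == "average":
        y = sum(d.y2010 for d in donors) / len(donors)
    else:
        raise ValueError(f"unknown donor kind {kind!r}")
    d0 = donors[0]
    return YieldModel(
        crop=crop,
        country=target_country,
        y2010=y,
        anchor=d0.anchor,
        inflation=d0.inflation,
        base_year=d0.base_year,
        ref_year=d0.ref_year,
    )


@dataclass
class YieldFlag:
    kind: str  # equal_across_bases | basis_jump | implausible
    crop: str
    country: str
    year: int
    detail: str = ""


def flag_yield_anomalies(
    national: pd.Series | None,
    eu_standard: pd.Series | None,
    national_water: pd.Series | None = None,
    *,
    country: str = "",
    crop: str = "",
    ratio_tol: float = 0.05,
    dm_bounds: tuple[float, float] = (1.0, 25.0),
) -> list[YieldFlag]:
    """Advisory screening of candidate yield series for reporting errors.

    Flags raised (never acted on automatically):

    * ``equal_across_bases`` - national and EU-standard yields equal while
      the implied humidity differs (a conversion was likely skipped);
    * ``basis_jump`` - a year-to-year step whose ratio matches the implied
      DM factor, i.e. the series switched basis between years;
    * ``implausible`` - DM yields outside configurable bounds (t DM/ha).
    """
    flags: list[YieldFlag] = []
    if national is not None and eu_standard is not None:
        common = national.dropna().index.intersection(eu_standard.dropna().index)
        for year in common:
            nat, eu = national.loc[year], eu_standard.loc[year]
            water = (
                national_water.loc[year]
                if national_water is not None and year in national_water.index
                else np.nan
            )
            if (
                np.isfinite(water)
                and abs(water - EU_STANDARD_WATER) > 1e-9
                and np.isclose(nat, eu, rtol=1e-9)
            ):
                flags.append(
                    YieldFlag(
                        "equal_across_bases",
                        crop,
                        country,
                        int(year),
                        f"national water {water:.2f} != EU {EU_STANDARD_WATER}",
                    )
                )
    for name, series, dm_factor in (
        ("national", national, None),
        ("eu_standard", eu_standard, 1.0 - EU_STANDARD_WATER),
    ):
        if series is None:
            continue
        vals = series.dropna()
        for prev, cur in zip(vals.index[:-1], vals.index[1:]):
            if cur - prev != 1:
                continue
            a, b = vals.loc[prev], vals.loc[cur]
            if a <= 0 or b <= 0:
                continue
            factor = dm_factor
            if factor is None and national_water is not None and prev in national_water.index:
                w = national_water.loc[prev]
                factor = 1.0 - w if np.isfinite(w) else None
            if factor is None:
                continue
            if abs(b / a - factor) <= ratio_tol * factor or abs(
                a / b - factor
            ) <= ratio_tol * factor:
                flags.append(
                    YieldFlag(
                        "basis_jump",
                        crop,
                        country,
                        int(cur),
                        f"{name} step ratio matches DM factor {factor:.2f}",
                    )
                )
    if eu_standard is not None:
        dm = eu_standard.dropna() * (1.0 - EU_STANDARD_WATER)
        lo, hi = dm_bounds
        for year, v in dm.items():
            if v < lo or v > hi:
                flags.append(
                    YieldFlag(
                        "implausible", crop, country, int(year), f"{v:.2f} t DM/ha"
                    )
                )
    return flags
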