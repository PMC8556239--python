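"""Aggregation of arable and permanent crops into output categories.

Statistical crop panels often report harvests without the matching areas
(especially before the mid-1980s for permanent crops).  Summing available
areas and harvests separately would give incompatible category totals, so
category areas are estimated with a consistent set of estimators:

* ``A_sum`` - sum of available crop areas,
* ``H_sum`` - sum of available crop N harvests,
* ``Y_est`` - weighted average N yield over crops with BOTH area and
  harvest, computed as ratio of sums (sum H / sum A), which equals the
  area-weighted mean of crop yields,
* ``A_est = H_sum / Y_est`` - category area assuming crops with missing
  areas yield like the rest of the category.

When every crop in a category has both area and harvest, ``A_est`` reduces
algebraically to ``A_sum``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import gapfill
from .panel import PanelSeries
from .registry import CropRegistry, NContentTable


@dataclass
class CropRecord:
    """One crop observation: area (kha) and/or fresh production (Gg)."""

    country: str
    year: int
    crop: str
    area: float | None  # kha
    production: float | None  # Gg fresh matter
    n_content: float  # % N of fresh production

    def __post_init__(self) -> None:
        if self.area is not None and not np.isnan(self.area) and self.area < 0:
            raise ValueError(
                f"negative area for {self.crop} in {self.country}/{self.year}"
            )
        if (
            self.production is not None
            and not np.isnan(self.production)
            and self.production < 0
        ):
            raise ValueError(
                f"negative production for {self.crop} in {self.country}/{self.year}"
            )


def n_harvest(production: float, n_content: float) -> float:
    """Convert fresh production (Gg) at an N content (%) to Gg N."""
    return production * n_content / 100.0


@dataclass
class CropCategoryAggregate:
    """Category-level estimates for one country-year."""

    a_sum: float  # kha, sum of available crop areas
    h_sum: float  # Gg N, sum of available crop N harvests
    y_est: float | None  # Gg N / kha over crops with both area and harvest
    a_est: float  # kha
    flags: list[str] = field(default_factory=list)


def aggregate_category(records: Sequence[CropRecord]) -> CropCategoryAggregate:
    """Aggregate the crops of one country-year-category.

    Missing areas or productions contribute nothing to the sums.  ``Y_est``
    is undefined (and flagged) when no crop has both area and harvest, in
    which case ``A_est`` falls back to ``A_sum``.
    """
    if not records:
        raise ValueError("aggregate_category: empty record list")
    flags: list[str] = []

    def has(v) -> bool:
        return v is not None and not np.isnan(v)

    a_sum = sum(r.area for r in records if has(r.area))
    h_sum = sum(
        n_harvest(r.production, r.n_content) for r in records if has(r.production)
    )
    both = [r for r in records if has(r.area) and has(r.production)]
    a_both = sum(r.area for r in both)
    h_both = sum(n_harvest(r.production, r.n_content) for r in both)
    if both and a_both > 0:
        y_est = h_both / a_both
        a_est = h_sum / y_est if y_est > 0 else a_sum
        if y_est <= 0:
            flags.append("zero_yield")
    else:
        y_est = None
        a_est = a_sum
        flags.append("y_est_undefined")
    incomplete_area = [r.crop for r in records if has(r.production) and not has(r.area)]
    if incomplete_area:
        flags.append("area_estimated")
    return CropCategoryAggregate(a_sum, h_sum, y_est, a_est, flags)


def aggregate_panel(
    records: pd.DataFrame,
    registry: CropRegistry,
    n_contents: NContentTable | Mapping[str, float],
) -> pd.DataFrame:
    """Aggregate a crop-record table to category level.

    ``records`` has columns country, year, crop, area, production (NaN for
    missing).  Returns one row per (country, year, category) with columns
    a_sum, h_sum, y_est, a_est, flags.
    """
    rows = []
    records = records.copy()
    records["category"] = [registry.category_of(c) for c in records["crop"]]
    records = records[records["category"].notna()]
    for (country, year, category), grp in records.groupby(
        ["country", "year", "category"], sort=True
    ):
        recs = [
            CropRecord(
                country,
                int(year),
                r.crop,
                None if pd.isna(r.area) else float(r.area),
                None if pd.isna(r.production) else float(r.production),
                float(n_contents[r.crop]),
            )
            for r in grp.itertuples()
        ]
        agg = aggregate_category(recs)
        rows.append(
            {
                "country": country,
                "year": int(year),
                "category": category,
                "a_sum": agg.a_sum,
                "h_sum": agg.h_sum,
                "y_est": np.nan if agg.y_est is None else agg.y_est,
                "a_est": agg.a_est,
                "flags": ";".join(agg.flags),
            }
        )
    return pd.DataFrame(rows)


def category_series(
    aggregates: pd.DataFrame,
    country: str,
    variable: str,
    unit: str,
    years: Iterable[int] | None = None,
) -> dict[str, PanelSeries]:
    """Turn an aggregate table column into per-category PanelSeries."""
    out: dict[str, PanelSeries] = {}
    sub = aggregates[aggregates["country"] == country]
    for category, grp in sub.groupby("category"):
        data = {
            int(y): float(v)
            for y, v in zip(grp["year"], grp[variable])
            if not pd.isna(v)
        }
        out[category] = PanelSeries.from_dict(
            country, f"{variable}.{category}", unit, data, years=years
        )
    return out


def apply_category_overrides(
    series: Mapping[str, PanelSeries],
    rules: Iterable[gapfill.EditRule | Mapping],
) -> dict[str, PanelSeries]:
    """Apply case-by-case category-level edits (delegates to the rule engine).

    Rules referencing categories absent from ``series`` raise; the default
    (no rules) passes the estimates through unchanged.
    """
    return gapfill.apply_rules(series, rules)


def zero_fill_missing_categories(
    series: Mapping[str, PanelSeries],
    categories: Iterable[str],
    country: str,
    variable_prefix: str,
    unit: str,
    years: Iterable[int] | None = None,
) -> dict[str, PanelSeries]:
    """Assign explicit zero series to categories with no data at all."""
    out = dict(series)
    for cat in categories:
        if cat not in out:
            empty = PanelSeries.from_dict(
                country, f"{variable_prefix}.{cat}", unit, {}, years=years
            )
            out[cat] = empty.with_values(empty.values.fillna(0.0))
    return out
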