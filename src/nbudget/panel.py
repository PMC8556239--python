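"""Country-year panel series and tidy-CSV input/output.

Every stage of the pipeline exchanges data as :class:`PanelSeries`: one
variable for one country (or composite region) on an explicit year grid,
with missing values encoded as NaN internally and as an empty field in the
tidy CSV representation.  Units are restricted to the small set used in
cropland nitrogen accounting: areas in kha, N quantities in Gg N/yr, rates
in kg N/ha/yr, N contents in % of dry matter, and dimensionless shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Units accepted throughout the package.
ALLOWED_UNITS = frozenset(
    {"kha", "Gg N/yr", "kg N/ha/yr", "% N of DM", "dimensionless"}
)

#: Units whose values must be nonnegative (areas, quantities, rates).
NONNEGATIVE_UNITS = frozenset({"kha", "Gg N/yr", "kg N/ha/yr"})

#: Default year grid of the database.
DEFAULT_YEARS = range(1961, 2020)

TIDY_COLUMNS = ["country", "year", "variable", "unit", "value"]


class PanelError(ValueError):
    """Raised for malformed panel data (bad units, duplicates, negatives)."""


def year_index(years: Iterable[int] | None = None) -> pd.Index:
    """Return an integer year index for the given grid (default 1961-2019)."""
    if years is None:
        years = DEFAULT_YEARS
    idx = pd.Index(sorted(int(y) for y in years), name="year")
    if idx.has_duplicates:
        raise PanelError("year grid contains duplicate years")
    return idx


@dataclass
class PanelSeries:
    """One variable for one country on an explicit year grid.

    ``values`` is a float Series indexed by the year grid; NaN marks a
    missing observation.  The grid is complete by construction: every year
    of the grid is present and no year outside it.
    """

    country: str
    variable: str
    unit: str
    values: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.unit not in ALLOWED_UNITS:
            raise PanelError(
                f"unknown unit {self.unit!r} for {self.country}/{self.variable}; "
                f"expected one of {sorted(ALLOWED_UNITS)}"
            )
        vals = pd.Series(self.values, dtype=float)
        vals.index = pd.Index([int(y) for y in vals.index], name="year")
        if not vals.index.is_monotonic_increasing:
            vals = vals.sort_index()
        self.values = vals
        self._check_nonnegative()

    def _check_nonnegative(self) -> None:
        if self.unit in NONNEGATIVE_UNITS:
            bad = self.values[self.values < 0]
            if len(bad):
                year = int(bad.index[0])
                raise PanelError(
                    f"negative value {bad.iloc[0]!r} for "
                    f"{self.country}/{self.variable} ({self.unit}) in {year}"
                )

    @classmethod
    def from_dict(
        cls,
        country: str,
        variable: str,
        unit: str,
        data: Mapping[int, float],
        years: Iterable[int] | None = None,
    ) -> "PanelSeries":
        """Build a grid-complete series from a {year: value} mapping."""
        idx = year_index(years)
        outside = [y for y in data if int(y) not in idx]
        if outside:
            raise PanelError(
                f"{country}/{variable}: year {outside[0]} outside the grid"
            )
        vals = pd.Series({int(y): float(v) for y, v in data.items()}, dtype=float)
        vals = vals.reindex(idx)
        return cls(country, variable, unit, vals)

    @property
    def years(self) -> pd.Index:
        return self.values.index

    def is_missing(self) -> pd.Series:
        return self.values.isna()

    def copy(self) -> "PanelSeries":
        return PanelSeries(self.country, self.variable, self.unit, self.values.copy())

    def with_values(self, values: pd.Series) -> "PanelSeries":
        """Return a copy carrying ``values`` (same grid expected)."""
        out = PanelSeries(self.country, self.variable, self.unit, values)
        if not out.values.index.equals(self.values.index):
            raise PanelError("with_values changed the year grid")
        return out

    def equals(self, other: "PanelSeries") -> bool:
        return (
            self.country == other.country
            and self.variable == other.variable
            and self.unit == other.unit
            and self.values.index.equals(other.values.index)
            and ((self.values == other.values) | (self.values.isna() & other.values.isna())).all()
        )


def rate_kg_per_ha(quantity_gg: float, area_kha: float) -> float:
    """Convert Gg N/yr over kha to kg N/ha/yr (1 Gg over 1 kha = 1000 kg/ha)."""
    return quantity_gg * 1000.0 / area_kha


def quantity_gg(rate_kg_ha: float, area_kha: float) -> float:
    """Convert a kg N/ha/yr rate on an area in kha to Gg N/yr."""
    return rate_kg_ha * area_kha / 1000.0


def read_panel(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    years: Iterable[int] | None = None,
    country_years: Mapping[str, Iterable[int]] | None = None,
) -> dict[tuple[str, str], PanelSeries]:
    """Read a tidy CSV (country,year,variable,unit,value) into PanelSeries.

    Parameters
    ----------
    schema
        Optional {variable: unit} mapping; variables present in the file but
        not in the schema, or with a different unit, are rejected.
    years
        Year grid applied to every country (default 1961-2019).
    country_years
        Per-country grid overrides (e.g. 1992-2019 for late-starting
        countries); takes precedence over ``years``.
    """
    df = pd.read_csv(
        path,
        dtype={"country": str, "variable": str, "unit": str},
        float_precision="round_trip",
    )
    missing_cols = [c for c in TIDY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelError(f"{path}: missing tidy columns {missing_cols}")
    df = df.dropna(subset=["value"])
    dup = df.duplicated(subset=["country", "year", "variable"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise PanelError(
            f"{path}: duplicate rows for ({row['country']}, {int(row['year'])}, "
            f"{row['variable']})"
        )
    out: dict[tuple[str, str], PanelSeries] = {}
    for (country, variable), grp in df.groupby(["country", "variable"], sort=True):
        units = grp["unit"].unique()
        if len(units) != 1:
            raise PanelError(
                f"{path}: inconsistent units {list(units)} for {country}/{variable}"
            )
        unit = units[0]
        if schema is not None:
            if variable not in schema:
                raise PanelError(f"{path}: unexpected variable {variable!r}")
            if schema[variable] != unit:
                raise PanelError(
                    f"{path}: {variable!r} has unit {unit!r}, expected "
                    f"{schema[variable]!r}"
                )
        grid = (
            country_years.get(country, years)
            if country_years is not None
            else years
        )
        data = dict(zip(grp["year"].astype(int), grp["value"].astype(float)))
        out[(country, variable)] = PanelSeries.from_dict(
            country, variable, unit, data, years=grid
        )
    return out


def write_panel(
    series: Iterable[PanelSeries] | Mapping[tuple[str, str], PanelSeries],
    path: str | Path,
) -> None:
    """Write PanelSeries to a tidy CSV; missing years become empty fields.

    ``read_panel(write_panel(x))`` is the identity on the value grid
    (float formatting uses the shortest round-trippable representation).
    """
    if isinstance(series, Mapping):
        series = list(series.values())
    rows = []
    for s in series:
        for year, value in s.values.items():
            rows.append(
                {
                    "country": s.country,
                    "year": int(year),
                    "variable": s.variable,
                    "unit": s.unit,
                    "value": "" if pd.isna(value) else repr(float(value)),
                }
            )
    df = pd.DataFrame(rows, columns=TIDY_COLUMNS)
    if len(df):
        df = df.sort_values(["country", "variable", "year"], kind="stable")
    df.to_csv(path, index=False)


def merge_constituents(
    parts: Iterable[PanelSeries],
    country: str,
) -> PanelSeries:
    """Sum constituent series into a composite region (e.g. BE+LU).

    All parts must share variable and unit; years where every part is
    missing stay missing, otherwise missing parts are treated as absent.
    """
    parts = list(parts)
    if not parts:
        raise PanelError("merge_constituents: empty part list")
    variable = parts[0].variable
    unit = parts[0].unit
    for p in parts[1:]:
        if p.variable != variable or p.unit != unit:
            raise PanelError("merge_constituents: variable/unit mismatch")
    frame = pd.concat([p.values for p in parts], axis=1)
    total = frame.sum(axis=1, min_count=1)
    return PanelSeries(country, variable, unit, total)
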