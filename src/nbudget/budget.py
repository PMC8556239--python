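"""Assembly of the cropland soil-surface N budget per country-year.

The budget confronts the four N inputs to cropland -- synthetic fertilizer,
manure, symbiotic fixation, atmospheric deposition -- with the N removed in
crop harvest.  Derived indicators: surplus (inputs minus harvest), per-ha
input and harvest rates over cropland in use, and nitrogen use efficiency
(harvest over inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import PanelSeries, rate_kg_per_ha


class BudgetError(ValueError):
    pass


@dataclass
class BudgetRow:
    """One country-year of the cropland N budget (quantities Gg N/yr)."""

    country: str
    year: int
    harvest_n: float
    fert_c: float
    manure_c: float
    bnf: float
    deposition_c: float
    cropland_in_use: float  # kha
    input_total: float = field(init=False)
    surplus: float = field(init=False)
    input_rate: float = field(init=False)  # kg N/ha/yr
    harvest_rate: float = field(init=False)  # kg N/ha/yr
    nue: float = field(init=False)  # harvest / inputs, dimensionless
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        terms = {
            "harvest_n": self.harvest_n,
            "fert_c": self.fert_c,
            "manure_c": self.manure_c,
            "bnf": self.bnf,
            "deposition_c": self.deposition_c,
        }
        missing = [k for k, v in terms.items() if v is None or np.isnan(v)]
        if missing:
            raise BudgetError(
                f"{self.country}/{self.year}: missing budget terms {missing} "
                "(terms are flagged upstream, never zero-filled here)"
            )
        self.input_total = self.fert_c + self.manure_c + self.bnf + self.deposition_c
        self.surplus = self.input_total - self.harvest_n
        if self.cropland_in_use > 0:
            self.input_rate = rate_kg_per_ha(self.input_total, self.cropland_in_use)
            self.harvest_rate = rate_kg_per_ha(self.harvest_n, self.cropland_in_use)
        else:
            self.input_rate = float("nan")
            self.harvest_rate = float("nan")
            if self.input_total != 0 or self.harvest_n != 0:
                self.flags.append("rates_undefined_zero_area")
        self.nue = (
            self.harvest_n / self.input_total if self.input_total > 0 else float("nan")
        )


BUDGET_COLUMNS = [
    "country",
    "year",
    "harvest_n",
    "fert_c",
    "manure_c",
    "bnf",
    "deposition_c",
    "cropland_in_use",
    "input_total",
    "surplus",
    "input_rate",
    "harvest_rate",
    "nue",
    "flags",
]


def assemble_budget(
    harvest_n: PanelSeries,
    fert_c: PanelSeries,
    manure_c: PanelSeries,
    bnf_total: PanelSeries,
    deposition_c: PanelSeries,
    cropland_in_use: PanelSeries,
) -> pd.DataFrame:
    """Assemble BudgetRows for one country over its year grid.

    Years where any term is missing are skipped with a flag row rather
    than zero-filled.
    """
    country = harvest_n.country
    rows = []
    for year in harvest_n.values.index:
        vals = [
            s.values.get(year, np.nan)
            for s in (harvest_n, fert_c, manure_c, bnf_total, deposition_c)
        ]
        area = cropland_in_use.values.get(year, np.nan)
        if any(np.isnan(v) for v in vals) or np.isnan(area):
            continue
        row = BudgetRow(country, int(year), *map(float, vals), float(area))
        rows.append(
            {
                "country": row.country,
                "year": row.year,
                "harvest_n": row.harvest_n,
                "fert_c": row.fert_c,
                "manure_c": row.manure_c,
                "bnf": row.bnf,
                "deposition_c": row.deposition_c,
                "cropland_in_use": row.cropland_in_use,
                "input_total": row.input_total,
                "surplus": row.surplus,
                "input_rate": row.input_rate,
                "harvest_rate": row.harvest_rate,
                "nue": row.nue,
                "flags": ";".join(row.flags),
            }
        )
    return pd.DataFrame(rows, columns=BUDGET_COLUMNS)
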