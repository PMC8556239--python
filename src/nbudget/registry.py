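"""Crop-code registry, output categories, and fodder N contents.

The database reports 17 crop categories: 12 aggregated from FAOSTAT-style
arable and permanent crops, and 5 fodder categories built from the Eurostat
crop-code hierarchy (G1000 temporary grasses and grazings, G2100 lucerne,
G2900 other leguminous plants harvested green, G3000 green maize, G9000
other plants harvested green, R9000 other root crops).  G2100 and G2900 are
merged into the single category "Forage legumes".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

#: The 12 categories aggregated from FAOSTAT-style crops.
NON_FODDER_CATEGORIES = (
    "Wheat",
    "Barley",
    "Grain maize",
    "Other cereals",
    "Oilseeds",
    "Potatoes",
    "Sugar beet",
    "Pulses",
    "Vegetables and other",
    "Olives",
    "Grapes",
    "Other permanent crops",
)

#: The 5 fodder categories built from Eurostat crop codes.
FODDER_CATEGORIES = (
    "Green maize",
    "Temporary grassland",
    "Forage legumes",
    "Fodder roots",
    "Other forage crops",
)

#: All 17 output categories.
CATEGORIES = NON_FODDER_CATEGORIES + FODDER_CATEGORIES

#: Eurostat fodder crop code -> output category (G2100 and G2900 merge).
FODDER_CODE_CATEGORY: Mapping[str, str] = {
    "G1000": "Temporary grassland",
    "G2100": "Forage legumes",
    "G2900": "Forage legumes",
    "G3000": "Green maize",
    "G9000": "Other forage crops",
    "R9000": "Fodder roots",
}

#: Codes that feed the derived fodder codes.
G9000_PARTS = ("G9100", "G9900")
R9000_PARENT = "R0000"
R9000_SIBLINGS = ("R1000", "R2000")


class RegistryError(KeyError):
    """Raised when a crop code cannot be categorized."""


def mixture_n_content(components: list[tuple[float, float]]) -> float:
    """Weighted-mean N content of a mixture, e.g. grass/clover swards.

    ``components`` is a list of (mass share of DM, % N of DM) pairs; shares
    must sum to 1 within 1e-9.
    """
    total = sum(share for share, _ in components)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture shares sum to {total}, expected 1")
    if any(share < 0 for share, _ in components):
        raise ValueError("negative mixture share")
    return sum(share * nc for share, nc in components)


#: Mixture compositions behind the fodder N contents (share of DM, % N of DM):
#: temporary grassland is 75% grass (2.0) / 25% clover (3.3); other forage
#: legumes 90% clover (3.3) / 10% grass (2.0); other green fodder 75% cereal
#: forage (1.6) / 25% legumes (3.0).
FODDER_N_MIXTURES: Mapping[str, list[tuple[float, float]]] = {
    "G1000": [(0.75, 2.0), (0.25, 3.3)],
    "G2900": [(0.90, 3.3), (0.10, 2.0)],
    "G9000": [(0.75, 1.6), (0.25, 3.0)],
}

#: Assumed fodder N contents, % N of dry matter (mixtures rounded to the
#: precision used in the database; G2100 lucerne, G3000 green maize, R9000
#: fodder beet are single-crop values).
FODDER_N_CONTENT: Mapping[str, float] = {
    "G1000": 2.3,
    "G2100": 3.0,
    "G2900": 3.2,
    "G3000": 1.2,
    "G9000": 2.0,
    "R9000": 1.3,
}


class NContentTable:
    """Crop code -> N content in % of dry matter; values must lie in (0, 10]."""

    def __init__(self, contents: Mapping[str, float]):
        for code, value in contents.items():
            if not (0.0 < value <= 10.0):
                raise ValueError(
                    f"N content {value} for {code!r} outside (0, 10] % of DM"
                )
        self._contents = dict(contents)

    def __getitem__(self, code: str) -> float:
        try:
            return self._contents[code]
        except KeyError:
            raise RegistryError(f"no N content registered for crop {code!r}")

    def __contains__(self, code: str) -> bool:
        return code in self._contents

    def items(self):
        return self._contents.items()


@dataclass(frozen=True)
class CropCode:
    """A crop identifier with its source nomenclature and output category."""

    code: str
    source: str  # "faostat-like" or "eurostat-like"
    category: str | None  # one of CATEGORIES, or None if uncategorized


class CropRegistry:
    """Total mapping from registered crop codes to output categories."""

    def __init__(self, codes: Mapping[str, CropCode]):
        for cc in codes.values():
            if cc.category is not None and cc.category not in CATEGORIES:
                raise RegistryError(
                    f"crop {cc.code!r} maps to unknown category {cc.category!r}"
                )
        self._codes = dict(codes)

    @classmethod
    def from_rows(cls, rows: list[tuple[str, str, str | None]]) -> "CropRegistry":
        codes = {}
        for code, source, category in rows:
            if code in codes:
                raise RegistryError(f"crop code {code!r} registered twice")
            codes[code] = CropCode(code, source, category or None)
        return cls(codes)

    @classmethod
    def from_csv(cls, path) -> "CropRegistry":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            rows = [
                (r["crop"], r.get("source", "faostat-like"), r.get("category"))
                for r in reader
            ]
        return cls.from_rows(rows)

    @classmethod
    def default_fodder(cls) -> "CropRegistry":
        rows = [
            (code, "eurostat-like", cat) for code, cat in FODDER_CODE_CATEGORY.items()
        ]
        return cls.from_rows(rows)

    def category_of(self, code: str) -> str | None:
        try:
            return self._codes[code].category
        except KeyError:
            raise RegistryError(f"crop code {code!r} is not registered")

    def __contains__(self, code: str) -> bool:
        return code in self._codes

    def codes(self) -> list[str]:
        return sorted(self._codes)


def load_faostat_registry() -> CropRegistry:
    """The shipped mapping of 121 FAOSTAT-style crops to the 12 categories."""
    path = resources.files("nbudget.data").joinpath("crop_categories_faostat.csv")
    with resources.as_file(path) as p:
        return CropRegistry.from_csv(p)


#: Composite regions reported as one unit for part of the period, with their
#: present-day constituents (enables area/quantity-weighted merges).
COMPOSITE_REGIONS: Mapping[str, tuple[str, ...]] = {
    "Belgium-Luxembourg": ("Belgium", "Luxembourg"),
    "Czechoslovakia": ("Czechia", "Slovakia"),
}

#: Countries covered 1992-2019 instead of the full 1961-2019 period.
LATE_START_COUNTRIES: Mapping[str, int] = {
    "Croatia": 1992,
    "Estonia": 1992,
    "Latvia": 1992,
    "Lithuania": 1992,
    "Slovenia": 1992,
}
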