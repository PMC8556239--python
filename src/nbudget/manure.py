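"""Manure N flow chain: excretion -> management -> losses -> land.

Excreted N per livestock class is split between grazing and housing by
manure-management-system (MMS) shares reported in greenhouse-gas inventory
format; detailed systems aggregate to four simplified ones (grazing, solid,
liquid, other) and detailed livestock classes to three (ruminants and
equines, pigs, poultry and rabbits).  Housed excretion loses a constant
country-specific fraction in houses and storage; what remains is applied to
grass or non-grass land using constant allocation shares (liquid/solid
specific for ruminants and pigs, weighted by the mean liquid/solid split
over a reference window, 1997-2001 by default).  Grassland-destined N
(field-applied plus all grazing excretion) is divided between permanent and
temporary grassland in proportion to their areas; cropland receives the
non-grass applications plus the temporary-grassland portion.  Every step is
a product-and-remainder split, so the chain conserves N bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .land import grassland_split

#: Aggregation of detailed (UNFCCC-style) manure management systems.
MMS_SYSTEM_MAP: Mapping[str, str] = {
    "Pasture range and paddock": "grazing",
    "Composting": "solid",
    "Daily spread": "solid",
    "Solid storage and dry lot": "solid",
    "Anaerobic lagoon": "liquid",
    "Digesters": "liquid",
    "Liquid system": "liquid",
    "Other": "other",
}

#: Aggregation of detailed livestock classes.
LIVESTOCK_CLASS_MAP: Mapping[str, str] = {
    "Cattle": "ruminants_equines",
    "Sheep": "ruminants_equines",
    "Buffalo": "ruminants_equines",
    "Goats": "ruminants_equines",
    "Horses": "ruminants_equines",
    "Mules and Asses": "ruminants_equines",
    "Swine": "pigs",
    "Poultry": "poultry_rabbits",
    "Rabbit": "poultry_rabbits",
}

SIMPLIFIED_SYSTEMS = ("grazing", "solid", "liquid", "other")
SIMPLIFIED_CLASSES = ("ruminants_equines", "pigs", "poultry_rabbits")

#: "Other" MMS share above which exogenous liquid/solid data are required.
OTHER_SHARE_THRESHOLD = 0.20

#: Generic housing/storage loss fraction (fallback when no country data).
GENERIC_LOSS_SHARE = 0.30

#: Averaging window for the liquid/solid weighting of allocation shares.
MMS_WEIGHT_WINDOW = (1997, 2001)

SHARE_TOL = 1e-9


class ManureError(ValueError):
    pass


@dataclass
class MmsShares:
    """Simplified-system shares for one country-year-class (sum to 1)."""

    country: str
    year: int
    livestock_class: str
    shares: dict[str, float]

    def __post_init__(self) -> None:
        if self.livestock_class not in SIMPLIFIED_CLASSES:
            raise ManureError(f"unknown livestock class {self.livestock_class!r}")
        missing = [s for s in SIMPLIFIED_SYSTEMS if s not in self.shares]
        if missing:
            raise ManureError(f"missing system shares {missing}")
        if any(v < 0 for v in self.shares.values()):
            raise ManureError("negative MMS share")
        total = sum(self.shares.values())
        if abs(total - 1.0) > SHARE_TOL:
            raise ManureError(f"MMS shares sum to {total}, expected 1")


def aggregate_mms(
    raw: Mapping[tuple[str, str], float],
    country: str = "",
    year: int = 0,
    excretion_weights: Mapping[str, float] | None = None,
) -> dict[str, MmsShares]:
    """Aggregate detailed (class, system) shares to the simplified scheme.

    ``raw`` maps (detailed class, detailed system) -> share of that class's
    excretion; shares per detailed class must sum to 1.  Detailed classes
    merging into one simplified class are combined with excretion-weighted
    means (``excretion_weights`` per detailed class; equal weights when
    omitted).  Unmapped systems or classes raise.
    """
    per_class: dict[str, dict[str, float]] = {}
    for (cls, system), share in raw.items():
        if cls not in LIVESTOCK_CLASS_MAP:
            raise ManureError(f"unmapped livestock class {cls!r}")
        if system not in MMS_SYSTEM_MAP:
            raise ManureError(f"unmapped manure management system {system!r}")
        d = per_class.setdefault(cls, {s: 0.0 for s in SIMPLIFIED_SYSTEMS})
        d[MMS_SYSTEM_MAP[system]] += share
    for cls, shares in per_class.items():
        total = sum(shares.values())
        if abs(total - 1.0) > 1e-6:
            raise ManureError(f"shares for {cls!r} sum to {total}, expected 1")
    out: dict[str, MmsShares] = {}
    for simplified in SIMPLIFIED_CLASSES:
        members = [c for c in per_class if LIVESTOCK_CLASS_MAP[c] == simplified]
        if not members:
            continue
        if excretion_weights is None:
            weights = {c: 1.0 for c in members}
        else:
            weights = {c: excretion_weights[c] for c in members}
        wtot = sum(weights.values())
        if wtot <= 0:
            raise ManureError(f"nonpositive excretion weights for {simplified}")
        combined = {
            s: sum(per_class[c][s] * weights[c] for c in members) / wtot
            for s in SIMPLIFIED_SYSTEMS
        }
        # exact renormalization against rounding drift
        combined["other"] = max(
            0.0, 1.0 - combined["grazing"] - combined["solid"] - combined["liquid"]
        )
        out[simplified] = MmsShares(country, year, simplified, combined)
    return out


def backfill_shares(shares: pd.DataFrame, years: Sequence[int]) -> pd.DataFrame:
    """Extend an MMS share table over the full year grid.

    ``shares`` is indexed by year with one column per simplified system.
    Years before the first observation take the first observed shares;
    years after the last take the last (e.g. 2018 extended to 2019).
    Extrapolated rows still sum to 1 because whole rows are copied.
    """
    if shares.empty:
        raise ManureError("backfill_shares: no observed years")
    idx = pd.Index(sorted(int(y) for y in years), name="year")
    out = shares.sort_index().reindex(idx.union(shares.index)).ffill().bfill()
    return out.loc[idx]


def split_grazing_housed(
    excreted_total: float, grazing_share: float
) -> tuple[float, float]:
    """(grazing, housed) = (total*share, exact remainder)."""
    if not (0.0 <= grazing_share <= 1.0):
        raise ManureError(f"grazing share {grazing_share} outside [0, 1]")
    grazing = excreted_total * grazing_share
    return grazing, excreted_total - grazing


def apply_storage_losses(housed: float, loss_share: float) -> tuple[float, float]:
    """(lost, applied) = (housed*loss, exact remainder); loss in [0, 1)."""
    if not (0.0 <= loss_share < 1.0):
        raise ManureError(f"loss share {loss_share} outside [0, 1)")
    lost = housed * loss_share
    return lost, housed - lost


def liquid_solid_shares(
    shares: MmsShares | Mapping[str, float],
    other_threshold: float = OTHER_SHARE_THRESHOLD,
    override: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Partition in-house excretion between liquid and solid handling.

    The binary liquid/solid division required by land-allocation data
    mismatches MMS data that report an "other" system.  When the "other"
    share of in-house excretion is at most ``other_threshold`` it is
    ignored and liquid/solid are renormalized to sum to 1; above the
    threshold exogenous liquid/solid data (``override``) are required.
    """
    d = shares.shares if isinstance(shares, MmsShares) else dict(shares)
    solid, liquid, other = d["solid"], d["liquid"], d.get("other", 0.0)
    in_house = solid + liquid + other
    if override is not None:
        liq, sol = override
        total = liq + sol
        if total <= 0:
            raise ManureError("liquid/solid override sums to zero")
        return liq / total, sol / total
    if in_house <= 0:
        raise ManureError("no in-house excretion to partition")
    other_share = other / in_house
    if other_share > other_threshold:
        who = ""
        if isinstance(shares, MmsShares):
            who = f" for {shares.country}/{shares.livestock_class}"
        raise ManureError(
            f"'Other' MMS share {other_share:.0%} exceeds "
            f"{other_threshold:.0%}{who}; exogenous liquid/solid data required"
        )
    if solid + liquid <= 0:
        raise ManureError("liquid and solid shares both zero")
    liq = liquid / (liquid + solid)
    return liq, 1.0 - liq


def effective_grass_share(
    livestock_class: str,
    alloc: Mapping[str, float],
    liquid_weight: float | None = None,
) -> float:
    """Constant share of applied (post-storage) manure going to grassland.

    Poultry/rabbits use a single share (``alloc['all']``).  Ruminants and
    pigs use liquid/solid-specific shares weighted by the reference-window
    mean liquid split ``liquid_weight``.
    """
    if livestock_class == "poultry_rabbits" or "all" in alloc:
        share = alloc["all"]
    else:
        if liquid_weight is None:
            raise ManureError(
                f"liquid/solid weight required for {livestock_class}"
            )
        share = liquid_weight * alloc["liquid"] + (1.0 - liquid_weight) * alloc["solid"]
    if not (0.0 <= share <= 1.0):
        raise ManureError(f"grass allocation share {share} outside [0, 1]")
    return share


def split_to_land(
    applied_grass: float,
    excreted_grazing: float,
    applied_nongrass: float,
    a_pg: float,
    a_tg: float,
) -> tuple[float, float]:
    """(to_cropland, to_permanent_grassland).

    Grassland-destined N (field applications to grass plus all grazing
    excretion) splits between PG and TG in proportion to their areas; the
    TG portion belongs to cropland.  Conservation is bit-exact:
    to_cropland + to_PG = applied_grass + grazing + applied_nongrass.
    """
    grass_destined = applied_grass + excreted_grazing
    w_pg, _, flag = grassland_split(a_pg, a_tg)
    if flag == "no_grassland" and grass_destined > 0:
        raise ManureError(
            "grassland-destined manure N with zero grassland area"
        )
    to_pg = grass_destined * w_pg
    to_tg = grass_destined - to_pg
    return applied_nongrass + to_tg, to_pg


@dataclass
class ManureFlows:
    """Per country-year-class N flows (Gg N/yr), conservation-checked."""

    country: str
    year: int
    livestock_class: str
    excreted_total: float
    excreted_grazing: float
    excreted_housed: float
    lost_housing_storage: float
    applied_grass: float
    applied_nongrass: float
    to_cropland: float
    to_permanent_grassland: float

    def check(self) -> None:
        """Verify the three conservation identities bit-exactly.

        Each identity is evaluated in the residual direction used during
        construction (binary subtraction reproduces the construction
        exactly, whereas re-adding independently rounded parts can differ
        in the last bit):

        * housed = total - grazing
        * applied_nongrass = (housed - lost) - applied_grass
        * to_cropland = nongrass + ((applied_grass + grazing) - to_PG)
        """
        if self.excreted_housed != self.excreted_total - self.excreted_grazing:
            raise ManureError("excretion split does not conserve N")
        if self.applied_nongrass != (
            (self.excreted_housed - self.lost_housing_storage) - self.applied_grass
        ):
            raise ManureError("housing/storage balance does not conserve N")
        grass_destined = self.applied_grass + self.excreted_grazing
        if self.to_cropland != self.applied_nongrass + (
            grass_destined - self.to_permanent_grassland
        ):
            raise ManureError("land allocation does not conserve N")


def chain(
    country: str,
    year: int,
    livestock_class: str,
    excreted_total: float,
    mms: MmsShares | Mapping[str, float],
    loss_share: float,
    grass_share: float,
    a_pg: float,
    a_tg: float,
) -> ManureFlows:
    """Run the whole flow chain for one country-year-class."""
    d = mms.shares if isinstance(mms, MmsShares) else dict(mms)
    grazing, housed = split_grazing_housed(excreted_total, d["grazing"])
    lost, applied = apply_storage_losses(housed, loss_share)
    applied_grass = applied * grass_share
    applied_nongrass = applied - applied_grass
    to_c, to_pg = split_to_land(applied_grass, grazing, applied_nongrass, a_pg, a_tg)
    flows = ManureFlows(
        country,
        year,
        livestock_class,
        excreted_total,
        grazing,
        housed,
        lost,
        applied_grass,
        applied_nongrass,
        to_c,
        to_pg,
    )
    flows.check()
    return flows


def excretion_weighted_average(
    shares_by_region: Mapping[str, Mapping[str, float]],
    excretion_by_region: Mapping[str, float],
) -> dict[str, float]:
    """Combine constituent-region MMS shares into a composite region's
    shares, weighting by constituent excretion."""
    total = sum(excretion_by_region.values())
    if total <= 0:
        raise ManureError("composite region has zero excretion")
    systems = set()
    for d in shares_by_region.values():
        systems.update(d)
    return {
        s: sum(
            shares_by_region[r].get(s, 0.0) * excretion_by_region[r]
            for r in shares_by_region
        )
        / total
        for s in sorted(systems)
    }
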