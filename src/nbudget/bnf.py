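"""Symbiotic N fixation and atmospheric deposition inputs to cropland.

Symbiotic fixation is assumed linear in the harvested legume N yield Y:

    BNF = Y * Ndfa * BGN / NHI

where Ndfa is the fraction of plant N derived from the atmosphere, BGN the
ratio of total (above- plus below-ground) to above-ground plant N, and NHI
the N harvest index (harvested over above-ground N).  For mixed fodder
swards only a fraction of the dry-matter harvest is legume: 25% for
temporary grassland, 90% for pure forage legume stands, 25% for other
green fodder; pulses are 100% legume and their harvested N is used
directly.  Deposition input is the deposition rate times cropland in use,
with rates extrapolated constant beyond their last observed year.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import gapfill
from .panel import PanelSeries


@dataclass
class BnfParams:
    """Fixation parameters for one crop or category.

    ``legume_dm_share`` is the legume fraction of the DM harvest and
    ``legume_n_content`` (% N of DM) applies to that fraction; for crops
    whose harvested N is already pure legume N (pulses) set the share to 1
    and feed harvested N directly to :func:`bnf`.
    """

    crop: str
    ndfa: float
    bgn: float
    nhi: float
    legume_dm_share: float
    legume_n_content: float | None = None

    def __post_init__(self) -> None:
        for name in ("ndfa", "legume_dm_share"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} {v} outside [0, 1] for {self.crop}")
        if not (0.0 < self.nhi <= 1.0):
            raise ValueError(f"nhi {self.nhi} outside (0, 1] for {self.crop}")
        if self.bgn < 1.0:
            raise ValueError(f"bgn {self.bgn} below 1 for {self.crop}")


def legume_n_harvest(dm_harvest: float, params: BnfParams) -> float:
    """Harvested legume N (Gg N) from a DM harvest (Gg DM)."""
    if params.legume_n_content is None:
        raise ValueError(f"legume N content required for {params.crop}")
    return dm_harvest * params.legume_dm_share * params.legume_n_content / 100.0


def bnf(y_legume: float, params: BnfParams) -> float:
    """Fixed N (Gg N) from harvested legume N via BNF = Y*Ndfa*BGN/NHI."""
    return y_legume * params.ndfa * params.bgn / params.nhi


def deposition_to_cropland(
    rate: PanelSeries, cropland_in_use: PanelSeries
) -> PanelSeries:
    """Deposition input (Gg N/yr) = rate (kg N/ha/yr) x area (kha) / 1000.

    Trailing missing rate years are filled by constant extrapolation (the
    deposition-rate record ends before the land record does).
    """
    if rate.unit != "kg N/ha/yr":
        raise ValueError(f"deposition rate unit {rate.unit!r}")
    if cropland_in_use.unit != "kha":
        raise ValueError(f"cropland area unit {cropland_in_use.unit!r}")
    filled = gapfill.extrapolate_const(rate, "forward")
    values = filled.values * cropland_in_use.values / 1000.0
    return PanelSeries(rate.country, "deposition_to_cropland", "Gg N/yr", values)
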