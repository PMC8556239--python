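"""Land-area bookkeeping: cropland in use, grasslands, fallow check.

Cropland in use is estimated as the sum of harvested crop-category areas,
capped by the reported total cropland area (the sum can exceed it through
multi- and intercropping).  Permanent grassland comes from reported land
use; temporary grassland is the gap-filled G1000 crop area and is part of
cropland.  A consistency check compares the crop area sum against reported
cropland minus fallow, flagging deviations beyond a tolerance (default 5%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import PanelSeries

FALLOW_TOL = 0.05


def cropland_in_use(a_crop_sum: float, a_reported: float) -> tuple[float, str]:
    """min(crop area sum, reported cropland); one-sided values are flagged.

    Returns (value, flag); flag is '' when both inputs exist, otherwise
    names the side used; NaN when both are missing.
    """
    sum_ok = a_crop_sum is not None and np.isfinite(a_crop_sum)
    rep_ok = a_reported is not None and np.isfinite(a_reported)
    if sum_ok and rep_ok:
        return min(a_crop_sum, a_reported), ""
    if sum_ok:
        return a_crop_sum, "crop_sum_only"
    if rep_ok:
        return a_reported, "reported_only"
    return float("nan"), "both_missing"


def cropland_in_use_series(
    a_crop_sum: PanelSeries, a_reported: PanelSeries
) -> tuple[PanelSeries, pd.Series]:
    """Elementwise :func:`cropland_in_use` over two panel series."""
    values = []
    flags = []
    for year in a_crop_sum.values.index:
        v, f = cropland_in_use(
            a_crop_sum.values.get(year, np.nan), a_reported.values.get(year, np.nan)
        )
        values.append(v)
        flags.append(f)
    out = PanelSeries(
        a_crop_sum.country,
        "cropland_in_use",
        "kha",
        pd.Series(values, index=a_crop_sum.values.index),
    )
    return out, pd.Series(flags, index=a_crop_sum.values.index)


def fallow_consistency(
    a_crop_sum: float,
    a_reported: float,
    a_fallow: float,
    tol: float = FALLOW_TOL,
) -> bool:
    """True (flag) when the crop area sum disagrees with cropland minus
    fallow by more than ``tol`` (relative); also flags nonpositive bases."""
    base = a_reported - a_fallow
    if base <= 0:
        return True
    return abs(a_crop_sum - base) / base > tol


def grassland_split(a_pg: float, a_tg: float) -> tuple[float, float, str]:
    """Proportional weights (w_pg, w_tg) for grassland-destined flows.

    With no grassland at all the split is degenerate: returns zeros with a
    flag, so that downstream flows are all-zero rather than undefined.
    """
    if a_pg < 0 or a_tg < 0:
        raise ValueError("negative grassland area")
    total = a_pg + a_tg
    if total == 0:
        return 0.0, 0.0, "no_grassland"
    w_pg = a_pg / total
    return w_pg, 1.0 - w_pg, ""


@dataclass
class LandAreas:
    """Per country-year land bookkeeping (areas in kha)."""

    country: str
    year: int
    a_reported: float
    a_crop_sum: float
    a_c_in_use: float
    a_pg: float
    a_tg: float
    a_fallow: float | None = None

    def __post_init__(self) -> None:
        if (
            np.isfinite(self.a_crop_sum)
            and np.isfinite(self.a_reported)
            and not np.isclose(
                self.a_c_in_use, min(self.a_crop_sum, self.a_reported)
            )
        ):
            raise ValueError(
                f"{self.country}/{self.year}: cropland in use "
                f"{self.a_c_in_use} != min(crop sum, reported)"
            )
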