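"""Composable gap-filling and series-editing operations.

Country panels assembled from heterogeneous statistical sources need a
recurring set of mechanical edits: linear interpolation of interior gaps,
constant extrapolation at the edges, proportional splitting of lumped
historical categories (e.g. a single "hay" area divided among temporary
grassland, forage legumes and other green fodder by their shares in a
reference year), residuals within a code hierarchy (fodder roots as
R0000 - R1000 - R2000), year-wise merging (G9000 = G9100 + G9900), and
explicit discard/replace/scale edits.  All of them are exposed both as
plain functions on :class:`~nbudget.panel.PanelSeries` and as declarative
:class:`EditRule` entries applied in listed order, so that country-specific
adjustments live in human-editable config rather than code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .panel import PanelError, PanelSeries

log = logging.getLogger(__name__)

RULE_KINDS = (
    "interpolate_linear",
    "extrapolate_const",
    "proportional_split",
    "residual",
    "merge_sum",
    "discard",
    "replace",
    "scale",
)


def _year_mask(index: pd.Index, years: tuple[int, int] | None) -> pd.Series:
    if years is None:
        return pd.Series(True, index=index)
    lo, hi = years
    return pd.Series((index >= lo) & (index <= hi), index=index)


def interpolate_linear(
    s: PanelSeries, years: tuple[int, int] | None = None
) -> PanelSeries:
    """Fill interior missing years by linear interpolation.

    Observed values are never modified; years outside the observed envelope
    remain missing (edges are the business of :func:`extrapolate_const`).
    """
    filled = s.values.interpolate(method="index", limit_area="inside")
    mask = _year_mask(s.values.index, years)
    out = s.values.where(~(s.values.isna() & mask), filled)
    return s.with_values(out)


def extrapolate_const(
    s: PanelSeries, direction: str = "both"
) -> PanelSeries:
    """Fill leading/trailing missing years with the nearest observed value."""
    if direction not in ("backward", "forward", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    if s.values.notna().sum() == 0:
        raise PanelError(
            f"extrapolate_const: {s.country}/{s.variable} is all-missing"
        )
    out = s.values.copy()
    notna = out.notna()
    first, last = notna.idxmax(), notna[::-1].idxmax()
    if direction in ("backward", "both"):
        out.loc[out.index < first] = out.loc[first]
    if direction in ("forward", "both"):
        out.loc[out.index > last] = out.loc[last]
    return s.with_values(out)


def proportional_split(
    total: PanelSeries,
    shares: Mapping[str, float],
) -> dict[str, PanelSeries]:
    """Split a lumped series into components by fixed shares.

    Shares must be nonnegative and sum to 1 within 1e-9.  The last-listed
    component takes the residual so that the components sum to the total
    bit-exactly in every year.
    """
    names = list(shares)
    vals = [shares[n] for n in names]
    if any(v < 0 for v in vals):
        raise ValueError("negative share in proportional_split")
    if abs(sum(vals) - 1.0) > 1e-9:
        raise ValueError(f"shares sum to {sum(vals)}, expected 1")
    out: dict[str, PanelSeries] = {}
    running = pd.Series(0.0, index=total.values.index)
    for name in names[:-1]:
        comp = total.values * shares[name]
        running = running + comp
        out[name] = PanelSeries(total.country, name, total.unit, comp)
    last = total.values - running
    out[names[-1]] = PanelSeries(total.country, names[-1], total.unit, last)
    return out


def shares_from_reference_year(
    components: Sequence[PanelSeries], year: int
) -> dict[str, float]:
    """Component shares proportional to their observed values in one year."""
    vals = {}
    for c in components:
        v = c.values.get(year, np.nan)
        if pd.isna(v):
            raise PanelError(
                f"shares_from_reference_year: {c.country}/{c.variable} "
                f"missing in {year}"
            )
        vals[c.variable] = float(v)
    total = sum(vals.values())
    if total <= 0:
        raise PanelError(f"reference year {year} has zero total")
    names = list(vals)
    shares = {n: vals[n] / total for n in names[:-1]}
    shares[names[-1]] = 1.0 - sum(shares.values())
    return shares


def residual(parent: PanelSeries, children: Sequence[PanelSeries]) -> PanelSeries:
    """parent - sum(children), clipped at zero with a logged warning.

    A year yields a value only when parent and all children are observed;
    otherwise missing propagates.
    """
    out = parent.values.copy()
    for c in children:
        if c.unit != parent.unit:
            raise PanelError("residual: unit mismatch")
        out = out - c.values
    negative = out < 0
    if negative.any():
        yrs = list(out.index[negative])
        log.warning(
            "residual %s/%s negative in %d year(s) (e.g. %s); clipped to 0",
            parent.country,
            parent.variable,
            int(negative.sum()),
            yrs[0],
        )
        out = out.clip(lower=0.0)
    return parent.with_values(out)


def merge_sum(a: PanelSeries, b: PanelSeries, variable: str | None = None) -> PanelSeries:
    """Year-wise sum treating missing as absent unless both are missing."""
    if a.unit != b.unit:
        raise PanelError(f"merge_sum: unit mismatch {a.unit!r} vs {b.unit!r}")
    total = pd.concat([a.values, b.values], axis=1).sum(axis=1, min_count=1)
    return PanelSeries(a.country, variable or a.variable, a.unit, total)


def discard(s: PanelSeries, years: tuple[int, int]) -> PanelSeries:
    """Set the given year span to missing (explicit outlier removal)."""
    out = s.values.copy()
    mask = _year_mask(out.index, years)
    out[mask] = np.nan
    return s.with_values(out)


def replace(
    s: PanelSeries, other: PanelSeries, years: tuple[int, int] | None = None
) -> PanelSeries:
    """Substitute values from an external series over a year span."""
    if s.unit != other.unit:
        raise PanelError("replace: unit mismatch")
    mask = _year_mask(s.values.index, years) & other.values.notna()
    out = s.values.where(~mask, other.values)
    return s.with_values(out)


def scale(
    s: PanelSeries, factor: float, years: tuple[int, int] | None = None
) -> PanelSeries:
    """Multiply a year span by a constant factor."""
    mask = _year_mask(s.values.index, years)
    out = s.values.where(~mask, s.values * factor)
    return s.with_values(out)


@dataclass
class EditRule:
    """One declarative edit: ``kind`` plus its parameters.

    ``target`` names the variable the rule edits (for proportional_split the
    lumped source variable); ``params`` carries kind-specific fields such as
    ``components``, ``shares``, ``reference_year``, ``factor``, ``direction``,
    ``parent``/``children`` or ``source``; ``years`` optionally restricts the
    span edited.
    """

    kind: str
    target: str
    params: dict = dc_field(default_factory=dict)
    years: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.years is not None:
            self.years = (int(self.years[0]), int(self.years[1]))

    @classmethod
    def from_dict(cls, d: Mapping) -> "EditRule":
        d = dict(d)
        kind = d.pop("kind")
        target = d.pop("target")
        years = d.pop("years", None)
        if years is not None:
            years = (int(years[0]), int(years[1]))
        return cls(kind=kind, target=target, params=d, years=years)


def apply_rules(
    series: Mapping[str, PanelSeries],
    rules: Iterable[EditRule | Mapping],
) -> dict[str, PanelSeries]:
    """Apply a rule list in order to a {variable: PanelSeries} panel.

    Deterministic: the same rules on the same panel give bit-identical
    output.  Each applied rule is logged with the number of years filled
    or edited.
    """
    panel = {k: v.copy() for k, v in series.items()}
    for rule in rules:
        if not isinstance(rule, EditRule):
            rule = EditRule.from_dict(rule)
        if rule.target not in panel:
            raise PanelError(f"rule {rule.kind} targets unknown variable {rule.target!r}")
        s = panel[rule.target]
        before_missing = int(s.is_missing().sum())
        if rule.kind == "interpolate_linear":
            panel[rule.target] = interpolate_linear(s, rule.years)
        elif rule.kind == "extrapolate_const":
            panel[rule.target] = extrapolate_const(
                s, rule.params.get("direction", "both")
            )
        elif rule.kind == "proportional_split":
            components = rule.params["components"]
            if "shares" in rule.params:
                shares = {c: rule.params["shares"][c] for c in components}
            else:
                ref = int(rule.params["reference_year"])
                shares = shares_from_reference_year(
                    [panel[c] for c in components], ref
                )
            split = proportional_split(s, shares)
            mask = _year_mask(s.values.index, rule.years) & s.values.notna()
            for name in components:
                if name not in panel:
                    raise PanelError(
                        f"proportional_split component {name!r} not in panel"
                    )
                tgt = panel[name]
                fill = mask & tgt.values.isna()
                panel[name] = tgt.with_values(
                    tgt.values.where(~fill, split[name].values)
                )
        elif rule.kind == "residual":
            children = [panel[c] for c in rule.params["children"]]
            res = residual(s, children)
            into = rule.params.get("into", rule.target)
            panel[into] = PanelSeries(res.country, into, res.unit, res.values)
        elif rule.kind == "merge_sum":
            other = panel[rule.params["other"]]
            merged = merge_sum(s, other, rule.params.get("into", rule.target))
            panel[merged.variable] = merged
        elif rule.kind == "discard":
            panel[rule.target] = discard(s, rule.years)
        elif rule.kind == "replace":
            panel[rule.target] = replace(s, panel[rule.params["source"]], rule.years)
        elif rule.kind == "scale":
            panel[rule.target] = scale(s, float(rule.params["factor"]), rule.years)
        after_missing = int(panel[rule.target].is_missing().sum())
        log.info(
            "rule %s on %s/%s: missing %d -> %d",
            rule.kind,
            panel[rule.target].country,
            rule.target,
            before_missing,
            after_missing,
        )
    return panel


def load_example_rules() -> dict[str, list[dict]]:
    """The shipped example country rule configs (illustrative, editable)."""
    path = resources.files("nbudget.data").joinpath("example_country_rules.yaml")
    with resources.as_file(path) as p, open(p) as fh:
        return yaml.safe_load(fh)
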