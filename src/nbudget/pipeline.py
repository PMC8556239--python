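"""Pipeline orchestration: crops -> fodder -> land -> fertilizer -> manure
-> fixation/deposition -> budget.

Each stage is a pure function on in-memory inputs (:class:`PipelineInputs`)
so the same code path serves the file-driven ``build`` command and the
synthetic-data generator's construction of ground truth.  All inputs are
tidy CSVs; all randomness lives in the generator, never here, so a rebuild
on the same inputs is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .bnf import BnfParams, bnf as bnf_fn, deposition_to_cropland, legume_n_harvest
from . import budget as budget_mod
from . import crops as crops_mod
from . import fertilizer as fert_mod
from . import fodder as fodder_mod
from . import gapfill
from . import land as land_mod
from . import manure as manure_mod
from .panel import PanelSeries, read_panel, write_panel, year_index
from .registry import (
    CATEGORIES,
    FODDER_CODE_CATEGORY,
    FODDER_N_CONTENT,
    NON_FODDER_CATEGORIES,
    CropRegistry,
)

log = logging.getLogger(__name__)

FODDER_CROPS = tuple(FODDER_CODE_CATEGORY)  # G1000..R9000
BNF_SOURCES = ("G1000", "G2100", "G2900", "G9000", "Pulses")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineInputs:
    """In-memory inputs to the stage functions (one value grid per country)."""

    countries: list[str]
    years: Mapping[str, pd.Index]  # per-country year grid
    crops: pd.DataFrame  # country, year, crop, area, production
    registry: CropRegistry
    n_contents: Mapping[str, float]  # crop -> % N of fresh production
    fodder_areas: Mapping[str, Mapping[str, PanelSeries]]  # country -> var -> series
    fodder_rules: Mapping[str, list]  # country -> rule dicts
    yield_obs: pd.DataFrame  # country, crop, year, value, basis
    land: Mapping[tuple[str, str], PanelSeries]
    fert_total: Mapping[tuple[str, str], PanelSeries]
    fert_obs: pd.DataFrame  # country, year, land_category, R, Q, A, source
    excretion: pd.DataFrame  # country, year, class, value
    mms_shares: pd.DataFrame  # country, year, livestock_class, system, share, weight
    loss_shares: pd.DataFrame  # country, class, loss_share
    alloc_shares: pd.DataFrame  # country, class, system, grass_share
    deposition: Mapping[tuple[str, str], PanelSeries]
    bnf_params: pd.DataFrame
    config: dict = field(default_factory=dict)


def _sum_series(series_list: list[pd.Series]) -> pd.Series:
    """Deterministic left-to-right sum of aligned series."""
    if not series_list:
        raise ValueError("empty series list")
    out = series_list[0].copy()
    for s in series_list[1:]:
        out = out + s
    return out


# ---------------------------------------------------------------------------
# Stage 1: non-fodder crop categories


def stage_crops(inputs: PipelineInputs) -> pd.DataFrame:
    """Aggregate crop records to the 12 non-fodder categories."""
    try:
        return crops_mod.aggregate_panel(
            inputs.crops, inputs.registry, inputs.n_contents
        )
    except Exception as exc:  # pragma: no cover - wrapped for stage naming
        raise StageError(f"crops stage failed: {exc}") from exc


# ---------------------------------------------------------------------------
# Stage 2: fodder crops


def stage_fodder(
    inputs: PipelineInputs,
) -> tuple[dict[str, dict[str, PanelSeries]], dict[str, dict[str, PanelSeries]], dict[tuple[str, str], fodder_mod.YieldModel]]:
    """Gap-fill fodder areas, fit yield models, compute N and DM harvests.

    Returns (areas, harvests, models): per-country per-crop area series,
    per-country dict of N-harvest and DM-harvest series (keys
    ``n.<crop>`` / ``dm.<crop>``), and the yield models used.
    """
    fcfg = inputs.config.get("fodder", {})
    anchor = float(fcfg.get("anchor", fodder_mod.TREND_ANCHOR))
    inflation = float(fcfg.get("inflation", fodder_mod.GRAZING_INFLATION))
    donors_cfg = fcfg.get("donors", {})

    areas: dict[str, dict[str, PanelSeries]] = {}
    for country in inputs.countries:
        panel = {k: v.copy() for k, v in inputs.fodder_areas.get(country, {}).items()}
        rules = inputs.fodder_rules.get(country, [])
        panel = gapfill.apply_rules(panel, rules)
        per_crop: dict[str, PanelSeries] = {}
        for crop in FODDER_CROPS:
            var = f"area.{crop}"
            if var not in panel:
                continue
            s = panel[var]
            if s.values.notna().any():
                s = gapfill.interpolate_linear(s)
                s = gapfill.extrapolate_const(s, "both")
            per_crop[crop] = s
        areas[country] = per_crop

    # reference yields per (country, crop)
    models: dict[tuple[str, str], fodder_mod.YieldModel] = {}
    obs_by = {}
    for row in inputs.yield_obs.itertuples():
        obs_by.setdefault((row.country, row.crop), []).append(
            fodder_mod.YieldObservation(
                row.country,
                row.crop,
                int(row.year),
                float(row.value),
                fodder_mod.HumidityBasis.parse(row.basis),
            )
        )
    for country in inputs.countries:
        for crop in FODDER_CROPS:
            if crop not in areas.get(country, {}):
                continue
            key = (country, crop)
            if key in obs_by:
                y2010 = fodder_mod.reference_yield(obs_by[key])
                models[key] = fodder_mod.YieldModel(
                    crop=crop,
                    country=country,
                    y2010=y2010,
                    anchor=anchor,
                    inflation=inflation,
                )
    for country in inputs.countries:
        for crop in FODDER_CROPS:
            key = (country, crop)
            if key in models or crop not in areas.get(country, {}):
                continue
            spec = donors_cfg.get(country, {}).get(crop)
            if spec is None:
                raise StageError(
                    f"fodder stage failed: no yield data or donors for "
                    f"{country}/{crop}"
                )
            donor_models = [models[(d, crop)] for d in spec["from"]]
            models[key] = fodder_mod.donor_yield(
                donor_models, country, crop, spec.get("kind", "average")
            )

    harvests: dict[str, dict[str, PanelSeries]] = {}
    for country in inputs.countries:
        idx = inputs.years[country]
        per: dict[str, PanelSeries] = {}
        for crop, area in areas[country].items():
            model = models[(country, crop)]
            dm_yield = pd.Series(
                [fodder_mod.yield_at(model, int(y)) for y in idx], index=idx
            )
            nc = FODDER_N_CONTENT[crop]
            n_vals = pd.Series(
                [
                    fodder_mod.fodder_n_harvest(a, y, nc)
                    if np.isfinite(a)
                    else np.nan
                    for a, y in zip(area.values.reindex(idx), dm_yield)
                ],
                index=idx,
            )
            dm_vals = area.values.reindex(idx) * dm_yield
            per[f"n.{crop}"] = PanelSeries(country, f"n_harvest.{crop}", "Gg N/yr", n_vals)
            per[f"dm.{crop}"] = PanelSeries(
                country, f"dm_harvest.{crop}", "Gg N/yr", dm_vals
            )  # carries Gg DM/yr; unit tag reused for plumbing
            per[f"y.{crop}"] = PanelSeries(
                country, f"dm_yield.{crop}", "dimensionless", dm_yield
            )
        harvests[country] = per
    return areas, harvests, models


# ---------------------------------------------------------------------------
# Category-level series assembly


def category_tables(
    inputs: PipelineInputs,
    aggregates: pd.DataFrame,
    fodder_areas: dict[str, dict[str, PanelSeries]],
    fodder_harvests: dict[str, dict[str, PanelSeries]],
) -> tuple[dict[str, dict[str, PanelSeries]], dict[str, dict[str, PanelSeries]]]:
    """Per-country {category: series} for areas (kha) and N harvests."""
    area_out: dict[str, dict[str, PanelSeries]] = {}
    harv_out: dict[str, dict[str, PanelSeries]] = {}
    for country in inputs.countries:
        idx = inputs.years[country]
        a = crops_mod.category_series(aggregates, country, "a_est", "kha", years=idx)
        h = crops_mod.category_series(aggregates, country, "h_sum", "Gg N/yr", years=idx)
        overrides = inputs.config.get("category_rules", {}).get(country, [])
        if overrides:
            a = crops_mod.apply_category_overrides(
                {k: v for k, v in a.items()}, overrides
            )
        a = crops_mod.zero_fill_missing_categories(
            a, NON_FODDER_CATEGORIES, country, "a_est", "kha", years=idx
        )
        h = crops_mod.zero_fill_missing_categories(
            h, NON_FODDER_CATEGORIES, country, "h_sum", "Gg N/yr", years=idx
        )
        # fodder categories: sum member crops (G2100+G2900 merge)
        for cat in CATEGORIES:
            if cat in NON_FODDER_CATEGORIES:
                continue
            members = [c for c in FODDER_CROPS if FODDER_CODE_CATEGORY[c] == cat]
            a_parts = [
                fodder_areas[country][m].values.reindex(idx)
                for m in members
                if m in fodder_areas[country]
            ]
            h_parts = [
                fodder_harvests[country][f"n.{m}"].values.reindex(idx)
                for m in members
                if f"n.{m}" in fodder_harvests[country]
            ]
            if a_parts:
                a[cat] = PanelSeries(country, f"area.{cat}", "kha", _sum_series(a_parts))
            else:
                a[cat] = PanelSeries(
                    country, f"area.{cat}", "kha", pd.Series(0.0, index=idx)
                )
            if h_parts:
                h[cat] = PanelSeries(
                    country, f"n_harvest.{cat}", "Gg N/yr", _sum_series(h_parts)
                )
            else:
                h[cat] = PanelSeries(
                    country, f"n_harvest.{cat}", "Gg N/yr", pd.Series(0.0, index=idx)
                )
        area_out[country] = a
        harv_out[country] = h
    return area_out, harv_out


def total_over_categories(
    per_category: Mapping[str, PanelSeries],
    country: str,
    variable: str,
    unit: str,
) -> PanelSeries:
    """Sum category series in the fixed category order (deterministic)."""
    parts = [per_category[c].values for c in CATEGORIES if c in per_category]
    return PanelSeries(country, variable, unit, _sum_series(parts))


# ---------------------------------------------------------------------------
# Stage 3: land


def stage_land(
    inputs: PipelineInputs,
    category_areas: dict[str, dict[str, PanelSeries]],
    fodder_areas: dict[str, dict[str, PanelSeries]],
) -> dict[str, dict[str, PanelSeries]]:
    """Crop area sum, cropland in use, grassland areas per country."""
    out: dict[str, dict[str, PanelSeries]] = {}
    for country in inputs.countries:
        idx = inputs.years[country]
        crop_sum = total_over_categories(
            category_areas[country], country, "crop_area_sum", "kha"
        )
        reported = inputs.land.get((country, "cropland_reported"))
        if reported is None:
            raise StageError(f"land stage failed: no reported cropland for {country}")
        in_use, flags = land_mod.cropland_in_use_series(crop_sum, reported)
        a_pg = inputs.land.get((country, "permanent_grassland"))
        if a_pg is None:
            raise StageError(
                f"land stage failed: no permanent grassland for {country}"
            )
        if country in fodder_areas and "G1000" in fodder_areas[country]:
            a_tg = fodder_areas[country]["G1000"]
            a_tg = PanelSeries(country, "temporary_grassland", "kha", a_tg.values)
        else:
            a_tg = PanelSeries(
                country, "temporary_grassland", "kha", pd.Series(0.0, index=idx)
            )
        out[country] = {
            "crop_area_sum": crop_sum,
            "cropland_reported": reported,
            "cropland_in_use": in_use,
            "permanent_grassland": a_pg,
            "temporary_grassland": a_tg,
        }
    return out


# ---------------------------------------------------------------------------
# Stage 4: synthetic fertilizer allocation


def stage_fertilizer(
    inputs: PipelineInputs,
    land: dict[str, dict[str, PanelSeries]],
) -> pd.DataFrame:
    """Rate-ratio estimation, gap-fill, share and quantity allocation."""
    fcfg = inputs.config.get("fert", {})
    k_map = fcfg.get("k", {})
    zero_pg = set(fcfg.get("zero_pg", []))
    kept, _excluded = fert_mod.screen_observations(
        [
            fert_mod.FertObservation(
                r.country,
                int(r.year),
                r.land_category,
                None if pd.isna(r.R) else float(r.R),
                None if pd.isna(r.Q) else float(r.Q),
                None if pd.isna(r.A) else float(r.A),
                str(getattr(r, "source", "")),
            )
            for r in inputs.fert_obs.itertuples()
        ]
    )
    obs_by: dict[tuple[str, int], list[fert_mod.FertObservation]] = {}
    for o in kept:
        obs_by.setdefault((o.country, o.year), []).append(o)

    rows = []
    for country in inputs.countries:
        idx = inputs.years[country]
        q_tot_series = inputs.fert_total.get((country, "fert_total"))
        k = float(k_map.get(country, 1.0))
        if country in zero_pg:
            ratio_series = fert_mod.zero_pg_series(idx, country)
        else:
            points = []
            for year in idx:
                obs = obs_by.get((country, int(year)))
                if not obs:
                    continue
                a_pg = land[country]["permanent_grassland"].values.get(year, np.nan)
                a_tg = land[country]["temporary_grassland"].values.get(year, np.nan)
                a_c = land[country]["cropland_reported"].values.get(year, np.nan)
                q_tot = (
                    q_tot_series.values.get(year, np.nan)
                    if q_tot_series is not None
                    else np.nan
                )
                est = fert_mod.estimate_rate_ratio(
                    obs,
                    a_pg=float(a_pg) if np.isfinite(a_pg) else 0.0,
                    a_tg=float(a_tg) if np.isfinite(a_tg) else 0.0,
                    a_c=float(a_c) if np.isfinite(a_c) else 0.0,
                    q_tot=float(q_tot) if np.isfinite(q_tot) else None,
                    k=k,
                )
                if est is not None:
                    points.append((int(year), est[0], est[1]))
            if not points:
                raise StageError(
                    f"fertilizer stage failed: no rate-ratio estimates for "
                    f"{country} (not in the zero-PG list)"
                )
            ratio_series = fert_mod.build_rate_ratio_series(
                points, idx, country, k=k
            )
        for year in idx:
            ratio = ratio_series.values.get(year, np.nan)
            a_pg = land[country]["permanent_grassland"].values.get(year, np.nan)
            a_c = land[country]["cropland_reported"].values.get(year, np.nan)
            q_tot = (
                q_tot_series.values.get(year, np.nan)
                if q_tot_series is not None
                else np.nan
            )
            if not (np.isfinite(ratio) and np.isfinite(a_pg) and np.isfinite(a_c)):
                continue
            share = fert_mod.share_to_cropland(float(ratio), float(a_pg), float(a_c))
            if np.isfinite(q_tot):
                q_c, q_pg = fert_mod.allocate_quantities(float(q_tot), share)
            else:
                q_c = q_pg = np.nan
            rows.append(
                {
                    "country": country,
                    "year": int(year),
                    "rate_ratio": float(ratio),
                    "share_cropland": share,
                    "provenance": ratio_series.provenance.get(year, ""),
                    "q_tot": float(q_tot) if np.isfinite(q_tot) else np.nan,
                    "q_c": q_c,
                    "q_pg": q_pg,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage 5: manure


def stage_manure(
    inputs: PipelineInputs,
    land: dict[str, dict[str, PanelSeries]],
) -> pd.DataFrame:
    """Manure flow chain per country-year-class."""
    mcfg = inputs.config.get("manure", {})
    window = tuple(mcfg.get("window", manure_mod.MMS_WEIGHT_WINDOW))
    threshold = float(mcfg.get("other_threshold", manure_mod.OTHER_SHARE_THRESHOLD))
    alloc_donors = mcfg.get("alloc_donors", {})
    ls_overrides = mcfg.get("liquid_solid_overrides", {})

    loss = {
        (r.country, r.livestock_class): float(r.loss_share)
        for r in inputs.loss_shares.itertuples()
    }
    alloc: dict[tuple[str, str], dict[str, float]] = {}
    for r in inputs.alloc_shares.itertuples():
        alloc.setdefault((r.country, r.livestock_class), {})[r.system] = float(
            r.grass_share
        )

    rows = []
    for country in inputs.countries:
        idx = inputs.years[country]
        mshares = inputs.mms_shares[inputs.mms_shares["country"] == country]
        if mshares.empty:
            raise StageError(f"manure stage failed: no MMS shares for {country}")
        # aggregate detailed (class, system) shares per observed year
        simplified: dict[str, dict[int, dict[str, float]]] = {}
        for year, grp in mshares.groupby("year"):
            raw = {
                (r.livestock_class, r.system): float(r.share) for r in grp.itertuples()
            }
            weights = {r.livestock_class: float(r.weight) for r in grp.itertuples()}
            agg = manure_mod.aggregate_mms(
                raw, country, int(year), excretion_weights=weights
            )
            for cls, ms in agg.items():
                simplified.setdefault(cls, {})[int(year)] = ms.shares
        exc = inputs.excretion[inputs.excretion["country"] == country]
        exc_by = {
            (r.livestock_class, int(r.year)): float(r.value) for r in exc.itertuples()
        }
        for cls in manure_mod.SIMPLIFIED_CLASSES:
            if cls not in simplified:
                continue
            table = pd.DataFrame.from_dict(simplified[cls], orient="index").sort_index()
            table.index.name = "year"
            filled = manure_mod.backfill_shares(table, idx)
            alloc_country = country
            if (country, cls) not in alloc and country in alloc_donors:
                alloc_country = alloc_donors[country]
            try:
                alloc_shares = alloc[(alloc_country, cls)]
            except KeyError:
                raise StageError(
                    f"manure stage failed: no land-allocation share for "
                    f"{country}/{cls} and no donor configured"
                )
            if cls == "poultry_rabbits" or "all" in alloc_shares:
                liquid_weight = None
            else:
                override = ls_overrides.get(country, {}).get(cls)
                window_years = [y for y in filled.index if window[0] <= y <= window[1]]
                liqs = [
                    manure_mod.liquid_solid_shares(
                        filled.loc[y].to_dict(),
                        other_threshold=threshold,
                        override=tuple(override) if override else None,
                    )[0]
                    for y in window_years
                ]
                liquid_weight = sum(liqs) / len(liqs)
            grass_share = manure_mod.effective_grass_share(
                cls, alloc_shares, liquid_weight
            )
            loss_share = loss.get((country, cls), manure_mod.GENERIC_LOSS_SHARE)
            for year in idx:
                total = exc_by.get((cls, int(year)))
                if total is None:
                    continue
                a_pg = land[country]["permanent_grassland"].values.get(year, np.nan)
                a_tg = land[country]["temporary_grassland"].values.get(year, np.nan)
                flows = manure_mod.chain(
                    country,
                    int(year),
                    cls,
                    total,
                    filled.loc[int(year)].to_dict(),
                    loss_share,
                    grass_share,
                    float(a_pg) if np.isfinite(a_pg) else 0.0,
                    float(a_tg) if np.isfinite(a_tg) else 0.0,
                )
                rows.append(vars(flows).copy())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage 6: fixation and deposition


def stage_bnf(
    inputs: PipelineInputs,
    fodder_harvests: dict[str, dict[str, PanelSeries]],
    category_harvests: dict[str, dict[str, PanelSeries]],
) -> pd.DataFrame:
    """Symbiotic fixation per source crop/category and country-year."""
    params = {}
    for r in inputs.bnf_params.itertuples():
        params[r.crop] = BnfParams(
            r.crop,
            float(r.ndfa),
            float(r.bgn),
            float(r.nhi),
            float(r.legume_dm_share),
            None if pd.isna(r.legume_n_content) else float(r.legume_n_content),
        )
    rows = []
    for country in inputs.countries:
        idx = inputs.years[country]
        for source in BNF_SOURCES:
            if source not in params:
                continue
            p = params[source]
            if source == "Pulses":
                h = category_harvests[country].get("Pulses")
                if h is None:
                    continue
                y_series = h.values.reindex(idx)
            else:
                key = f"dm.{source}"
                if key not in fodder_harvests[country]:
                    continue
                dm = fodder_harvests[country][key].values.reindex(idx)
                y_series = pd.Series(
                    [
                        legume_n_harvest(v, p) if np.isfinite(v) else np.nan
                        for v in dm
                    ],
                    index=idx,
                )
            for year in idx:
                y = y_series.get(year, np.nan)
                if not np.isfinite(y):
                    continue
                rows.append(
                    {
                        "country": country,
                        "year": int(year),
                        "source": source,
                        "bnf": bnf_fn(float(y), p),
                    }
                )
    return pd.DataFrame(rows)


def bnf_total_series(
    bnf_table: pd.DataFrame, country: str, years: pd.Index
) -> PanelSeries:
    """Total fixation per year, summed over sources in fixed order."""
    vals = pd.Series(0.0, index=years)
    present = pd.Series(False, index=years)
    sub = bnf_table[bnf_table["country"] == country]
    for source in BNF_SOURCES:
        s = sub[sub["source"] == source].set_index("year")["bnf"]
        s = s.reindex(years)
        mask = s.notna()
        vals[mask] = vals[mask] + s[mask]
        present |= mask
    vals[~present] = np.nan
    return PanelSeries(country, "bnf_total", "Gg N/yr", vals)


def stage_deposition(
    inputs: PipelineInputs, land: dict[str, dict[str, PanelSeries]]
) -> dict[str, PanelSeries]:
    out = {}
    for country in inputs.countries:
        rate = inputs.deposition.get((country, "deposition_rate"))
        if rate is None:
            raise StageError(f"deposition stage failed: no rates for {country}")
        out[country] = deposition_to_cropland(
            rate, land[country]["cropland_in_use"]
        )
    return out


# ---------------------------------------------------------------------------
# Stage 7: budget assembly


def stage_budget(
    inputs: PipelineInputs,
    category_harvests: dict[str, dict[str, PanelSeries]],
    fert: pd.DataFrame,
    manure_flows: pd.DataFrame,
    bnf_table: pd.DataFrame,
    deposition: dict[str, PanelSeries],
    land: dict[str, dict[str, PanelSeries]],
) -> pd.DataFrame:
    frames = []
    for country in inputs.countries:
        idx = inputs.years[country]
        harvest = total_over_categories(
            category_harvests[country], country, "harvest_n", "Gg N/yr"
        )
        fsub = fert[fert["country"] == country].set_index("year")
        fert_c = PanelSeries(
            country, "fert_c", "Gg N/yr", fsub["q_c"].reindex(idx)
        )
        msub = manure_flows[manure_flows["country"] == country]
        manure_c_vals = pd.Series(np.nan, index=idx)
        for year, grp in msub.groupby("year"):
            parts = [
                float(grp[grp["livestock_class"] == cls]["to_cropland"].iloc[0])
                for cls in manure_mod.SIMPLIFIED_CLASSES
                if (grp["livestock_class"] == cls).any()
            ]
            total = parts[0]
            for p in parts[1:]:
                total += p
            manure_c_vals.loc[int(year)] = total
        manure_c = PanelSeries(country, "manure_c", "Gg N/yr", manure_c_vals)
        bnf_total = bnf_total_series(bnf_table, country, idx)
        frames.append(
            budget_mod.assemble_budget(
                harvest,
                fert_c,
                manure_c,
                bnf_total,
                deposition[country],
                land[country]["cropland_in_use"],
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Full run


def run_stages(inputs: PipelineInputs) -> dict:
    """Run all stages in order; returns a dict of result tables/series."""
    aggregates = stage_crops(inputs)
    fodder_areas, fodder_harvests, models = stage_fodder(inputs)
    category_areas, category_harvests = category_tables(
        inputs, aggregates, fodder_areas, fodder_harvests
    )
    land = stage_land(inputs, category_areas, fodder_areas)
    fert = stage_fertilizer(inputs, land)
    manure_flows = stage_manure(inputs, land)
    bnf_table = stage_bnf(inputs, fodder_harvests, category_harvests)
    deposition = stage_deposition(inputs, land)
    budget = stage_budget(
        inputs, category_harvests, fert, manure_flows, bnf_table, deposition, land
    )
    return {
        "aggregates": aggregates,
        "fodder_areas": fodder_areas,
        "fodder_harvests": fodder_harvests,
        "yield_models": models,
        "category_areas": category_areas,
        "category_harvests": category_harvests,
        "land": land,
        "fert": fert,
        "manure_flows": manure_flows,
        "bnf": bnf_table,
        "deposition": deposition,
        "budget": budget,
    }


# ---------------------------------------------------------------------------
# File IO


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _country_grids(config: dict) -> tuple[list[str], dict[str, pd.Index]]:
    ycfg = config.get("years", {})
    start, end = int(ycfg.get("start", 1961)), int(ycfg.get("end", 2019))
    countries = list(config["countries"])
    overrides = {c: int(y) for c, y in ycfg.get("start_overrides", {}).items()}
    grids = {
        c: year_index(range(overrides.get(c, start), end + 1)) for c in countries
    }
    return countries, grids


def load_inputs(config: dict, base_dir: str | Path) -> PipelineInputs:
    """Read all input files referenced by the config into PipelineInputs."""
    base = Path(base_dir)
    paths = {k: base / v for k, v in config["inputs"].items()}
    countries, grids = _country_grids(config)
    grid_ranges = {c: list(grids[c]) for c in countries}

    reg_df = pd.read_csv(paths["crop_registry"], float_precision="round_trip")
    registry = CropRegistry.from_csv(paths["crop_registry"])
    n_contents = dict(zip(reg_df["crop"], reg_df["n_content"].astype(float)))

    crops = pd.read_csv(paths["crops"], float_precision="round_trip")
    fodder_panel = read_panel(paths["fodder_areas"], country_years=grid_ranges)
    fodder_areas: dict[str, dict[str, PanelSeries]] = {}
    for (country, var), s in fodder_panel.items():
        fodder_areas.setdefault(country, {})[var] = s
    with open(paths["fodder_rules"]) as fh:
        fodder_rules = yaml.safe_load(fh) or {}

    yield_obs = pd.read_csv(paths["fodder_yield_obs"], float_precision="round_trip")
    land = read_panel(paths["land"], country_years=grid_ranges)
    fert_total = read_panel(paths["fert_total"], country_years=grid_ranges)
    fert_obs = pd.read_csv(paths["fert_obs"], float_precision="round_trip")
    excretion = pd.read_csv(paths["excretion"], float_precision="round_trip")
    mms = pd.read_csv(paths["mms_shares"], float_precision="round_trip")
    loss = pd.read_csv(paths["loss_shares"], float_precision="round_trip")
    alloc = pd.read_csv(paths["alloc_shares"], float_precision="round_trip")
    deposition = read_panel(paths["deposition"], country_years=grid_ranges)
    bnf_params = pd.read_csv(paths["bnf_params"], float_precision="round_trip")

    return PipelineInputs(
        countries=countries,
        years=grids,
        crops=crops,
        registry=registry,
        n_contents=n_contents,
        fodder_areas=fodder_areas,
        fodder_rules=fodder_rules,
        yield_obs=yield_obs,
        land=land,
        fert_total=fert_total,
        fert_obs=fert_obs,
        excretion=excretion,
        mms_shares=mms,
        loss_shares=loss,
        alloc_shares=alloc,
        deposition=deposition,
        bnf_params=bnf_params,
        config=config,
    )


def write_outputs(results: dict, outdir: str | Path) -> None:
    """Write the stage results as tidy/wide CSVs into ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results["budget"].to_csv(out / "budget.csv", index=False)
    results["fert"].to_csv(out / "fert_allocation.csv", index=False)
    results["manure_flows"].to_csv(out / "manure_flows.csv", index=False)
    results["bnf"].to_csv(out / "bnf.csv", index=False)
    land_series = []
    for country, d in results["land"].items():
        for name, s in d.items():
            land_series.append(PanelSeries(country, name, "kha", s.values))
    write_panel(land_series, out / "land_areas.csv")
    dep_series = list(results["deposition"].values())
    write_panel(dep_series, out / "deposition_to_cropland.csv")
    cat_series = []
    for country, d in results["category_areas"].items():
        for cat, s in d.items():
            cat_series.append(PanelSeries(country, f"area.{cat}", "kha", s.values))
    for country, d in results["category_harvests"].items():
        for cat, s in d.items():
            cat_series.append(
                PanelSeries(country, f"n_harvest.{cat}", "Gg N/yr", s.values)
            )
    write_panel(cat_series, out / "crop_categories.csv")


def run_build(config_path: str | Path, outdir: str | Path) -> dict:
    """File-driven build: read inputs, run all stages, write outputs."""
    config = load_config(config_path)
    inputs = load_inputs(config, Path(config_path).parent)
    results = run_stages(inputs)
    write_outputs(results, outdir)
    return results


# ---------------------------------------------------------------------------
# Validation report


def validate_outputs(outdir: str | Path, tol: float = 1e-9) -> pd.DataFrame:
    """Re-check the core identities on the written outputs.

    Returns a report with one row per check: name, n checked, n failed.
    """
    out = Path(outdir)
    rows = []

    def record(name: str, n: int, failed: int, detail: str = "") -> None:
        rows.append(
            {
                "check": name,
                "n": n,
                "failed": failed,
                "passed": failed == 0,
                "detail": detail,
            }
        )

    budget_path = out / "budget.csv"
    if not budget_path.exists():
        record("outputs_present", 0, 1, "budget.csv missing")
        return pd.DataFrame(rows)
    b = pd.read_csv(budget_path, float_precision="round_trip")
    lhs = b["fert_c"] + b["manure_c"] + b["bnf"] + b["deposition_c"]
    record(
        "budget_input_total",
        len(b),
        int((lhs != b["input_total"]).sum()),
    )
    record(
        "budget_surplus",
        len(b),
        int(((b["input_total"] - b["harvest_n"]) != b["surplus"]).sum()),
    )
    f = pd.read_csv(out / "fert_allocation.csv", float_precision="round_trip")
    fq = f.dropna(subset=["q_tot"])
    # residual-direction identity: Q_PG was constructed as Q_tot - Q_C
    record(
        "fert_conservation",
        len(fq),
        int(((fq["q_tot"] - fq["q_c"]) != fq["q_pg"]).sum()),
    )
    record(
        "fert_share_bounds",
        len(f),
        int(((f["share_cropland"] < 0) | (f["share_cropland"] > 1)).sum()),
    )
    m = pd.read_csv(out / "manure_flows.csv", float_precision="round_trip")
    # residual-direction identities (see ManureFlows.check)
    bad1 = (m["excreted_total"] - m["excreted_grazing"]) != m["excreted_housed"]
    bad2 = (
        (m["excreted_housed"] - m["lost_housing_storage"]) - m["applied_grass"]
    ) != m["applied_nongrass"]
    bad3 = (
        m["applied_nongrass"]
        + ((m["applied_grass"] + m["excreted_grazing"]) - m["to_permanent_grassland"])
    ) != m["to_cropland"]
    record("manure_excretion_split", len(m), int(bad1.sum()))
    record("manure_storage_balance", len(m), int(bad2.sum()))
    record("manure_land_balance", len(m), int(bad3.sum()))
    land = pd.read_csv(out / "land_areas.csv", float_precision="round_trip")
    piv = land.pivot_table(
        index=["country", "year"], columns="variable", values="value"
    )
    if {"crop_area_sum", "cropland_reported", "cropland_in_use"} <= set(piv.columns):
        expected = piv[["crop_area_sum", "cropland_reported"]].min(axis=1)
        ok = piv["cropland_in_use"].notna()
        record(
            "cropland_in_use_min",
            int(ok.sum()),
            int((np.abs(piv.loc[ok, "cropland_in_use"] - expected[ok]) > tol).sum()),
        )
    return pd.DataFrame(rows)
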