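"""Synthetic country panels: ground truth plus degraded observables.

The generator emulates the statistical structure of the real inputs —
crop panels with pre-1985 area gaps, fodder areas lumped into a single
"hay" aggregate before 1987 (as in the historical yearbooks of the
centrally planned economies), fodder yields reported on mixed humidity
bases, sparse fertilizer surveys, manure-management shares starting only
in 1990, and deposition rates ending in 2013 — without mimicking any real
file layout.  Ground truth is constructed by running the pipeline stages
on the complete, undegraded inputs, so it satisfies every conservation
invariant by construction; the observables are the same inputs after
seeded, deterministic degradation.  Every stage of the pipeline therefore
has a no-download recovery test: exact on undegraded inputs, within
stated tolerances on degraded ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import pipeline
from .panel import PanelSeries, write_panel, year_index
from .registry import CropRegistry, FODDER_N_CONTENT

HAY_COMPONENTS = ("G1000", "G2100", "G2900", "G9000")

#: Mock non-fodder registry: crop -> (category, % N of fresh production).
MOCK_CROPS = {
    "wheat": ("Wheat", 2.0),
    "barley": ("Barley", 1.8),
    "oats": ("Other cereals", 1.7),
    "rye": ("Other cereals", 1.6),
    "rapeseed": ("Oilseeds", 3.5),
    "sunflower": ("Oilseeds", 2.8),
    "field_peas": ("Pulses", 3.6),
    "faba_beans": ("Pulses", 4.1),
    "potatoes": ("Potatoes", 0.3),
    "sugar_beet": ("Sugar beet", 0.2),
}

#: Fixation parameters: legume DM shares and legume N contents follow the
#: accounting conventions (temporary grassland 25% legume at 3.3% N, pure
#: forage legumes 90% at 3.3% N, other green fodder 25% at 3.0% N, lucerne
#: treated as a pure stand, pulses harvested N used directly).  The
#: Ndfa/BGN/NHI values are synthetic placeholders of plausible magnitude,
#: not literature values.
DEFAULT_BNF_PARAMS = pd.DataFrame(
    [
        {"crop": "G1000", "ndfa": 0.80, "bgn": 1.40, "nhi": 0.90,
         "legume_dm_share": 0.25, "legume_n_content": 3.3},
        {"crop": "G2100", "ndfa": 0.80, "bgn": 1.40, "nhi": 0.90,
         "legume_dm_share": 1.00, "legume_n_content": 3.0},
        {"crop": "G2900", "ndfa": 0.80, "bgn": 1.40, "nhi": 0.90,
         "legume_dm_share": 0.90, "legume_n_content": 3.3},
        {"crop": "G9000", "ndfa": 0.80, "bgn": 1.40, "nhi": 0.90,
         "legume_dm_share": 0.25, "legume_n_content": 3.0},
        {"crop": "Pulses", "ndfa": 0.65, "bgn": 1.30, "nhi": 0.75,
         "legume_dm_share": 1.00, "legume_n_content": np.nan},
    ]
)

DETAILED_CLASSES = {
    "Cattle": "ruminants_equines",
    "Sheep": "ruminants_equines",
    "Swine": "pigs",
    "Poultry": "poultry_rabbits",
}


@dataclass
class DegradationSpec:
    """How the observables differ from the truth.

    Defaults are the moderate-degradation study scenario: 30% of pre-1985
    crop areas missing, fodder crops lumped into "hay" before 1987, yields
    reported on mixed humidity bases, fertilizer surveys every 5th year
    without noise, manure-management shares from 1990 on, deposition rates
    through 2013.
    """

    area_missing_rate: float = 0.3
    fodder_missing_rate: float = 0.15
    hay_lumping: bool = True
    mixed_humidity: bool = True
    survey_stride: int = 5
    survey_noise_sd: float = 0.0
    mms_start: int | None = 1990
    deposition_end: int | None = 2013

    @classmethod
    def none(cls) -> "DegradationSpec":
        return cls(0.0, 0.0, False, False, 1, 0.0, None, None)


@dataclass
class SynthConfig:
    seed: int = 0
    countries: tuple[str, ...] = ("AA", "BB", "CC", "DD")
    start: int = 1961
    end: int = 2019
    degradation: DegradationSpec = field(default_factory=DegradationSpec)
    zero_pg: tuple[str, ...] = ("DD",)
    k_map: dict = field(default_factory=lambda: {"CC": 1.5})
    eq5_countries: tuple[str, ...] = ("CC",)

    def __post_init__(self) -> None:
        if not self.countries or self.end < self.start:
            raise ValueError("degenerate config: need countries and a year span")


@dataclass
class SynthResult:
    config: SynthConfig
    truth_inputs: pipeline.PipelineInputs
    truth: dict
    obs_inputs: pipeline.PipelineInputs
    run_config: dict


def _quad(rng: np.random.Generator, base_lo, base_hi, g_lo, g_hi):
    """A smooth positive trend base*(1 + g*u + c*u^2) over u in [0, 1]."""
    base = rng.uniform(base_lo, base_hi)
    g = rng.uniform(g_lo, g_hi)
    c = rng.uniform(-0.15, 0.15)

    def f(u: float) -> float:
        return base * max(0.05, 1.0 + g * u + c * u * u)

    return f


def _mock_registry_frame() -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"crop": crop, "source": "faostat-like", "category": cat, "n_content": nc}
            for crop, (cat, nc) in MOCK_CROPS.items()
        ]
    )


def generate(config: SynthConfig) -> SynthResult:
    """Build truth and observables for the configured scenario.

    Deterministic: the same seed and config give bit-identical outputs.
    All random draws for the truth happen before any degradation draw, so
    the truth is invariant to the degradation settings.
    """
    rng = np.random.default_rng(config.seed)
    deg = config.degradation
    years = list(range(config.start, config.end + 1))
    idx = year_index(years)
    n_years = len(years)
    span = max(1, config.end - config.start)

    def u_of(year: int) -> float:
        return (year - config.start) / span

    registry_df = _mock_registry_frame()
    registry = CropRegistry.from_rows(
        [(r.crop, r.source, r.category) for r in registry_df.itertuples()]
    )
    n_contents = dict(zip(registry_df["crop"], registry_df["n_content"]))

    # ------------------------------------------------------------------ truth
    crop_rows = []
    fodder_true: dict[str, dict[str, PanelSeries]] = {}
    land_series: dict[tuple[str, str], PanelSeries] = {}
    fert_total: dict[tuple[str, str], PanelSeries] = {}
    fert_obs_full = []
    excretion_rows = []
    mms_rows_full = []
    loss_rows = []
    alloc_rows = []
    dep_series: dict[tuple[str, str], PanelSeries] = {}
    yield_obs_full = []
    y2010_map: dict[tuple[str, str], float] = {}
    ratio_curves: dict[str, dict] = {}

    for country in config.countries:
        # --- non-fodder crops
        for crop in MOCK_CROPS:
            area_f = _quad(rng, 50, 500, -0.4, 0.6)
            yield_f = _quad(rng, 2.0, 6.0, 0.3, 1.0)
            for year in years:
                u = u_of(year)
                area = area_f(u)
                production = area * yield_f(u)  # kha * t/ha = Gg fresh
                crop_rows.append(
                    {
                        "country": country,
                        "year": year,
                        "crop": crop,
                        "area": area,
                        "production": production,
                    }
                )

        # --- fodder areas: hay group shares constant before 1987
        hay_f = _quad(rng, 300, 1500, -0.5, 0.3)
        w = rng.uniform(0.5, 1.5, size=len(HAY_COMPONENTS))
        w = w / w.sum()
        drift = rng.uniform(-0.3, 0.3, size=len(HAY_COMPONENTS))
        comp_vals: dict[str, list[float]] = {c: [] for c in HAY_COMPONENTS}
        for year in years:
            u = u_of(year)
            hay = hay_f(u)
            if year <= 1987:
                s = w
            else:
                v = max(0.0, (year - 1987) / (config.end - 1987))
                s = w * (1.0 + drift * v)
                s = s / s.sum()
            for j, comp in enumerate(HAY_COMPONENTS):
                comp_vals[comp].append(hay * s[j])
        per_country: dict[str, PanelSeries] = {}
        for comp in HAY_COMPONENTS:
            per_country[f"area.{comp}"] = PanelSeries(
                country, f"area.{comp}", "kha", pd.Series(comp_vals[comp], index=idx)
            )
        for crop, lo, hi in (("G3000", 50, 400), ("R9000", 20, 150)):
            f = _quad(rng, lo, hi, -0.6, 0.4)
            per_country[f"area.{crop}"] = PanelSeries(
                country,
                f"area.{crop}",
                "kha",
                pd.Series([f(u_of(y)) for y in years], index=idx),
            )
        fodder_true[country] = per_country

        # --- fodder reference yields (mowing basis, t DM/ha in 2010)
        ranges = {
            "G1000": (4, 7),
            "G2100": (6, 10),
            "G2900": (5, 9),
            "G3000": (8, 14),
            "G9000": (4, 7),
            "R9000": (8, 12),
        }
        for crop, (lo, hi) in ranges.items():
            y2010_map[(country, crop)] = rng.uniform(lo, hi)

        # --- land: reported cropland above the crop-area sum, PG independent
        direct_sum = np.zeros(n_years)
        for row in crop_rows:
            if row["country"] == country:
                direct_sum[row["year"] - config.start] += row["area"]
        for s in per_country.values():
            direct_sum += s.values.to_numpy()
        factor0 = rng.uniform(1.02, 1.12)
        factor1 = rng.uniform(-0.03, 0.03)
        reported = direct_sum * (factor0 + factor1 * np.array([u_of(y) for y in years]))
        pg_f = _quad(rng, 800, 3000, -0.3, 0.3)
        a_pg = np.array([pg_f(u_of(y)) for y in years])
        land_series[(country, "cropland_reported")] = PanelSeries(
            country, "cropland_reported", "kha", pd.Series(reported, index=idx)
        )
        land_series[(country, "permanent_grassland")] = PanelSeries(
            country, "permanent_grassland", "kha", pd.Series(a_pg, index=idx)
        )
        land_series[(country, "fallow")] = PanelSeries(
            country,
            "fallow",
            "kha",
            pd.Series(np.maximum(reported - direct_sum, 0.0), index=idx),
        )

        # --- fertilizer: rates, smooth declining rate ratio, consumption
        rc0, rc1 = rng.uniform(15, 40), rng.uniform(80, 160)
        r0, r_inf = rng.uniform(0.5, 0.9), rng.uniform(0.05, 0.2)
        ratio_curves[country] = {"rc0": rc0, "rc1": rc1, "r0": r0, "r_inf": r_inf}
        k = float(config.k_map.get(country, 1.0))
        q_tot = np.zeros(n_years)
        a_tg = per_country["area.G1000"].values.to_numpy()
        for i, year in enumerate(years):
            u = u_of(year)
            r_c = rc0 + (rc1 - rc0) * u
            if country in config.zero_pg:
                ratio = 0.0
            else:
                ratio = r_inf + (r0 - r_inf) * np.exp(-(year - config.start) / 30.0)
            r_pg = ratio * r_c
            q_tot[i] = (r_c * reported[i] + r_pg * a_pg[i]) / 1000.0
            if country in config.zero_pg:
                continue
            if country in config.eq5_countries:
                r_tg = k * r_pg
                a_c = reported[i]
                a_c_minus_tg = a_c - a_tg[i]
                r_c_minus_tg = (r_c * a_c - r_tg * a_tg[i]) / a_c_minus_tg
                r_pg_plus_tg = (r_pg * a_pg[i] + r_tg * a_tg[i]) / (a_pg[i] + a_tg[i])
                fert_obs_full.append(
                    {
                        "country": country,
                        "year": year,
                        "land_category": "PG+TG",
                        "R": r_pg_plus_tg,
                        "Q": np.nan,
                        "A": np.nan,
                        "source": "synthetic-survey",
                    }
                )
                fert_obs_full.append(
                    {
                        "country": country,
                        "year": year,
                        "land_category": "C-TG",
                        "R": r_c_minus_tg,
                        "Q": np.nan,
                        "A": np.nan,
                        "source": "synthetic-survey",
                    }
                )
            else:
                fert_obs_full.append(
                    {
                        "country": country,
                        "year": year,
                        "land_category": "C",
                        "R": r_c,
                        "Q": r_c * reported[i] / 1000.0,
                        "A": reported[i],
                        "source": "synthetic-survey",
                    }
                )
                fert_obs_full.append(
                    {
                        "country": country,
                        "year": year,
                        "land_category": "PG",
                        "R": r_pg,
                        "Q": r_pg * a_pg[i] / 1000.0,
                        "A": a_pg[i],
                        "source": "synthetic-survey",
                    }
                )
        fert_total[(country, "fert_total")] = PanelSeries(
            country, "fert_total", "Gg N/yr", pd.Series(q_tot, index=idx)
        )

        # --- manure: excretion, detailed MMS shares, losses, allocations
        exc_ranges = {
            "ruminants_equines": (50, 150),
            "pigs": (20, 80),
            "poultry_rabbits": (10, 40),
        }
        for cls, (lo, hi) in exc_ranges.items():
            f = _quad(rng, lo, hi, -0.3, 0.5)
            for year in years:
                excretion_rows.append(
                    {
                        "country": country,
                        "year": year,
                        "livestock_class": cls,
                        "value": f(u_of(year)),
                    }
                )
            loss_rows.append(
                {
                    "country": country,
                    "livestock_class": cls,
                    "loss_share": rng.uniform(0.15, 0.35),
                }
            )
        alloc_rows.extend(
            [
                {"country": country, "livestock_class": "ruminants_equines",
                 "system": "liquid", "grass_share": rng.uniform(0.4, 0.7)},
                {"country": country, "livestock_class": "ruminants_equines",
                 "system": "solid", "grass_share": rng.uniform(0.2, 0.5)},
                {"country": country, "livestock_class": "pigs",
                 "system": "liquid", "grass_share": rng.uniform(0.1, 0.4)},
                {"country": country, "livestock_class": "pigs",
                 "system": "solid", "grass_share": rng.uniform(0.05, 0.3)},
                {"country": country, "livestock_class": "poultry_rabbits",
                 "system": "all", "grass_share": rng.uniform(0.02, 0.15)},
            ]
        )
        cattle_weight = rng.uniform(0.6, 0.9)
        mms_params = {}
        for detailed in DETAILED_CLASSES:
            mms_params[detailed] = {
                "g0": rng.uniform(0.15, 0.40),
                "g1": rng.uniform(0.10, 0.35),
                "other": rng.uniform(0.02, 0.10),
                "l0": rng.uniform(0.3, 0.6),
                "l1": rng.uniform(0.4, 0.8),
            }
        mms_era = (1990, 2018)
        for year in years:
            v = min(1.0, max(0.0, (year - mms_era[0]) / (mms_era[1] - mms_era[0])))
            for detailed, p in mms_params.items():
                g = p["g0"] + (p["g1"] - p["g0"]) * v
                rest = 1.0 - g - p["other"]
                liq = rest * (p["l0"] + (p["l1"] - p["l0"]) * v)
                sol = rest - liq
                weight = {
                    "Cattle": cattle_weight,
                    "Sheep": 1.0 - cattle_weight,
                }.get(detailed, 1.0)
                for system, share in (
                    ("Pasture range and paddock", g),
                    ("Solid storage and dry lot", sol * 0.7),
                    ("Composting", sol * 0.3),
                    ("Liquid system", liq * 0.8),
                    ("Anaerobic lagoon", liq * 0.2),
                    ("Other", p["other"]),
                ):
                    mms_rows_full.append(
                        {
                            "country": country,
                            "year": year,
                            "livestock_class": detailed,
                            "system": system,
                            "share": share,
                            "weight": weight,
                        }
                    )

        # --- deposition rates: rising to 2013, constant after
        d0, d1 = rng.uniform(4, 8), rng.uniform(8, 20)
        dep_end_era = 2013
        dep_vals = []
        for year in years:
            v = min(1.0, (year - config.start) / (dep_end_era - config.start))
            dep_vals.append(d0 + (d1 - d0) * v)
        dep_series[(country, "deposition_rate")] = PanelSeries(
            country, "deposition_rate", "kg N/ha/yr", pd.Series(dep_vals, index=idx)
        )

    # truth yield observations: the exact 2010 reference value in dry matter
    for (country, crop), y2010 in y2010_map.items():
        yield_obs_full.append(
            {
                "country": country,
                "crop": crop,
                "year": 2010,
                "value": y2010,
                "basis": "dry_matter",
            }
        )

    crops_df = pd.DataFrame(crop_rows)
    base_config = {
        "years": {"start": config.start, "end": config.end},
        "countries": list(config.countries),
        "fert": {
            "k": {c: float(k) for c, k in config.k_map.items()},
            "zero_pg": list(config.zero_pg),
        },
        "fodder": {"donors": {}},
        "manure": {"window": [1997, 2001], "other_threshold": 0.2},
    }
    grids = {c: idx for c in config.countries}

    truth_inputs = pipeline.PipelineInputs(
        countries=list(config.countries),
        years=grids,
        crops=crops_df,
        registry=registry,
        n_contents=n_contents,
        fodder_areas=fodder_true,
        fodder_rules={c: [] for c in config.countries},
        yield_obs=pd.DataFrame(yield_obs_full),
        land=land_series,
        fert_total=fert_total,
        fert_obs=pd.DataFrame(fert_obs_full),
        excretion=pd.DataFrame(excretion_rows),
        mms_shares=pd.DataFrame(mms_rows_full),
        loss_shares=pd.DataFrame(loss_rows),
        alloc_shares=pd.DataFrame(alloc_rows),
        deposition=dep_series,
        bnf_params=DEFAULT_BNF_PARAMS.copy(),
        config=dict(base_config),
    )
    truth = pipeline.run_stages(truth_inputs)

    # ------------------------------------------------------------- degrade
    obs_inputs = degrade(truth_inputs, config, rng)
    run_config = dict(obs_inputs.config)
    run_config["inputs"] = {
        "crops": "crops.csv",
        "crop_registry": "crop_registry.csv",
        "fodder_areas": "fodder_areas.csv",
        "fodder_rules": "fodder_rules.yaml",
        "fodder_yield_obs": "fodder_yield_obs.csv",
        "land": "land.csv",
        "fert_total": "fert_total.csv",
        "fert_obs": "fert_obs.csv",
        "excretion": "manure_excretion.csv",
        "mms_shares": "mms_shares.csv",
        "loss_shares": "loss_shares.csv",
        "alloc_shares": "alloc_shares.csv",
        "deposition": "deposition_rates.csv",
        "bnf_params": "bnf_params.csv",
    }
    return SynthResult(config, truth_inputs, truth, obs_inputs, run_config)


def degrade(
    truth_inputs: pipeline.PipelineInputs,
    config: SynthConfig,
    rng: np.random.Generator,
) -> pipeline.PipelineInputs:
    """Apply the configured degradations; retained values are never altered
    (only masked, lumped, re-based, thinned, or noised where configured)."""
    deg = config.degradation
    years = list(range(config.start, config.end + 1))
    idx = year_index(years)

    # crop areas: mask pre-1985 areas at the configured rate
    crops = truth_inputs.crops.copy()
    if deg.area_missing_rate > 0:
        early = (crops["year"] < 1985).to_numpy()
        mask = rng.random(len(crops)) < deg.area_missing_rate
        crops.loc[early & mask, "area"] = np.nan

    # fodder areas: interior masking plus pre-1987 hay lumping
    fodder_obs: dict[str, dict[str, PanelSeries]] = {}
    fodder_rules: dict[str, list] = {}
    for country in config.countries:
        panel = {k: v.copy() for k, v in truth_inputs.fodder_areas[country].items()}
        if deg.fodder_missing_rate > 0:
            for var, s in panel.items():
                vals = s.values.copy()
                for year in vals.index:
                    if 1988 <= year <= 2018 and rng.random() < deg.fodder_missing_rate:
                        vals.loc[year] = np.nan
                panel[var] = s.with_values(vals)
        rules = []
        if deg.hay_lumping:
            hay_vals = pd.Series(0.0, index=idx)
            for comp in HAY_COMPONENTS:
                hay_vals = hay_vals + truth_inputs.fodder_areas[country][
                    f"area.{comp}"
                ].values
            hay_vals[hay_vals.index > 1986] = np.nan
            panel["area.hay"] = PanelSeries(country, "area.hay", "kha", hay_vals)
            for comp in HAY_COMPONENTS:
                s = panel[f"area.{comp}"]
                vals = s.values.copy()
                vals[vals.index <= 1986] = np.nan
                panel[f"area.{comp}"] = s.with_values(vals)
            rules.append(
                {
                    "kind": "proportional_split",
                    "target": "area.hay",
                    "components": [f"area.{c}" for c in HAY_COMPONENTS],
                    "reference_year": 1987,
                }
            )
        fodder_obs[country] = panel
        fodder_rules[country] = rules

    # fodder yield observations: mixed bases around the reference year
    if deg.mixed_humidity:
        obs_rows = []
        bases_grass = ("hay", "dry_matter", "national:20")
        bases_green = ("eu_standard", "dry_matter", "national:75")
        for row in truth_inputs.yield_obs.itertuples():
            country, crop, y2010 = row.country, row.crop, float(row.value)
            if crop in ("G1000", "G2100", "G2900"):
                bases = bases_grass
            elif crop == "R9000":
                bases = ("fodder_root_default",) * 3
            else:
                bases = bases_green
            for year, basis in zip((2005, 2010, 2015), bases):
                from .fodder import HumidityBasis, TREND_ANCHOR

                dm = y2010 * (
                    TREND_ANCHOR
                    + (1 - TREND_ANCHOR) * (year - 1961) / (2010 - 1961)
                )
                value = dm / HumidityBasis.parse(basis).dm_fraction()
                if deg.survey_noise_sd > 0:
                    value *= float(np.exp(rng.normal(0.0, deg.survey_noise_sd)))
                obs_rows.append(
                    {
                        "country": country,
                        "crop": crop,
                        "year": year,
                        "value": value,
                        "basis": basis,
                    }
                )
        yield_obs = pd.DataFrame(obs_rows)
    else:
        yield_obs = truth_inputs.yield_obs.copy()

    # fertilizer surveys: every Nth year, optional multiplicative noise
    fert_obs = truth_inputs.fert_obs.copy()
    if deg.survey_stride > 1:
        keep_years = set(range(config.start, config.end + 1, deg.survey_stride))
        fert_obs = fert_obs[fert_obs["year"].isin(keep_years)].reset_index(drop=True)
    if deg.survey_noise_sd > 0:
        noise = np.exp(rng.normal(0.0, deg.survey_noise_sd, size=len(fert_obs)))
        for col in ("R", "Q"):
            fert_obs[col] = fert_obs[col] * noise

    # manure management shares: drop years before the reporting era
    mms = truth_inputs.mms_shares.copy()
    if deg.mms_start is not None:
        mms = mms[(mms["year"] >= deg.mms_start) & (mms["year"] <= 2018)]
        mms = mms.reset_index(drop=True)

    # deposition rates: truncate after the last modelled year
    deposition = {}
    for key, s in truth_inputs.deposition.items():
        if deg.deposition_end is not None:
            vals = s.values.copy()
            vals[vals.index > deg.deposition_end] = np.nan
            deposition[key] = s.with_values(vals)
        else:
            deposition[key] = s.copy()

    return pipeline.PipelineInputs(
        countries=truth_inputs.countries,
        years=truth_inputs.years,
        crops=crops,
        registry=truth_inputs.registry,
        n_contents=dict(truth_inputs.n_contents),
        fodder_areas=fodder_obs,
        fodder_rules=fodder_rules,
        yield_obs=yield_obs,
        land={k: v.copy() for k, v in truth_inputs.land.items()},
        fert_total={k: v.copy() for k, v in truth_inputs.fert_total.items()},
        fert_obs=fert_obs,
        excretion=truth_inputs.excretion.copy(),
        mms_shares=mms,
        loss_shares=truth_inputs.loss_shares.copy(),
        alloc_shares=truth_inputs.alloc_shares.copy(),
        deposition=deposition,
        bnf_params=truth_inputs.bnf_params.copy(),
        config=dict(truth_inputs.config),
    )


def write_scenario(result: SynthResult, outdir: str | Path) -> Path:
    """Write observables, run config, metadata, and truth tables to disk."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    obs = result.obs_inputs

    _mock_registry_frame().to_csv(out / "crop_registry.csv", index=False)
    obs.crops.to_csv(out / "crops.csv", index=False)
    fodder_series = [
        s for panel in obs.fodder_areas.values() for s in panel.values()
    ]
    write_panel(fodder_series, out / "fodder_areas.csv")
    with open(out / "fodder_rules.yaml", "w") as fh:
        yaml.safe_dump(obs.fodder_rules, fh, sort_keys=True)
    obs.yield_obs.to_csv(out / "fodder_yield_obs.csv", index=False)
    write_panel(obs.land, out / "land.csv")
    write_panel(obs.fert_total, out / "fert_total.csv")
    obs.fert_obs.to_csv(out / "fert_obs.csv", index=False)
    obs.excretion.to_csv(out / "manure_excretion.csv", index=False)
    obs.mms_shares.to_csv(out / "mms_shares.csv", index=False)
    obs.loss_shares.to_csv(out / "loss_shares.csv", index=False)
    obs.alloc_shares.to_csv(out / "alloc_shares.csv", index=False)
    write_panel(obs.deposition, out / "deposition_rates.csv")
    obs.bnf_params.to_csv(out / "bnf_params.csv", index=False)
    # run config with fodder rules referenced by file
    cfg = dict(result.run_config)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    with open(out / "metadata.json", "w") as fh:
        json.dump(
            {"seed": result.config.seed, "degradation": asdict(result.config.degradation)},
            fh,
            indent=2,
        )
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    pipeline.write_outputs(result.truth, truth_dir)
    return out
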