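"""End-to-end tests: generator scenarios through the full pipeline."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from nbudget import cli, pipeline, synth
from nbudget.panel import read_panel


class TestGenerator:
    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            synth.SynthConfig(countries=())
        with pytest.raises(ValueError):
            synth.SynthConfig(start=2000, end=1990)

    def test_same_seed_gives_identical_outputs(self):
        a = synth.generate(synth.SynthConfig(seed=5))
        b = synth.generate(synth.SynthConfig(seed=5))
        assert a.obs_inputs.crops.equals(b.obs_inputs.crops)
        assert a.obs_inputs.fert_obs.equals(b.obs_inputs.fert_obs)
        assert a.truth["budget"].equals(b.truth["budget"])
        for c in a.config.countries:
            for var in a.obs_inputs.fodder_areas[c]:
                assert a.obs_inputs.fodder_areas[c][var].equals(
                    b.obs_inputs.fodder_areas[c][var]
                )

    def test_truth_is_invariant_to_degradation_settings(self):
        a = synth.generate(synth.SynthConfig(seed=5))
        b = synth.generate(
            synth.SynthConfig(seed=5, degradation=synth.DegradationSpec.none())
        )
        assert a.truth["budget"].equals(b.truth["budget"])

    def test_masking_never_alters_retained_values(self, degraded_result):
        truth = degraded_result.truth_inputs.crops
        obs = degraded_result.obs_inputs.crops
        kept = obs["area"].notna()
        assert (obs.loc[kept, "area"] == truth.loc[kept, "area"]).all()
        assert (obs["production"] == truth["production"]).all()

    def test_observables_pass_panel_validation(self, scenario_dir):
        # every panel file reads back cleanly under the declared grids
        for name in ("fodder_areas.csv", "land.csv", "fert_total.csv",
                     "deposition_rates.csv"):
            panels = read_panel(scenario_dir / name)
            assert panels


class TestIdentityPathway:
    def test_pipeline_on_undegraded_observables_equals_truth(self, identity_result):
        res = pipeline.run_stages(identity_result.obs_inputs)
        assert res["budget"].equals(identity_result.truth["budget"])
        assert res["fert"].equals(identity_result.truth["fert"])
        assert res["manure_flows"].equals(identity_result.truth["manure_flows"])
        assert res["bnf"].equals(identity_result.truth["bnf"])

    def test_file_round_trip_preserves_the_identity(self, identity_result, scenario_dir, tmp_path):
        res = pipeline.run_build(scenario_dir / "config.yaml", tmp_path / "out")
        assert res["budget"].equals(identity_result.truth["budget"])

    def test_rebuild_is_bit_identical(self, scenario_dir, tmp_path):
        r1 = pipeline.run_build(scenario_dir / "config.yaml", tmp_path / "o1")
        r2 = pipeline.run_build(scenario_dir / "config.yaml", tmp_path / "o2")
        assert r1["budget"].equals(r2["budget"])
        assert (tmp_path / "o1" / "budget.csv").read_bytes() == (
            tmp_path / "o2" / "budget.csv"
        ).read_bytes()


class TestRecoveryUnderDegradation:
    def test_total_harvest_recovered_within_5_percent(self, degraded_result):
        res = pipeline.run_stages(degraded_result.obs_inputs)
        t = degraded_result.truth["budget"].set_index(["country", "year"])
        o = res["budget"].set_index(["country", "year"])
        rel = ((o["harvest_n"] - t["harvest_n"]) / t["harvest_n"]).abs()
        assert rel.max() < 0.05

    def test_share_to_cropland_within_002_in_interpolated_years(self, degraded_result):
        res = pipeline.run_stages(degraded_result.obs_inputs)
        t = degraded_result.truth["fert"].set_index(["country", "year"])
        o = res["fert"].set_index(["country", "year"])
        interp = o["provenance"] == "interpolated"
        err = (o.loc[interp, "share_cropland"] - t.loc[interp, "share_cropland"]).abs()
        assert len(err) > 0
        assert err.max() < 0.02

    def test_hay_split_recovers_components_exactly_in_reference_year(
        self, degraded_result
    ):
        res = pipeline.run_stages(degraded_result.obs_inputs)
        for country in degraded_result.config.countries:
            for crop in synth.HAY_COMPONENTS:
                truth = degraded_result.truth["fodder_areas"][country][crop]
                got = res["fodder_areas"][country][crop]
                assert got.values.loc[1987] == pytest.approx(
                    truth.values.loc[1987], rel=1e-12
                )


class TestValidationReport:
    def test_clean_run_all_pass(self, scenario_dir, tmp_path):
        out = tmp_path / "out"
        pipeline.run_build(scenario_dir / "config.yaml", out)
        report = pipeline.validate_outputs(out)
        assert report["passed"].all()

    def test_corrupted_value_fails_the_matching_identity(self, scenario_dir, tmp_path):
        out = tmp_path / "out"
        pipeline.run_build(scenario_dir / "config.yaml", out)
        b = pd.read_csv(out / "budget.csv", float_precision="round_trip")
        b.loc[0, "input_total"] += 1.0
        b.to_csv(out / "budget.csv", index=False)
        report = pipeline.validate_outputs(out).set_index("check")
        assert not report.loc["budget_input_total", "passed"]

    def test_missing_outputs_reported(self, tmp_path):
        report = pipeline.validate_outputs(tmp_path)
        assert not report["passed"].all()


class TestCli:
    def test_generate_build_validate_round_trip(self, tmp_path):
        runner = CliRunner()
        scen = tmp_path / "scen"
        r = runner.invoke(cli.main, ["generate", "--seed", "7", "--out", str(scen),
                                     "--no-degradation"])
        assert r.exit_code == 0, r.output
        out = tmp_path / "out"
        r = runner.invoke(cli.main, ["build", "--config", str(scen / "config.yaml"),
                                     "--out", str(out)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli.main, ["validate", "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert (out / "validation_report.csv").exists()

    def test_generate_same_seed_writes_identical_files(self, tmp_path):
        runner = CliRunner()
        a, b = tmp_path / "a", tmp_path / "b"
        for d in (a, b):
            r = runner.invoke(cli.main, ["generate", "--seed", "11", "--out", str(d)])
            assert r.exit_code == 0, r.output
        for f in sorted(a.iterdir()):
            if f.is_file():
                assert f.read_bytes() == (b / f.name).read_bytes(), f.name
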