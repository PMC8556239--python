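import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nbudget import gapfill
from nbudget.panel import PanelError, PanelSeries

YEARS = range(1961, 1971)


def series(data, unit="kha", country="AA", variable="x", years=YEARS):
    return PanelSeries.from_dict(country, variable, unit, data, years)


class TestInterpolate:
    def test_midpoint(self):
        s = series({1961: 10.0, 1963: 14.0}, years=range(1961, 1964))
        out = gapfill.interpolate_linear(s)
        assert out.values.loc[1962] == 12.0

    def test_longer_gap_follows_the_line(self):
        s = series({1961: 10.0, 1965: 30.0}, years=range(1961, 1966))
        out = gapfill.interpolate_linear(s)
        assert out.values.loc[1963] == 20.0

    def test_no_missing_is_identity(self):
        s = series({y: float(y) for y in YEARS})
        assert gapfill.interpolate_linear(s).equals(s)

    def test_edges_stay_missing(self):
        s = series({1965: 5.0})
        out = gapfill.interpolate_linear(s)
        assert np.isnan(out.values.loc[1961]) and np.isnan(out.values.loc[1970])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_observed_values_never_modified(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 100, 10)
        vals[rng.random(10) < 0.4] = np.nan
        s = PanelSeries("AA", "x", "kha", pd.Series(vals, index=list(YEARS)))
        out = gapfill.interpolate_linear(s)
        obs = s.values.notna()
        assert (out.values[obs] == s.values[obs]).all()


class TestExtrapolate:
    def test_backward_constant(self):
        s = series({2000: 5.0}, years=range(1992, 2002))
        out = gapfill.extrapolate_const(s, "backward")
        assert (out.values.loc[1992:1999] == 5.0).all()

    def test_forward_2018_to_2019(self):
        s = series({2018: 7.0}, years=range(2010, 2020))
        out = gapfill.extrapolate_const(s, "forward")
        assert out.values.loc[2019] == out.values.loc[2018]

    def test_complete_series_unchanged(self):
        s = series({y: 1.0 for y in YEARS})
        assert gapfill.extrapolate_const(s, "both").equals(s)

    def test_all_missing_errors(self):
        s = series({})
        with pytest.raises(PanelError, match="all-missing"):
            gapfill.extrapolate_const(s)


class TestProportionalSplit:
    def test_fixed_hay_proportions(self):
        # 29/6/42/23 split of a lumped fodder area
        total = series({y: 100.0 for y in YEARS}, variable="hay")
        parts = gapfill.proportional_split(
            total, {"G1000": 0.29, "G2100": 0.06, "G2900": 0.42, "G9000": 0.23}
        )
        assert parts["G1000"].values.loc[1961] == pytest.approx(29.0)
        assert parts["G2100"].values.loc[1961] == pytest.approx(6.0)
        assert parts["G2900"].values.loc[1961] == pytest.approx(42.0)
        assert parts["G9000"].values.loc[1961] == pytest.approx(23.0)

    def test_single_component_identity(self):
        total = series({y: 7.0 for y in YEARS})
        parts = gapfill.proportional_split(total, {"only": 1.0})
        assert (parts["only"].values == total.values).all()

    def test_conservation_exact_on_randomized_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            total = series({y: float(rng.uniform(0, 1e4)) for y in YEARS})
            raw = rng.uniform(0.01, 1.0, 4)
            names = ["a", "b", "c", "d"]
            shares = {n: v / raw.sum() for n, v in zip(names[:-1], raw[:-1])}
            shares["d"] = 1.0 - sum(shares.values())
            parts = gapfill.proportional_split(total, shares)
            # residual construction: total minus the leading parts is the last
            running = parts["a"].values + 0.0
            for n in ("b", "c"):
                running = running + parts[n].values
            assert ((total.values - running) == parts["d"].values).all()

    def test_negative_share_errors(self):
        total = series({1961: 1.0})
        with pytest.raises(ValueError, match="negative"):
            gapfill.proportional_split(total, {"a": -0.1, "b": 1.1})

    def test_reference_year_shares_reproduce_components(self):
        comps = [
            series({1965: 30.0}, variable="a"),
            series({1965: 70.0}, variable="b"),
        ]
        shares = gapfill.shares_from_reference_year(comps, 1965)
        total = series({1965: 100.0})
        parts = gapfill.proportional_split(total, shares)
        assert parts["a"].values.loc[1965] == pytest.approx(30.0)
        assert parts["b"].values.loc[1965] == pytest.approx(70.0)


class TestResidual:
    def test_root_crop_hierarchy(self):
        r0 = series({1961: 50.0}, variable="R0000")
        r1 = series({1961: 30.0}, variable="R1000")
        r2 = series({1961: 15.0}, variable="R2000")
        out = gapfill.residual(r0, [r1, r2])
        assert out.values.loc[1961] == 5.0

    def test_children_equal_parent_gives_zero(self):
        r0 = series({1961: 45.0})
        out = gapfill.residual(r0, [series({1961: 30.0}), series({1961: 15.0})])
        assert out.values.loc[1961] == 0.0

    def test_negative_residual_clipped_with_warning(self, caplog):
        r0 = series({1961: 44.0})
        with caplog.at_level(logging.WARNING, logger="nbudget.gapfill"):
            out = gapfill.residual(r0, [series({1961: 30.0}), series({1961: 15.0})])
        assert out.values.loc[1961] == 0.0
        assert any("clipped" in r.message for r in caplog.records)

    def test_missing_propagates(self):
        r0 = series({1961: 50.0, 1962: 40.0})
        out = gapfill.residual(r0, [series({1961: 30.0})])
        assert np.isnan(out.values.loc[1962])


class TestMergeSum:
    def test_both_present(self):
        out = gapfill.merge_sum(series({1961: 3.0}), series({1961: 7.0}))
        assert out.values.loc[1961] == 10.0

    def test_one_sided_treats_missing_as_absent(self):
        out = gapfill.merge_sum(series({1961: 3.0}), series({}))
        assert out.values.loc[1961] == 3.0

    def test_both_missing_stays_missing(self):
        out = gapfill.merge_sum(series({}), series({}))
        assert out.values.isna().all()

    def test_unit_mismatch_errors(self):
        with pytest.raises(PanelError, match="unit mismatch"):
            gapfill.merge_sum(series({1961: 1.0}), series({1961: 1.0}, unit="Gg N/yr"))


class TestRuleEngine:
    def _panel(self):
        return {
            "hay": series({y: 100.0 for y in range(1961, 1966)}, variable="hay",
                          years=range(1961, 1971)),
            "a": series({y: 20.0 + y - 1966 for y in range(1966, 1971)}, variable="a",
                        years=range(1961, 1971)),
            "b": series({y: 80.0 for y in range(1966, 1971)}, variable="b",
                        years=range(1961, 1971)),
        }

    def test_rules_applied_in_order_and_deterministic(self):
        rules = [
            {
                "kind": "proportional_split",
                "target": "hay",
                "components": ["a", "b"],
                "reference_year": 1966,
            },
            {"kind": "scale", "target": "b", "factor": 2.0, "years": [1961, 1962]},
        ]
        out1 = gapfill.apply_rules(self._panel(), rules)
        out2 = gapfill.apply_rules(self._panel(), rules)
        for k in out1:
            assert out1[k].equals(out2[k])
        assert out1["a"].values.loc[1961] == pytest.approx(20.0)
        assert out1["b"].values.loc[1961] == pytest.approx(160.0)

    def test_unknown_target_errors(self):
        with pytest.raises(PanelError, match="unknown variable"):
            gapfill.apply_rules(self._panel(), [{"kind": "discard", "target": "zz",
                                                 "years": [1961, 1962]}])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown rule kind"):
            gapfill.EditRule(kind="smooth", target="a")

    def test_example_configs_load_and_contain_the_hay_splits(self):
        rules = gapfill.load_example_rules()
        assert "Poland" in rules and "Czechoslovakia" in rules
        poland = rules["Poland"][0]
        assert poland["kind"] == "proportional_split"
        assert poland["shares"]["area.G2900"] == 0.42
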