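import numpy as np
import pandas as pd
import pytest

from nbudget import manure
from nbudget.manure import (
    ManureError,
    MmsShares,
    aggregate_mms,
    apply_storage_losses,
    backfill_shares,
    chain,
    effective_grass_share,
    excretion_weighted_average,
    liquid_solid_shares,
    split_grazing_housed,
    split_to_land,
)


class TestAggregateMms:
    def test_direct_mapping(self):
        raw = {
            ("Cattle", "Pasture range and paddock"): 0.3,
            ("Cattle", "Solid storage and dry lot"): 0.4,
            ("Cattle", "Liquid system"): 0.3,
        }
        out = aggregate_mms(raw, "AA", 2000)
        s = out["ruminants_equines"].shares
        assert s == {"grazing": 0.3, "solid": 0.4, "liquid": 0.3, "other": 0.0}

    def test_composting_and_daily_spread_count_as_solid(self):
        raw = {
            ("Swine", "Composting"): 0.2,
            ("Swine", "Daily spread"): 0.3,
            ("Swine", "Solid storage and dry lot"): 0.1,
            ("Swine", "Liquid system"): 0.4,
        }
        out = aggregate_mms(raw, "AA", 2000)
        assert out["pigs"].shares["solid"] == pytest.approx(0.6)

    def test_cattle_and_sheep_merge_with_excretion_weights(self):
        raw = {
            ("Cattle", "Pasture range and paddock"): 0.2,
            ("Cattle", "Liquid system"): 0.8,
            ("Sheep", "Pasture range and paddock"): 0.8,
            ("Sheep", "Solid storage and dry lot"): 0.2,
        }
        out = aggregate_mms(raw, "AA", 2000, excretion_weights={"Cattle": 3.0, "Sheep": 1.0})
        s = out["ruminants_equines"].shares
        assert s["grazing"] == pytest.approx((0.2 * 3 + 0.8 * 1) / 4)
        assert s["liquid"] == pytest.approx(0.6)

    def test_unmapped_system_errors(self):
        with pytest.raises(ManureError, match="unmapped"):
            aggregate_mms({("Cattle", "Compost heap"): 1.0})

    def test_unmapped_class_errors(self):
        with pytest.raises(ManureError, match="unmapped"):
            aggregate_mms({("Camels", "Other"): 1.0})


class TestBackfillShares:
    def _table(self):
        years = range(1990, 2019)
        return pd.DataFrame(
            {
                "grazing": np.linspace(0.3, 0.2, len(list(years))),
                "solid": 0.3,
                "liquid": np.linspace(0.38, 0.48, 29),
                "other": 0.02,
            },
            index=pd.Index(range(1990, 2019), name="year"),
        )

    def test_constant_backward_and_forward_extension(self):
        filled = backfill_shares(self._table(), range(1961, 2020))
        assert (filled.loc[1961] == filled.loc[1990]).all()
        assert (filled.loc[1989] == filled.loc[1990]).all()
        assert (filled.loc[2019] == filled.loc[2018]).all()

    def test_fully_observed_series_unchanged(self):
        t = self._table()
        filled = backfill_shares(t, range(1990, 2019))
        assert filled.equals(t)

    def test_extrapolated_rows_still_sum_to_one(self):
        filled = backfill_shares(self._table(), range(1961, 2020))
        assert np.allclose(filled.sum(axis=1), 1.0)

    def test_empty_table_errors(self):
        with pytest.raises(ManureError):
            backfill_shares(pd.DataFrame(), range(1961, 2020))


class TestSplitsAndLosses:
    def test_grazing_housed_split(self):
        assert split_grazing_housed(100.0, 0.3) == (30.0, 70.0)

    def test_zero_grazing_share(self):
        assert split_grazing_housed(50.0, 0.0) == (0.0, 50.0)

    def test_split_conserves_bit_exactly(self):
        rng = np.random.default_rng(53)
        for _ in range(1000):
            total, share = rng.uniform(0, 500), rng.uniform(0, 1)
            grazing, housed = split_grazing_housed(total, share)
            assert total - grazing == housed

    def test_storage_losses(self):
        assert apply_storage_losses(70.0, 0.2) == (14.0, 56.0)
        assert apply_storage_losses(70.0, 0.0) == (0.0, 70.0)

    def test_generic_30_percent_fallback_value(self):
        lost, applied = apply_storage_losses(100.0, manure.GENERIC_LOSS_SHARE)
        assert lost == pytest.approx(30.0)

    def test_loss_share_of_one_rejected(self):
        with pytest.raises(ManureError):
            apply_storage_losses(10.0, 1.0)


class TestLiquidSolid:
    def test_minor_other_share_renormalized(self):
        liq, sol = liquid_solid_shares({"solid": 0.3, "liquid": 0.5, "other": 0.2})
        assert (liq, sol) == (pytest.approx(0.625), pytest.approx(0.375))

    def test_no_other_gives_raw_proportions(self):
        liq, sol = liquid_solid_shares({"solid": 0.25, "liquid": 0.75, "other": 0.0})
        assert liq == 0.75 and sol == 0.25

    def test_large_other_share_requires_exogenous_data(self):
        shares = MmsShares("ES", 2000, "pigs",
                           {"grazing": 0.0, "solid": 0.27, "liquid": 0.40, "other": 0.33})
        with pytest.raises(ManureError, match="exceeds"):
            liquid_solid_shares(shares)

    def test_override_used_when_supplied(self):
        liq, sol = liquid_solid_shares(
            {"solid": 0.27, "liquid": 0.40, "other": 0.33}, override=(0.6, 0.4)
        )
        assert liq == pytest.approx(0.6)


class TestLandAllocation:
    def test_poultry_single_share(self):
        assert effective_grass_share("poultry_rabbits", {"all": 0.1}) == 0.1

    def test_liquid_solid_weighted_share(self):
        share = effective_grass_share(
            "ruminants_equines", {"liquid": 0.8, "solid": 0.5}, liquid_weight=0.6
        )
        assert share == pytest.approx(0.68)

    def test_missing_weight_errors(self):
        with pytest.raises(ManureError):
            effective_grass_share("pigs", {"liquid": 0.5, "solid": 0.5})

    def test_proportional_split_between_grasslands(self):
        to_c, to_pg = split_to_land(100.0, 0.0, 40.0, a_pg=300.0, a_tg=100.0)
        assert to_pg == 75.0 and to_c == 40.0 + 25.0

    def test_no_temporary_grassland_sends_all_to_pg(self):
        to_c, to_pg = split_to_land(50.0, 10.0, 5.0, a_pg=100.0, a_tg=0.0)
        assert to_pg == 60.0 and to_c == 5.0

    def test_grass_destined_without_grassland_errors(self):
        with pytest.raises(ManureError):
            split_to_land(1.0, 0.0, 0.0, a_pg=0.0, a_tg=0.0)


class TestChainConservation:
    def test_identities_bit_exact_on_randomized_instances(self):
        rng = np.random.default_rng(59)
        for _ in range(1000):
            shares = rng.dirichlet(np.ones(4))
            mms = {
                "grazing": shares[0], "solid": shares[1],
                "liquid": shares[2], "other": shares[3],
            }
            flows = chain(
                "AA", 2000, "pigs",
                excreted_total=float(rng.uniform(0, 300)),
                mms=mms,
                loss_share=float(rng.uniform(0, 0.9)),
                grass_share=float(rng.uniform(0, 1)),
                a_pg=float(rng.uniform(1, 1e3)),
                a_tg=float(rng.uniform(0, 1e3)),
            )
            flows.check()  # raises on any broken identity
            # and the sums agree to numerical precision in the plain form
            assert flows.excreted_grazing + flows.excreted_housed == pytest.approx(
                flows.excreted_total, rel=1e-12, abs=1e-12
            )
            assert (
                flows.to_cropland + flows.to_permanent_grassland
                + flows.lost_housing_storage
            ) == pytest.approx(flows.excreted_total, rel=1e-12, abs=1e-12)

    def test_higher_losses_leave_less_for_land(self):
        common = dict(
            excreted_total=100.0,
            mms={"grazing": 0.2, "solid": 0.3, "liquid": 0.45, "other": 0.05},
            grass_share=0.4, a_pg=100.0, a_tg=50.0,
        )
        low = chain("AA", 2000, "pigs", loss_share=0.1, **common)
        high = chain("AA", 2000, "pigs", loss_share=0.3, **common)
        assert (high.to_cropland + high.to_permanent_grassland) < (
            low.to_cropland + low.to_permanent_grassland
        )


class TestCompositeRegions:
    def test_excretion_weighted_average(self):
        combined = excretion_weighted_average(
            {"CZ": {"grazing": 0.2, "solid": 0.8}, "SK": {"grazing": 0.6, "solid": 0.4}},
            {"CZ": 30.0, "SK": 10.0},
        )
        assert combined["grazing"] == pytest.approx(0.3)
        assert combined["solid"] == pytest.approx(0.7)

    def test_zero_excretion_errors(self):
        with pytest.raises(ManureError):
            excretion_weighted_average({"CZ": {"grazing": 1.0}}, {"CZ": 0.0})
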