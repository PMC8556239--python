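import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nbudget import fertilizer as fert
from nbudget.fertilizer import (
    FertObservation,
    allocate_quantities,
    area_weighted_rate,
    build_rate_ratio_series,
    estimate_rate_ratio,
    rate_ratio_from_total_grass,
    rate_ratio_last_resort,
    renormalize_fertilized,
    screen_observations,
    share_to_cropland,
    zero_pg_series,
)

YEARS = range(1961, 2020)


class TestAreaWeightedRate:
    def test_equal_areas_give_plain_mean(self):
        assert area_weighted_rate([(100.0, 10.0), (50.0, 10.0)]) == 75.0

    def test_single_crop_returns_its_rate(self):
        assert area_weighted_rate([(42.0, 3.0)]) == 42.0

    def test_randomized_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(500):
            n = rng.integers(1, 8)
            pairs = [(float(rng.uniform(0, 300)), float(rng.uniform(0.1, 100)))
                     for _ in range(n)]
            expected = sum(r * a for r, a in pairs) / sum(a for _, a in pairs)
            assert area_weighted_rate(pairs) == pytest.approx(expected, rel=1e-12)

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            area_weighted_rate([])


class TestRenormalizeFertilized:
    def test_quarter_of_the_area_quarters_the_rate(self):
        assert renormalize_fertilized(100.0, 50.0, 200.0) == 25.0

    def test_full_coverage_is_identity(self):
        assert renormalize_fertilized(80.0, 10.0, 10.0) == 80.0

    def test_conserves_the_applied_quantity(self):
        rng = np.random.default_rng(29)
        for _ in range(500):
            a_tot = rng.uniform(1, 1e3)
            a_f = rng.uniform(0, a_tot)
            r_f = rng.uniform(0, 400)
            r = renormalize_fertilized(r_f, a_f, a_tot)
            assert r * a_tot == pytest.approx(r_f * a_f, rel=1e-12, abs=1e-12)

    def test_fertilized_exceeding_total_errors(self):
        with pytest.raises(ValueError):
            renormalize_fertilized(10.0, 2.0, 1.0)


class TestShareToCropland:
    def test_zero_ratio_means_everything_to_cropland(self):
        assert share_to_cropland(0.0, 5000.0, 1000.0) == 1.0

    def test_equal_rates_and_areas_split_evenly(self):
        assert share_to_cropland(1.0, 100.0, 100.0) == 0.5

    def test_forward_construction_oracle(self):
        # construct R_C=100, R_PG=60, A_PG=4000, A_C=14000 and compare with
        # the direct Q_C/(Q_C+Q_PG)
        r_c, r_pg, a_pg, a_c = 100.0, 60.0, 4000.0, 14000.0
        q_c, q_pg = r_c * a_c, r_pg * a_pg
        expected = q_c / (q_c + q_pg)
        got = share_to_cropland(r_pg / r_c, a_pg, a_c)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.8537, abs=5e-5)

    @given(
        st.floats(0.0, 5.0),
        st.floats(1.0, 1e4),
        st.floats(1.0, 1e4),
    )
    @settings(max_examples=300, deadline=None)
    def test_bounds_and_monotonicity(self, ratio, a_pg, a_c):
        s = share_to_cropland(ratio, a_pg, a_c)
        assert 0.0 <= s <= 1.0
        assert share_to_cropland(ratio + 0.5, a_pg, a_c) <= s
        assert share_to_cropland(ratio, a_pg + 100.0, a_c) <= s

    def test_zero_cropland_errors(self):
        with pytest.raises(ValueError):
            share_to_cropland(0.5, 100.0, 0.0)


def _construct_eq5_instance(rng):
    """Forward-construct a consistent total-grass/non-grass instance."""
    a_pg = rng.uniform(10, 5000)
    a_tg = rng.uniform(0, 2000)
    a_c_minus_tg = rng.uniform(10, 8000)
    a_c = a_c_minus_tg + a_tg
    k = rng.uniform(0.5, 3.0)
    r_pg = rng.uniform(1, 300)
    r_tg = k * r_pg
    r_c_minus_tg = rng.uniform(1, 400)
    r_pg_plus_tg = (r_pg * a_pg + r_tg * a_tg) / (a_pg + a_tg)
    r_c = (r_c_minus_tg * a_c_minus_tg + r_tg * a_tg) / a_c
    return dict(
        r_pg_plus_tg=r_pg_plus_tg,
        r_c_minus_tg=r_c_minus_tg,
        a_pg=a_pg,
        a_tg=a_tg,
        a_c=a_c,
        a_c_minus_tg=a_c_minus_tg,
        a_pg_plus_tg=a_pg + a_tg,
        k=k,
        expected=r_pg / r_c,
    )


class TestRateRatioFromTotalGrass:
    def test_reduces_to_simple_ratio_without_temporary_grassland(self):
        got = rate_ratio_from_total_grass(
            80.0, 100.0, a_pg=500.0, a_tg=0.0, a_c=1000.0,
            a_c_minus_tg=1000.0, a_pg_plus_tg=500.0, k=1.0,
        )
        assert got == pytest.approx(0.8, rel=1e-12)

    def test_worked_instance(self):
        # R_PG=60, R_TG=120 (k=2): grassland mean is 80, R_C works out to 104
        got = rate_ratio_from_total_grass(
            80.0, 100.0, a_pg=100.0, a_tg=50.0, a_c=250.0,
            a_c_minus_tg=200.0, a_pg_plus_tg=150.0, k=2.0,
        )
        assert got == pytest.approx(60.0 / 104.0, rel=1e-9)

    def test_randomized_forward_construction_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(1000):
            inst = _construct_eq5_instance(rng)
            expected = inst.pop("expected")
            got = rate_ratio_from_total_grass(
                inst["r_pg_plus_tg"], inst["r_c_minus_tg"],
                a_pg=inst["a_pg"], a_tg=inst["a_tg"], a_c=inst["a_c"],
                a_c_minus_tg=inst["a_c_minus_tg"],
                a_pg_plus_tg=inst["a_pg_plus_tg"], k=inst["k"],
            )
            assert got == pytest.approx(expected, rel=1e-9)

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            rate_ratio_from_total_grass(0.0, 10.0, a_pg=1, a_tg=1, a_c=2,
                                        a_c_minus_tg=1, a_pg_plus_tg=2)


class TestRateRatioLastResort:
    def test_forward_construction(self):
        # two categories: R_x=60 on 100 kha, complement 90 on 200 kha
        q_tot = (60.0 * 100.0 + 90.0 * 200.0) / 1000.0
        got = rate_ratio_last_resort(60.0, 100.0, 300.0, q_tot)
        assert got == pytest.approx(60.0 / 90.0, rel=1e-12)

    def test_uniform_rate_gives_one(self):
        q_tot = 50.0 * 300.0 / 1000.0
        assert rate_ratio_last_resort(50.0, 100.0, 300.0, q_tot) == pytest.approx(1.0)

    def test_zero_rate_gives_zero(self):
        assert rate_ratio_last_resort(0.0, 100.0, 300.0, 10.0) == 0.0

    def test_randomized_forward_construction_oracle(self):
        rng = np.random.default_rng(37)
        for _ in range(1000):
            a_x = rng.uniform(1, 1e3)
            a_comp = rng.uniform(1, 1e3)
            r_x = rng.uniform(0.1, 300)
            r_comp = rng.uniform(0.1, 300)
            q_tot = (r_x * a_x + r_comp * a_comp) / 1000.0
            got = rate_ratio_last_resort(r_x, a_x, a_x + a_comp, q_tot)
            assert got == pytest.approx(r_x / r_comp, rel=1e-9)

    def test_implied_nonpositive_complement_errors(self):
        with pytest.raises(ValueError):
            rate_ratio_last_resort(100.0, 100.0, 200.0, 10.0)


class TestRateRatioSeries:
    def test_single_point_extrapolates_constant(self):
        s = build_rate_ratio_series([(1995, 0.11)], YEARS, "AT")
        assert (s.values == 0.11).all()
        assert s.provenance.loc[1995] == "eq2-direct"
        assert s.provenance.loc[1961] == "extrapolated"

    def test_linear_interpolation_between_points(self):
        s = build_rate_ratio_series([(1996, 0.70), (2006, 0.17)], YEARS, "DK")
        assert s.values.loc[2001] == pytest.approx(0.435)
        assert s.provenance.loc[2001] == "interpolated"

    def test_same_year_estimates_averaged(self):
        s = build_rate_ratio_series([(1990, 0.10), (1990, 0.20)], YEARS)
        assert s.values.loc[1990] == pytest.approx(0.15)

    def test_empty_points_error(self):
        with pytest.raises(ValueError):
            build_rate_ratio_series([], YEARS)

    def test_zero_pg_series_is_all_zero(self):
        s = zero_pg_series(YEARS, "SE")
        assert (s.values == 0.0).all()


class TestAllocateQuantities:
    def test_share_one_sends_all_to_cropland(self):
        assert allocate_quantities(10.0, 1.0) == (10.0, 0.0)

    def test_even_split(self):
        assert allocate_quantities(10.0, 0.5) == (5.0, 5.0)

    def test_conservation_exact_on_randomized_instances(self):
        rng = np.random.default_rng(41)
        for _ in range(1000):
            q_tot = rng.uniform(0, 2000)
            share = rng.uniform(0, 1)
            q_c, q_pg = allocate_quantities(q_tot, share)
            assert q_tot - q_c == q_pg  # residual construction, bit-exact

    def test_share_out_of_bounds_errors(self):
        with pytest.raises(ValueError):
            allocate_quantities(10.0, 1.5)


class TestObservations:
    def test_consistent_record_kept_inconsistent_excluded(self):
        good = FertObservation("AA", 2000, "C", R=100.0, A=1000.0, Q=100.0)
        bad = FertObservation("AA", 2000, "C", R=100.0, A=1000.0, Q=120.0)
        kept, excluded = screen_observations([good, bad])
        assert kept == [good] and excluded == [bad]

    def test_unknown_land_category_rejected(self):
        with pytest.raises(ValueError):
            FertObservation("AA", 2000, "arable", R=1.0)

    def test_direct_ratio_preferred(self):
        obs = [
            FertObservation("AA", 2000, "C", R=100.0),
            FertObservation("AA", 2000, "PG", R=40.0),
        ]
        ratio, prov = estimate_rate_ratio(obs, a_pg=500, a_tg=100, a_c=1000)
        assert ratio == pytest.approx(0.4) and prov == "eq2-direct"

    def test_total_grass_falls_back_to_eq5(self):
        inst_rng = np.random.default_rng(43)
        a_pg, a_tg, a_c = 500.0, 100.0, 1000.0
        obs = [
            FertObservation("AA", 2000, "PG+TG", R=80.0),
            FertObservation("AA", 2000, "C-TG", R=100.0),
        ]
        ratio, prov = estimate_rate_ratio(obs, a_pg=a_pg, a_tg=a_tg, a_c=a_c, k=1.0)
        assert prov == "eq5"
        expected = rate_ratio_from_total_grass(
            80.0, 100.0, a_pg=a_pg, a_tg=a_tg, a_c=a_c,
            a_c_minus_tg=a_c - a_tg, a_pg_plus_tg=a_pg + a_tg, k=1.0,
        )
        assert ratio == expected

    def test_single_rate_uses_total_consumption_last(self):
        obs = [FertObservation("AA", 2000, "PG", R=60.0)]
        ratio, prov = estimate_rate_ratio(
            obs, a_pg=100.0, a_tg=0.0, a_c=200.0, q_tot=(60 * 100 + 90 * 200) / 1000
        )
        assert prov == "eq6" and ratio == pytest.approx(60 / 90, rel=1e-9)

    def test_fertilized_subset_renormalized_first(self):
        obs = [
            FertObservation("AA", 2000, "PGf", R=100.0, A=50.0),
            FertObservation("AA", 2000, "C", R=50.0),
        ]
        ratio, prov = estimate_rate_ratio(obs, a_pg=200.0, a_tg=0.0, a_c=1000.0)
        # R_PG = 100*50/200 = 25; ratio = 25/50
        assert ratio == pytest.approx(0.5) and prov == "eq2-direct"

    def test_no_usable_observations_returns_none(self):
        assert estimate_rate_ratio([], a_pg=1, a_tg=0, a_c=1) is None
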