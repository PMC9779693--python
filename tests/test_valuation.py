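"""Six-service valuation: unit arithmetic, limits, and summary identities."""

import numpy as np
import pandas as pd
import pytest

from esvscape.grid import Grid, LandUseGrid
from esvscape.valuation import (
    EconomicParams,
    FoodItem,
    HabitatParams,
    ServiceGrids,
    biodiversity_baseline,
    compute_npp,
    food_production_value,
    habitat_degradation,
    habitat_quality,
    habitat_support_value,
    landscape_aesthetic_value,
    npp_value,
    rusle_retention,
    soil_retention_value,
    total_esv,
    water_conservation_value,
    water_retention,
    water_yield,
)


def const(v, shape=(4, 4), cs=100.0):
    return Grid(np.full(shape, float(v)), cs)


@pytest.fixture
def farm_lu():
    codes = np.ones((4, 4), np.int16)
    codes[2:, :] = 2
    return LandUseGrid(codes, {1: "dry farm", 2: "forest"}, 100.0)


class TestFoodProduction:
    def test_single_item_arithmetic(self, farm_lu):
        p = EconomicParams(food_items={"dry farm": [FoodItem(5.0, 2.0, 0.4)]})
        g = food_production_value(farm_lu, p)
        assert g.values[0, 0] == pytest.approx(4000.0)  # 5 t * 1000 * 2 * 0.4
        assert g.values[3, 3] == 0.0  # forest has no food items

    def test_zero_margin_zeroes_value(self, farm_lu):
        p = EconomicParams(food_items={"dry farm": [FoodItem(5.0, 2.0, 0.0)]})
        assert (food_production_value(farm_lu, p).values == 0).all()

    def test_items_are_additive(self, farm_lu):
        one = EconomicParams(food_items={"dry farm": [FoodItem(5.0, 2.0, 0.4)]})
        two = EconomicParams(food_items={"dry farm": [FoodItem(1.0, 3.0, 0.5)]})
        both = EconomicParams(
            food_items={"dry farm": [FoodItem(5.0, 2.0, 0.4), FoodItem(1.0, 3.0, 0.5)]}
        )
        assert np.allclose(
            food_production_value(farm_lu, both).values,
            food_production_value(farm_lu, one).values
            + food_production_value(farm_lu, two).values,
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            FoodItem(-1.0, 2.0, 0.4)


class TestCarbonOxygen:
    def test_unit_npp(self):
        p = EconomicParams(carbon_cost=100.0, oxygen_cost=50.0)
        g = npp_value(const(1.0), p)
        assert g.values[0, 0] == pytest.approx(1.63 * 100 + 1.2 * 50)  # 223

    def test_linear_in_npp(self):
        p = EconomicParams()
        assert np.allclose(
            npp_value(const(2.0), p).values, 2 * npp_value(const(1.0), p).values
        )
        assert (npp_value(const(0.0), p).values == 0).all()

    def test_compute_npp_units(self):
        g = compute_npp(const(100.0), const(0.5))
        assert g.values[0, 0] == pytest.approx(0.5)  # 50 gC/m2 = 0.5 t/ha

    def test_compute_npp_matches_elementwise_product(self):
        rng = np.random.default_rng(0)
        a, e = rng.random((5, 5)) * 2000, rng.random((5, 5))
        g = compute_npp(Grid(a, 30.0), Grid(e, 30.0))
        assert np.allclose(g.values, a * e * 0.01)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            compute_npp(const(1, (3, 3)), const(1, (4, 4)))


class TestWater:
    def test_yield_is_p_minus_aet(self):
        g = water_yield(const(800.0), const(500.0))
        assert (g.values == 300.0).all()

    def test_closed_basin_zero_yield(self):
        assert (water_yield(const(700.0), const(700.0)).values == 0).all()

    def test_no_aet_full_yield(self):
        assert (water_yield(const(650.0), const(0.0)).values == 650.0).all()

    def test_aet_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            g = water_yield(const(100.0), const(150.0))
        assert (g.values == 0).all()

    def test_retention_caps_saturate(self):
        g = water_retention(const(300.0), const(100.0), const(10.0), const(400.0))
        assert (g.values == 300.0).all()

    def test_retention_single_active_factor(self):
        g = water_retention(const(300.0), const(100.0), const(1.0), const(400.0))
        assert g.values[0, 0] == pytest.approx(0.3 * 300.0)

    def test_retention_never_exceeds_yield(self):
        rng = np.random.default_rng(1)
        y = Grid(rng.random((6, 6)) * 1000, 30.0)
        wr = water_retention(
            y,
            Grid(rng.random((6, 6)) * 500 + 1, 30.0),
            Grid(rng.random((6, 6)) * 10, 30.0),
            Grid(rng.random((6, 6)) * 600, 30.0),
        )
        assert (wr.values <= y.values + 1e-12).all()

    def test_conservation_value_unit_conversion(self):
        p = EconomicParams(reservoir_cost=6.0)
        g = water_conservation_value(const(100.0), p)
        assert g.values[0, 0] == pytest.approx(6000.0)  # 100 mm -> 1000 m3/ha


class TestSoil:
    def test_rusle_hand_value(self):
        g = rusle_retention(const(2.0), const(0.3), const(5.0), const(0.2), const(0.5))
        assert g.values[0, 0] == pytest.approx(2.7)

    def test_rusle_limits(self):
        full = rusle_retention(const(2.0), const(0.3), const(5.0), const(0.0), const(1.0))
        assert full.values[0, 0] == pytest.approx(3.0)
        none = rusle_retention(const(2.0), const(0.3), const(5.0), const(1.0), const(1.0))
        assert (none.values == 0).all()

    def test_rusle_factor_range_enforced(self):
        with pytest.raises(ValueError, match="C"):
            rusle_retention(const(1), const(1), const(1), const(1.5), const(1))

    def test_value_hand_arithmetic(self):
        p = EconomicParams(
            reservoir_cost=6.0, soil_bulk_density=1.25, soil_thickness=0.5,
            forestry_income=3000.0, sediment_deposit_ratio=0.24,
        )
        g = soil_retention_value(const(10.0), p)
        # term1 = 10*0.24*6/1.25 = 11.52 ; term2 = 10/(1.25*0.5)/1e4*3000 = 4.8
        assert g.values[0, 0] == pytest.approx(16.32)

    def test_linear_in_amount(self):
        p = EconomicParams()
        assert np.allclose(
            soil_retention_value(const(20.0), p).values,
            2 * soil_retention_value(const(10.0), p).values,
        )


@pytest.fixture
def habitat_setup():
    codes = np.ones((1, 8), np.int16)
    codes[0, 0] = 2  # single building pixel at the west edge
    lu = LandUseGrid(codes, {1: "forest", 2: "building"}, 100.0)
    hp = HabitatParams(
        suitability={"forest": 1.0, "building": 0.0},
        threats={"building": {"classes": ["building"], "weight": 1.0, "max_distance": 400.0}},
        sensitivity={"forest": {"building": 1.0}, "building": {"building": 0.0}},
        z=2.5,
    )
    return lu, hp


class TestHabitat:
    def test_on_threat_degradation_for_sensitive_class(self, habitat_setup):
        lu, hp = habitat_setup
        hp2 = HabitatParams(
            suitability=hp.suitability, threats=hp.threats,
            sensitivity={"forest": {"building": 1.0}, "building": {"building": 1.0}},
            z=hp.z,
        )
        D = habitat_degradation(lu, hp2)
        assert D.values[0, 0] == pytest.approx(1.0)  # distance 0, S=1

    def test_decay_formula_at_distance(self, habitat_setup):
        lu, hp = habitat_setup
        D = habitat_degradation(lu, hp)
        d = 400.0  # pixel 4 is 4 pixels = 400 m from the threat
        assert D.values[0, 4] == pytest.approx(np.exp(-2.99 * d / 400.0), rel=1e-12)

    def test_insensitive_class_has_zero_degradation(self, habitat_setup):
        lu, hp = habitat_setup
        hp0 = HabitatParams(
            suitability=hp.suitability, threats=hp.threats,
            sensitivity={"forest": {"building": 0.0}, "building": {"building": 0.0}},
            z=hp.z,
        )
        assert (habitat_degradation(lu, hp0).values == 0).all()

    def test_quality_pristine_and_half_saturation(self, habitat_setup):
        lu, hp = habitat_setup
        D = habitat_degradation(lu, hp)
        Q = habitat_quality(lu, D, hp)
        k = D.values.max() / 2
        # pixel with D ~ 0 -> Q ~ H
        far = Q.values[0, -1]
        assert far == pytest.approx(1.0 * (1 - D.values[0, -1] ** 2.5 / (D.values[0, -1] ** 2.5 + k**2.5)))
        # construct a pixel exactly at D = k
        D2 = Grid(np.full(lu.shape, k), lu.cell_size)
        D2.values[0, 0] = 2 * k  # preserve the max so the half-sat point stays k
        Q2 = habitat_quality(lu, D2, hp)
        assert Q2.values[0, 1] == pytest.approx(0.5, rel=1e-12)

    def test_quality_monotone_in_degradation(self, habitat_setup):
        lu, hp = habitat_setup
        D = habitat_degradation(lu, hp)
        Q = habitat_quality(lu, D, hp)
        row_d = D.values[0, 1:]
        row_q = Q.values[0, 1:]
        order = np.argsort(row_d)
        assert (np.diff(row_q[order]) <= 1e-12).all()

    def test_support_value_mean_equals_baseline(self, habitat_setup):
        lu, hp = habitat_setup
        p = EconomicParams(equivalent_A={"forest": 1.0, "building": 0.0})
        D = habitat_degradation(lu, hp)
        Q = habitat_quality(lu, D, hp)
        sh = habitat_support_value(Q, lu, p)
        vb = biodiversity_baseline(lu, p)
        assert sh.values.mean() == pytest.approx(vb)

    def test_baseline_single_class_arithmetic(self):
        lu = LandUseGrid(np.ones((2, 2), np.int16), {1: "forest"}, 100.0)
        p = EconomicParams(equivalent_A={"forest": 1.0}, grain_yield=6000.0, grain_price=2.5)
        assert biodiversity_baseline(lu, p) == pytest.approx(6000 * 2.5 / 7)  # 2142.857

    def test_uniform_quality_gives_uniform_value(self):
        lu = LandUseGrid(np.ones((3, 3), np.int16), {1: "forest"}, 100.0)
        p = EconomicParams(equivalent_A={"forest": 2.0})
        Q = Grid(np.full((3, 3), 0.8), 100.0)
        sh = habitat_support_value(Q, lu, p)
        vb = biodiversity_baseline(lu, p)
        assert np.allclose(sh.values, vb)


class TestAesthetic:
    def test_no_tourism_correction(self):
        lu = LandUseGrid(np.ones((2, 2), np.int16), {1: "forest"}, 100.0)
        p = EconomicParams(equivalent_L={"forest": 1.0}, tourism_local=1.0, tourism_national=1.0)
        g = landscape_aesthetic_value(lu, p)
        assert g.values[0, 0] == pytest.approx(6000 * 2.5 / 7)

    def test_doubled_tourism_doubles_value(self):
        lu = LandUseGrid(np.ones((2, 2), np.int16), {1: "forest"}, 100.0)
        p1 = EconomicParams(equivalent_L={"forest": 1.0}, tourism_local=1.0)
        p2 = EconomicParams(equivalent_L={"forest": 1.0}, tourism_local=2.0)
        assert np.allclose(
            landscape_aesthetic_value(lu, p2).values,
            2 * landscape_aesthetic_value(lu, p1).values,
        )

    def test_zero_factors_zero_value(self, farm_lu):
        p = EconomicParams(equivalent_L={"dry farm": 0.0, "forest": 0.0})
        assert (landscape_aesthetic_value(farm_lu, p).values == 0).all()

    def test_missing_factor_errors(self, farm_lu):
        p = EconomicParams(equivalent_L={"dry farm": 0.1})
        with pytest.raises(ValueError, match="forest"):
            landscape_aesthetic_value(farm_lu, p)

    def test_class_resolved_agrees_in_mean(self, farm_lu):
        p = EconomicParams(equivalent_L={"dry farm": 0.1, "forest": 1.2}, tourism_local=1.5)
        uni = landscape_aesthetic_value(farm_lu, p, class_resolved=False)
        res = landscape_aesthetic_value(farm_lu, p, class_resolved=True)
        assert res.values.mean() == pytest.approx(uni.values.mean())


class TestTotals:
    def test_uniform_service_total_equals_per_ha_value(self):
        # one hectare = one 100 m pixel
        lu = LandUseGrid(np.ones((1, 1), np.int16), {1: "forest"}, 100.0)
        z = Grid(np.zeros((1, 1)), 100.0)
        sg = ServiceGrids(const(500.0, (1, 1)), z, z, z, z, z)
        out = total_esv(sg, lu)
        assert out["by_service"].loc["TOTAL", "total_cny"] == pytest.approx(500.0)

    def test_shares_sum_to_100(self, farm_lu):
        rng = np.random.default_rng(5)
        gs = [Grid(rng.random((4, 4)) * 1000, 100.0) for _ in range(6)]
        out = total_esv(ServiceGrids(*gs), farm_lu)
        for key in ("by_service", "by_class"):
            shares = out[key]["share_pct"].drop("TOTAL")
            assert shares.sum() == pytest.approx(100.0, abs=0.02)

    def test_total_is_pixelwise_sum(self, farm_lu):
        rng = np.random.default_rng(6)
        gs = [Grid(rng.random((4, 4)), 100.0) for _ in range(6)]
        sg = ServiceGrids(*gs)
        assert np.allclose(sg.total.values, sum(g.values for g in gs))


class TestPriceHomogeneity:
    def test_services_scale_linearly_with_prices(self, farm_lu):
        base = EconomicParams(
            food_items={"dry farm": [FoodItem(5.0, 2.0, 0.4)], "forest": []},
            carbon_cost=100.0, oxygen_cost=50.0, reservoir_cost=6.0,
            equivalent_A={"dry farm": 0.2, "forest": 2.5},
            equivalent_L={"dry farm": 0.1, "forest": 1.2},
        )
        double = EconomicParams(
            food_items={"dry farm": [FoodItem(5.0, 4.0, 0.4)], "forest": []},
            carbon_cost=200.0, oxygen_cost=100.0, reservoir_cost=12.0,
            grain_price=2 * base.grain_price,
            equivalent_A=base.equivalent_A, equivalent_L=base.equivalent_L,
        )
        assert np.allclose(
            food_production_value(farm_lu, double).values,
            2 * food_production_value(farm_lu, base).values,
        )
        assert np.allclose(
            npp_value(const(1.5), double).values, 2 * npp_value(const(1.5), base).values
        )
        assert np.allclose(
            water_conservation_value(const(10.0), double).values,
            2 * water_conservation_value(const(10.0), base).values,
        )
        assert np.allclose(
            landscape_aesthetic_value(farm_lu, double).values,
            2 * landscape_aesthetic_value(farm_lu, base).values,
        )
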