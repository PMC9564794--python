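import numpy as np
import pandas as pd
import pytest

from esbundles import (
    CropParams,
    FloodParams,
    GridSpec,
    HeatParams,
    Pm25Params,
    RecreationParams,
    WaterParams,
    crop_demand,
    crop_supply,
    flood_demand,
    flood_supply,
    heat_demand,
    heat_supply,
    layer_from_array,
    pm25_demand,
    pm25_supply,
    quantify_all,
    recreation_demand,
    recreation_supply,
    vci,
    water_demand,
    water_retention_supply,
    water_yield,
)
from esbundles.grid import ZoneRaster
from esbundles.services import (
    BUILTUP,
    CULTIVATED,
    DegenerateInputError,
    FOREST,
    GRASSLAND,
    WATER,
)

import oracles


def grid(n=2, m=2):
    return GridSpec(n, m)


def const_layer(spec, value, units=""):
    return layer_from_array(spec, np.full(spec.shape, float(value)), units)


# ---------------------------------------------------------------------------
# crop production
# ---------------------------------------------------------------------------

class TestCrop:
    def test_vci_endpoints_and_midpoint(self):
        spec = GridSpec(1, 3)
        ndvi = layer_from_array(spec, np.array([[0.2, 0.5, 0.8]]))
        out = vci(ndvi, np.array([[True, True, True]]))
        np.testing.assert_allclose(out.values[0], [0.0, 0.5, 1.0])

    def test_vci_range_over_cultivated_mask_only(self):
        spec = GridSpec(1, 3)
        ndvi = layer_from_array(spec, np.array([[0.2, 0.5, 0.9]]))
        out = vci(ndvi, np.array([[True, True, False]]))
        np.testing.assert_allclose(out.values[0, :2], [0.0, 1.0])
        assert out.values[0, 2] == out.nodata

    def test_vci_constant_ndvi_is_degenerate(self):
        ndvi = const_layer(grid(), 0.5)
        with pytest.raises(DegenerateInputError):
            vci(ndvi, np.ones((2, 2), bool))

    def test_supply_proportional_to_vci(self):
        spec = GridSpec(1, 2)
        v = layer_from_array(spec, np.array([[1.0, 3.0]]))
        out = crop_supply(v, CropParams(total_production=4.0))
        np.testing.assert_allclose(out.values[0], [1.0, 3.0])

    def test_uniform_vci_splits_evenly_and_conserves_total(self):
        spec = GridSpec(10, 10)
        out = crop_supply(const_layer(spec, 0.37), CropParams())
        np.testing.assert_allclose(out.values, 2.09e6 / 100)
        assert abs(out.values.sum() - 2.09e6) <= 1e-9 * 2.09e6

    def test_demand_per_capita_and_linearity(self):
        spec = GridSpec(1, 2)
        pop = layer_from_array(spec, np.array([[100.0, 200.0]]))
        out = crop_demand(pop, CropParams())
        np.testing.assert_allclose(out.values[0], [12.21, 24.42])

    def test_negative_population_rejected(self):
        with pytest.raises(ValueError):
            crop_demand(const_layer(grid(), -1.0), CropParams())


# ---------------------------------------------------------------------------
# water retention
# ---------------------------------------------------------------------------

def make_water_inputs(spec, p, et0, awc_val, lulc_code):
    return (const_layer(spec, p, "mm"), const_layer(spec, et0, "mm"),
            const_layer(spec, awc_val, "mm"),
            layer_from_array(spec, np.full(spec.shape, lulc_code, dtype=int)))


class TestWaterRetention:
    def test_budyko_hand_case_w2_r1(self):
        # dryness R = 1 and w = 2 → AET/P = 3/4, Y = P/4  (forest, Kc = 1)
        params = WaterParams(budyko_z=5.0)
        p = 1000.0
        # w = Z·AWC/P + 1.25 = 2 needs AWC = 0.15·P (with Z = 5)
        layers = make_water_inputs(grid(), p, p, 0.15 * p, FOREST)
        y = water_yield(*layers, params)
        np.testing.assert_allclose(y.values, p / 4.0, rtol=1e-12)

    def test_dry_limit_yield_approaches_precipitation(self):
        params = WaterParams()
        p = 1000.0
        layers = make_water_inputs(grid(), p, 1e-9, 100.0, FOREST)
        y = water_yield(*layers, params)
        np.testing.assert_allclose(y.values, p, rtol=1e-6)

    def test_nonvegetated_aet_is_capped_by_precipitation(self):
        params = WaterParams()
        # built-up Kc = 0.3: AET = min(0.3·2000, 500) = 500 → Y = 0
        layers = make_water_inputs(grid(), 500.0, 2000.0, 100.0, BUILTUP)
        np.testing.assert_allclose(water_yield(*layers, params).values, 0.0)

    def test_runoff_coefficients_from_table(self):
        params = WaterParams()
        p = 800.0
        for code, cj in ((WATER, 0.0), (BUILTUP, 1.0)):
            precip, et0, awc, lulc = make_water_inputs(grid(), p, 900.0, 150.0,
                                                       code)
            y = water_yield(precip, et0, awc, lulc, params)
            wr = water_retention_supply(y, precip, lulc, params)
            np.testing.assert_allclose(wr.values, y.values - p * cj, rtol=1e-12)

    def test_zero_precipitation_on_water_keeps_wr_equal_to_yield(self):
        params = WaterParams()
        precip, et0, awc, lulc = make_water_inputs(grid(), 0.0, 900.0, 150.0,
                                                   WATER)
        y = water_yield(precip, et0, awc, lulc, params)
        wr = water_retention_supply(y, precip, lulc, params)
        np.testing.assert_allclose(wr.values, y.values)

    def test_negative_retention_propagates_unless_clamped(self):
        p = 800.0
        precip, et0, awc, lulc = make_water_inputs(grid(), p, 900.0, 150.0,
                                                   BUILTUP)
        y = water_yield(precip, et0, awc, lulc, WaterParams())
        wr = water_retention_supply(y, precip, lulc, WaterParams())
        assert (wr.values < 0).all()
        clamped = water_retention_supply(
            y, precip, lulc, WaterParams(clamp_negative_retention=True))
        assert (clamped.values == 0).all()

    def test_nonpositive_precip_on_vegetated_rejected(self):
        layers = make_water_inputs(grid(), 0.0, 900.0, 150.0, FOREST)
        with pytest.raises(ValueError, match="precipitation"):
            water_yield(*layers, WaterParams())

    def test_demand_uniform_spread_and_conservation(self):
        spec = GridSpec(2, 10)
        lulc = np.full(spec.shape, WATER, dtype=int)
        lulc[0, :] = CULTIVATED  # 10 cultivated pixels, all in zone 1
        zone = ZoneRaster(spec, np.ones(spec.shape, dtype=int), "village")
        table = pd.DataFrame([{"zone_id": 1, "agricultural": 900.0,
                               "industrial": 0.0, "ecological": 0.0}])
        out = water_demand(layer_from_array(spec, lulc),
                           const_layer(spec, 0.0), table, zone, WaterParams())
        np.testing.assert_allclose(out.values[0, :], 90.0)
        np.testing.assert_allclose(out.values[1, :], 0.0)
        assert abs(out.values.sum() - 900.0) < 1e-9

    def test_demand_zero_population_zero_table(self):
        spec = grid()
        lulc = layer_from_array(spec, np.full(spec.shape, CULTIVATED, int))
        zone = ZoneRaster(spec, np.ones(spec.shape, int), "village")
        table = pd.DataFrame([{"zone_id": 1, "agricultural": 0.0,
                               "industrial": 0.0, "ecological": 0.0}])
        out = water_demand(lulc, const_layer(spec, 0.0), table, zone,
                           WaterParams())
        np.testing.assert_allclose(out.values, 0.0)

    def test_demand_without_target_pixels_names_the_zone(self):
        spec = grid()
        lulc = layer_from_array(spec, np.full(spec.shape, WATER, int))
        zone = ZoneRaster(spec, np.ones(spec.shape, int), "village")
        table = pd.DataFrame([{"zone_id": 1, "agricultural": 100.0,
                               "industrial": 0.0, "ecological": 0.0}])
        with pytest.raises(ValueError, match="subdistrict 1"):
            water_demand(lulc, const_layer(spec, 0.0), table, zone,
                         WaterParams())


# ---------------------------------------------------------------------------
# PM2.5 reduction
# ---------------------------------------------------------------------------

class TestPm25:
    def test_supply_matches_hand_flux(self):
        # Ch = 50 μg/m³ → F = 1.62e-4 g/(m²·h); one forest pixel, LAI = 2
        spec = GridSpec(1, 1)
        params = Pm25Params(non_rainy_days=245)
        out = pm25_supply(const_layer(spec, 50.0),
                          const_layer(spec, 2.0),
                          layer_from_array(spec, np.array([[FOREST]])), params)
        f = 1.62e-4
        expected = 245 * f * (900 * 2.0) * 24 * (1 - 0.03)
        np.testing.assert_allclose(out.values[0, 0], expected, rtol=1e-12)

    def test_supply_zero_for_zero_lai_and_nonforest(self):
        spec = GridSpec(1, 2)
        lulc = layer_from_array(spec, np.array([[FOREST, CULTIVATED]]))
        out = pm25_supply(const_layer(spec, 50.0),
                          layer_from_array(spec, np.array([[0.0, 3.0]])),
                          lulc, Pm25Params())
        np.testing.assert_array_equal(out.values, [[0.0, 0.0]])

    @pytest.mark.parametrize("conc,expected", [
        (10.0, 0.0),                 # at the guideline: no demand
        (9.99, 0.0),                 # below threshold
        (11.0, 1.5768e9),            # 1 μg excess × 200 m × 900 m² × 8760 h
    ])
    def test_demand_threshold_branches(self, conc, expected):
        out = pm25_demand(const_layer(GridSpec(1, 1), conc), Pm25Params())
        np.testing.assert_allclose(out.values[0, 0], expected, rtol=1e-12)

    def test_demand_nondecreasing_in_concentration(self):
        spec = GridSpec(1, 50)
        conc = layer_from_array(spec, np.linspace(0, 60, 50)[None, :])
        out = pm25_demand(conc, Pm25Params())
        assert (np.diff(out.values[0]) >= 0).all()

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            pm25_supply(const_layer(grid(), -1.0), const_layer(grid(), 1.0),
                        layer_from_array(grid(), np.full((2, 2), FOREST, int)),
                        Pm25Params())


# ---------------------------------------------------------------------------
# flood mitigation
# ---------------------------------------------------------------------------

def fm_for(lulc_code, hsg_code, storm=100.0):
    spec = GridSpec(1, 1)
    out = flood_supply(
        layer_from_array(spec, np.array([[lulc_code]])),
        layer_from_array(spec, np.array([[hsg_code]])),
        FloodParams(design_storm=storm))
    return float(out.values[0, 0])


class TestFlood:
    def test_cn100_means_all_runoff(self):
        params = FloodParams(design_storm=100.0,
                             cn_table={**FloodParams().cn_table, 1: (100,) * 4})
        spec = GridSpec(1, 1)
        out = flood_supply(layer_from_array(spec, np.array([[CULTIVATED]])),
                           layer_from_array(spec, np.array([[1]])), params)
        assert out.values[0, 0] == 0.0

    def test_water_cn0_means_full_retention(self):
        assert fm_for(WATER, 1) == 1.0

    def test_builtup_hsg_a_storm_100mm_hand_value(self):
        # CN = 85 → I ≈ 44.82 mm, Rp ≈ 61.0 mm, FM ≈ 0.390
        assert fm_for(BUILTUP, 1) == pytest.approx(0.390, abs=1e-3)

    def test_small_storm_below_initial_abstraction_gives_fm_1(self):
        # forest on HSG A: CN = 36 → 0.2·I ≈ 90 mm > 50 mm storm
        assert fm_for(FOREST, 1, storm=50.0) == 1.0

    def test_fm_strictly_decreases_with_cn(self):
        # cultivated across soil groups A→D has CN 54→84
        fms = [fm_for(CULTIVATED, g) for g in (1, 2, 3, 4)]
        assert all(a > b for a, b in zip(fms, fms[1:]))

    def test_demand_scores_from_impervious_density(self):
        spec = GridSpec(1, 4)
        lulc = layer_from_array(spec, np.array(
            [[BUILTUP, FOREST, CULTIVATED, BUILTUP]]))
        imperv = layer_from_array(spec, np.array([[0.9, 0.0, 0.1, 0.1]]))
        pop = const_layer(spec, 10.0)
        out = flood_demand(pop, const_layer(spec, 2.0), const_layer(spec, 1.0),
                           imperv, lulc, FloodParams())
        # high-density developed pixel (score 8) has the top demand,
        # forest (score 1) the lowest
        assert out.values[0, 0] == 1.0
        assert out.values[0, 1] == 0.0
        assert (out.values >= 0).all() and (out.values <= 1).all()

    def test_uniform_inputs_degenerate_to_zero_with_warning(self):
        spec = grid()
        lulc = layer_from_array(spec, np.full(spec.shape, FOREST, int))
        with pytest.warns(UserWarning, match="constant field"):
            out = flood_demand(const_layer(spec, 5.0), const_layer(spec, 1.0),
                               const_layer(spec, 1.0), const_layer(spec, 0.0),
                               lulc, FloodParams())
        np.testing.assert_allclose(out.values, 0.0)


# ---------------------------------------------------------------------------
# heat mitigation
# ---------------------------------------------------------------------------

class TestHeat:
    def test_cc_hand_value(self):
        # forest shade 1, albedo 0.2; ET0 = 0.5·ETmax with Kc = 1 → CC = 0.74.
        # On a pure-forest grid, HM = CC (pixel is its own green patch).
        spec = GridSpec(2, 2)
        et0 = layer_from_array(spec, np.array([[500.0, 1000.0],
                                               [500.0, 500.0]]))
        lulc = layer_from_array(spec, np.full(spec.shape, FOREST, int))
        params = HeatParams(large_green_area=900.0)
        out = heat_supply(lulc, et0, params)
        assert out.values[0, 0] == pytest.approx(0.74, rel=1e-12)

    def test_no_green_within_reach_keeps_own_cc(self):
        spec = GridSpec(3, 3)
        lulc = layer_from_array(spec, np.full(spec.shape, BUILTUP, int))
        out = heat_supply(lulc, const_layer(spec, 800.0), HeatParams())
        # built-up: shade 0, Kc 0.3, albedo 0.15 → CC = 0.2·0.3 + 0.2·0.15
        np.testing.assert_allclose(out.values, 0.6 * 0 + 0.2 * 0.3 + 0.2 * 0.15)

    def test_small_cool_pixel_takes_park_cooling(self):
        # one built-up pixel inside a big forest: CCpark > CC(built-up)
        spec = GridSpec(9, 9)
        lulc_arr = np.full(spec.shape, FOREST, int)
        lulc_arr[4, 4] = BUILTUP
        out = heat_supply(layer_from_array(spec, lulc_arr),
                          const_layer(spec, 800.0), HeatParams())
        cc_built = 0.2 * 0.3 + 0.2 * 0.15
        assert out.values[4, 4] > cc_built

    def test_hm_bounded(self, landscape_200):
        stack, _ = landscape_200
        out = heat_supply(stack["lulc"], stack["pet"], HeatParams())
        v = out.values[out.mask]
        assert (v >= 0).all() and (v <= 1).all()

    def test_demand_zero_at_reference_and_midpoint_half(self):
        spec = GridSpec(1, 4)
        # cultivated reference pixels at 20 °C; others at +5 and +10
        lst = layer_from_array(spec, np.array([[20.0, 20.0, 25.0, 30.0]]))
        cult = np.array([[True, True, False, False]])
        out = heat_demand(lst, cult)
        np.testing.assert_allclose(out.values[0], [0.0, 0.0, 0.5, 1.0])

    def test_demand_zero_when_everything_cooler(self):
        spec = GridSpec(1, 3)
        lst = layer_from_array(spec, np.array([[25.0, 20.0, 15.0]]))
        cult = np.array([[True, False, False]])
        with pytest.warns(UserWarning, match="constant field"):
            out = heat_demand(lst, cult)
        np.testing.assert_allclose(out.values, 0.0)

    def test_printed_mode_keeps_literal_inequalities(self):
        spec = GridSpec(1, 3)
        lst = layer_from_array(spec, np.array([[20.0, 15.0, 25.0]]))
        cult = np.array([[True, False, False]])
        out = heat_demand(lst, cult, mode="printed")
        # in printed mode only the pixel cooler than cropland scores;
        # min-max then puts it at 0 and the rest at 1
        np.testing.assert_allclose(out.values[0], [1.0, 0.0, 1.0])

    def test_empty_cultivated_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            heat_demand(const_layer(grid(), 20.0), np.zeros((2, 2), bool))


# ---------------------------------------------------------------------------
# landscape recreation
# ---------------------------------------------------------------------------

class TestRecreation:
    def test_zone_green_fraction(self):
        spec = GridSpec(2, 2)
        lulc = layer_from_array(
            spec, np.array([[FOREST, CULTIVATED], [WATER, BUILTUP]]))
        zones = ZoneRaster(spec, np.ones(spec.shape, int), "village")
        out = recreation_supply(lulc, zones)
        np.testing.assert_allclose(out.values, 0.25)

    @pytest.mark.parametrize("code,expected", [(FOREST, 1.0), (BUILTUP, 0.0),
                                               (GRASSLAND, 1.0)])
    def test_endpoints(self, code, expected):
        spec = grid()
        lulc = layer_from_array(spec, np.full(spec.shape, code, int))
        zones = ZoneRaster(spec, np.ones(spec.shape, int), "village")
        np.testing.assert_allclose(
            recreation_supply(lulc, zones).values, expected)

    def test_demand_hand_value_and_linearity(self):
        spec = GridSpec(1, 2)
        dens = layer_from_array(spec, np.array([[0.0013, 0.0026]]))
        out = recreation_demand(dens, RecreationParams())
        np.testing.assert_allclose(out.values[0], [0.0169, 0.0338])
        assert out.values[0, 1] == pytest.approx(2 * out.values[0, 0])

    def test_zero_density_gives_zero(self):
        out = recreation_demand(const_layer(grid(), 0.0), RecreationParams())
        np.testing.assert_allclose(out.values, 0.0)


# ---------------------------------------------------------------------------
# oracle equivalence: vectorized pipeline vs independent scalar reference
# ---------------------------------------------------------------------------

class TestScalarOracleEquivalence:
    N = 1000
    RTOL = 1e-12

    def test_budyko_yield_and_retention(self, rng):
        params = WaterParams()
        spec = GridSpec(1, self.N)
        p = rng.uniform(200, 2000, self.N)
        et0 = rng.uniform(100, 1500, self.N)
        awc = rng.uniform(50, 250, self.N)
        codes = rng.integers(1, 7, self.N)
        y = water_yield(layer_from_array(spec, p[None]),
                        layer_from_array(spec, et0[None]),
                        layer_from_array(spec, awc[None]),
                        layer_from_array(spec, codes[None]), params)
        wr = water_retention_supply(
            y, layer_from_array(spec, p[None]),
            layer_from_array(spec, codes[None]), params)
        for i in range(self.N):
            c = int(codes[i])
            y_ref = oracles.budyko_yield_scalar(
                p[i], et0[i], awc[i], params.kc[c], params.budyko_z,
                bool(params.veg[c]))
            np.testing.assert_allclose(y.values[0, i], y_ref, rtol=self.RTOL)
            wr_ref = oracles.water_retention_scalar(y_ref, p[i],
                                                    params.runoff_coef[c])
            np.testing.assert_allclose(wr.values[0, i], wr_ref,
                                       rtol=self.RTOL, atol=1e-9)

    def test_pm25_supply_and_demand(self, rng):
        params = Pm25Params()
        spec = GridSpec(1, self.N)
        conc = rng.uniform(0, 80, self.N)
        lai = rng.uniform(0, 8, self.N)
        codes = rng.integers(1, 7, self.N)
        sup = pm25_supply(layer_from_array(spec, conc[None]),
                          layer_from_array(spec, lai[None]),
                          layer_from_array(spec, codes[None]), params)
        dem = pm25_demand(layer_from_array(spec, conc[None]), params)
        for i in range(self.N):
            s_ref = oracles.pm25_supply_scalar(
                conc[i], lai[i], 900.0, params.deposition_velocity,
                params.resuspension, 24.0, params.non_rainy_days,
                int(codes[i]) == FOREST)
            d_ref = oracles.pm25_demand_scalar(conc[i], 10.0, 200.0, 900.0)
            np.testing.assert_allclose(sup.values[0, i], s_ref, rtol=self.RTOL)
            np.testing.assert_allclose(dem.values[0, i], d_ref, rtol=self.RTOL)

    def test_flood_supply_against_scalar_cn(self, rng):
        params = FloodParams(design_storm=100.0)
        spec = GridSpec(1, self.N)
        codes = rng.integers(1, 7, self.N)
        hsg = rng.integers(1, 5, self.N)
        out = flood_supply(layer_from_array(spec, codes[None]),
                           layer_from_array(spec, hsg[None]), params)
        for i in range(self.N):
            cn = params.cn_table[int(codes[i])][int(hsg[i]) - 1]
            ref = oracles.flood_supply_scalar(cn, 100.0)
            np.testing.assert_allclose(out.values[0, i], ref, rtol=self.RTOL)

    def test_crop_and_recreation_linear_forms(self, rng):
        spec = GridSpec(1, self.N)
        pop = rng.uniform(0, 500, self.N)
        dens = rng.uniform(0, 0.01, self.N)
        cd = crop_demand(layer_from_array(spec, pop[None]), CropParams())
        rd = recreation_demand(layer_from_array(spec, dens[None]),
                               RecreationParams())
        for i in range(self.N):
            np.testing.assert_allclose(
                cd.values[0, i], oracles.crop_demand_scalar(pop[i], 0.1221),
                rtol=self.RTOL)
            np.testing.assert_allclose(
                rd.values[0, i], oracles.recreation_demand_scalar(dens[i], 13.0),
                rtol=self.RTOL)

    def test_cooling_capacity_against_scalar(self, rng):
        params = HeatParams()
        spec = GridSpec(1, self.N)
        codes = rng.integers(1, 7, self.N)
        et0 = rng.uniform(100, 1200, self.N)
        lulc = layer_from_array(spec, codes[None])
        # all-green table so every pixel keeps its own CC (g=1, 1-pixel rows
        # can't beat their own park average in a pure row of themselves) —
        # instead compare via a params clone with the park step neutralized
        out = heat_supply(lulc, layer_from_array(spec, et0[None]),
                          HeatParams(green={c: 0 for c in range(1, 7)}))
        etmax = et0.max()
        for i in range(self.N):
            c = int(codes[i])
            ref = oracles.cooling_capacity_scalar(
                params.shade[c], params.kc[c], et0[i], etmax, params.albedo[c])
            np.testing.assert_allclose(out.values[0, i], ref, rtol=self.RTOL)


# ---------------------------------------------------------------------------
# whole-stack bounds, masks, conservation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def services(landscape_200, zones_200):
    stack, _ = landscape_200
    return quantify_all(stack, zones_200["village"]), stack


class TestStackLevelInvariants:

    def test_bounded_indices(self, services):
        svc, _ = services
        bounded = [svc["FM"].supply, svc["FM"].demand, svc["HM"].supply,
                   svc["HM"].demand, svc["LR"].supply]
        for layer in bounded:
            v = layer.values[layer.mask]
            assert (v >= 0).all() and (v <= 1).all()
        # recreation demand (m²/m² wanted per m² of land) is nonnegative but
        # may exceed 1 where residents outnumber what the pixel can host
        d = svc["LR"].demand
        assert (d.values[d.mask] >= 0).all()

    def test_crop_total_conserved(self, services):
        svc, _ = services
        total = svc["CP"].supply.values[svc["CP"].supply.mask].sum()
        assert abs(total - 2.09e6) <= 1e-9 * 2.09e6

    def test_supply_masks(self, services):
        svc, stack = services
        lulc = stack["lulc"].values
        cp = svc["CP"].supply.values
        assert (cp[lulc != CULTIVATED] == 0).all()
        pr = svc["PR"].supply.values
        assert (pr[lulc != FOREST] == 0).all()
        assert (pr[lulc == FOREST] > 0).any()

    def test_water_demand_conserves_table_totals(self, services, landscape_200,
                                                 zones_200):
        svc, stack = services
        table = stack.tables["water_use"]
        vz = zones_200["village"].zone_ids
        dom = stack["population"].values.sum() * WaterParams().per_capita_domestic
        expected = table[["agricultural", "industrial", "ecological"]].sum().sum()
        assert svc["WR"].demand.values.sum() == pytest.approx(dom + expected,
                                                              rel=1e-9)
        # and per-subdistrict: total demand minus domestic equals table row sum
        wc = WaterParams().per_capita_domestic
        for _, row in table.head(8).iterrows():
            m = vz == row["zone_id"]
            allocated = (svc["WR"].demand.values[m].sum()
                         - stack["population"].values[m].sum() * wc)
            assert allocated == pytest.approx(
                row[["agricultural", "industrial", "ecological"]].sum(),
                rel=1e-9)

    def test_yield_fraction_strictly_inside_unit_interval_on_vegetated(
            self, landscape_200):
        stack, _ = landscape_200
        y = water_yield(stack["precipitation"], stack["pet"], stack["awc"],
                        stack["lulc"], WaterParams())
        veg = np.isin(stack["lulc"].values, (CULTIVATED, FOREST, GRASSLAND))
        ratio = 1 - y.values[veg] / stack["precipitation"].values[veg]
        assert (ratio > 0).all() and (ratio < 1).all()
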