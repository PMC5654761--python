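"""Grid model: aggregation, decade matching, areas, scaling, I/O."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from eidhotspots.grid import (DECADES, GridSpec, Layer, PredictorSet,
                              band_area_km2, change_interval_for_year,
                              diff_decades, layer_from_tiff, layer_to_tiff,
                              layers_from_csv, layers_to_csv, match_decade,
                              rescale_to_grid, sd_scale, sum_headcounts,
                              EARTH_RADIUS_KM)


def small_grid(n_lon=4, n_lat=2, mask=None):
    return GridSpec(n_lon=n_lon, n_lat=n_lat, land_mask=mask)


class TestRescale:
    def test_2x2_block_sum(self):
        grid = small_grid(1, 1)
        fine = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert rescale_to_grid(fine, grid, "sum").values[0, 0] == 10.0

    @pytest.mark.parametrize("method", ["sum", "mean"])
    def test_identity_at_native_resolution(self, method):
        grid = small_grid()
        vals = np.arange(8.0).reshape(2, 4)
        out = rescale_to_grid(vals, grid, method)
        np.testing.assert_array_equal(out.values, vals)

    @pytest.mark.parametrize("method", ["sum", "mean"])
    def test_matches_nested_loop_oracle(self, method):
        rng = np.random.default_rng(0)
        grid = small_grid(6, 3)
        factor = 4
        fine = rng.normal(size=(3 * factor, 6 * factor))
        fine[rng.random(fine.shape) < 0.1] = np.nan
        out = rescale_to_grid(fine, grid, method).values
        # independent brute-force block loop
        for i in range(3):
            for j in range(6):
                block = fine[i * factor:(i + 1) * factor,
                             j * factor:(j + 1) * factor].ravel()
                ok = np.isfinite(block)
                if method == "sum":
                    expect = block[ok].sum()
                else:
                    expect = block[ok].mean() if ok.any() else np.nan
                assert out[i, j] == pytest.approx(expect, rel=1e-12)

    def test_sum_conserves_global_total(self):
        rng = np.random.default_rng(1)
        grid = small_grid(8, 4)
        fine = rng.exponential(size=(4 * 5, 8 * 5))
        out = rescale_to_grid(fine, grid, "sum")
        assert out.values.sum() == pytest.approx(fine.sum(), rel=1e-12)

    def test_non_integer_factor_rejected(self):
        grid = small_grid(4, 2)
        with pytest.raises(ValueError, match="non-integer aggregation"):
            rescale_to_grid(np.zeros((3, 6)), grid, "sum")


class TestDecades:
    def test_diff_consecutive(self):
        a = Layer("pasture", np.array([[0.30]]), "1990")
        b = Layer("pasture", np.array([[0.42]]), "2000")
        ch = diff_decades(b, a)
        assert ch.values[0, 0] == pytest.approx(0.12)
        assert ch.temporal == "1990-2000"

    def test_identical_layers_give_zero_change(self):
        vals = np.random.default_rng(2).normal(size=(2, 4))
        ch = diff_decades(Layer("x", vals, "1980"), Layer("x", vals, "1970"))
        np.testing.assert_array_equal(ch.values, np.zeros((2, 4)))

    def test_random_layers_match_subtraction(self):
        rng = np.random.default_rng(3)
        v1, v2 = rng.normal(size=(2, 2, 4))
        ch = diff_decades(Layer("x", v2, "1990"), Layer("x", v1, "1980"))
        np.testing.assert_allclose(ch.values, v2 - v1)

    def test_name_and_gap_errors(self):
        a = Layer("x", np.zeros((1, 1)), "1970")
        with pytest.raises(ValueError, match="different names"):
            diff_decades(Layer("y", np.zeros((1, 1)), "1980"), a)
        with pytest.raises(ValueError, match="not consecutive"):
            diff_decades(Layer("x", np.zeros((1, 1)), "1990"), a)

    def test_mid_decade_years_round_up(self):
        assert match_decade(1975) == 1980
        assert match_decade(1985) == 1990

    def test_decade_years_are_fixed_points(self):
        for d in DECADES:
            assert match_decade(d) == d

    def test_full_table_against_enumeration_oracle(self):
        # brute force: nearest decade, ties up, clamp to 2000
        for year in range(1970, 2009):
            dists = {d: abs(year - d) for d in DECADES}
            mind = min(dists.values())
            candidates = [d for d, v in dists.items() if v == mind]
            assert match_decade(year) == max(candidates)

    def test_pre_1970_rejected(self):
        with pytest.raises(ValueError):
            match_decade(1969)

    def test_change_interval_mapping(self):
        assert change_interval_for_year(1972) == "1970-1980"
        assert change_interval_for_year(1975) == "1970-1980"
        assert change_interval_for_year(1988) == "1980-1990"
        assert change_interval_for_year(2005) == "1990-2000"


class TestCellArea:
    def test_matches_quadrature_oracle(self):
        val = band_area_km2(0.0, 1.0, 1.0)
        oracle, _ = quad(lambda phi: EARTH_RADIUS_KM ** 2
                         * math.radians(1.0) * math.cos(phi),
                         0.0, math.radians(1.0))
        assert val == pytest.approx(oracle, rel=1e-10)

    def test_strictly_decreasing_toward_poles(self):
        areas = [band_area_km2(b, b + 1.0, 1.0) for b in range(0, 89)]
        assert all(a > b for a, b in zip(areas, areas[1:]))
        assert all(a > 0 for a in areas)

    def test_hemispheric_symmetry(self):
        for b in (0, 15, 40, 77):
            north = band_area_km2(b, b + 1, 1.0)
            south = band_area_km2(-(b + 1), -b, 1.0)
            assert north == pytest.approx(south, rel=1e-12)

    def test_total_sphere_area(self, one_deg_grid):
        total = one_deg_grid.cell_area.sum()
        assert total == pytest.approx(4 * math.pi * EARTH_RADIUS_KM ** 2,
                                      rel=1e-9)

    def test_masked_land_area_matches_analytic_fraction(self):
        # mask = tropics band; analytic area = 2π R² (sinφ1 − sinφ0) · full lon
        grid = GridSpec(n_lon=36, n_lat=18)
        mask = np.zeros(grid.shape, dtype=bool)
        mask[8:10, :] = True  # −10°..10°
        masked_area = grid.cell_area[mask].sum()
        analytic = (2 * math.pi * EARTH_RADIUS_KM ** 2
                    * (math.sin(math.radians(10)) - math.sin(math.radians(-10))))
        assert masked_area == pytest.approx(analytic, rel=0.01)


class TestHeadcountsAndScaling:
    def test_two_layer_sum_and_identity(self):
        a = Layer("cattle", np.array([[1.0, 2.0]]), "static")
        b = Layer("pigs", np.array([[3.0, 4.0]]), "static")
        np.testing.assert_array_equal(sum_headcounts([a, b]).values,
                                      [[4.0, 6.0]])
        np.testing.assert_array_equal(sum_headcounts([a]).values, a.values)

    def test_five_random_layers_match_loop_oracle(self):
        rng = np.random.default_rng(4)
        layers = [Layer(f"l{i}", rng.exponential(size=(3, 5)), "static")
                  for i in range(5)]
        layers[0].values[0, 0] = np.nan  # missing treated as 0
        out = sum_headcounts(layers).values
        expect = np.zeros((3, 5))
        for lay in layers:
            expect += np.nan_to_num(lay.values)
        np.testing.assert_allclose(out, expect)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            sum_headcounts([])

    def test_sd_scale_constant_layer_degenerates_to_zero(self):
        out = sd_scale(np.full((2, 3), 7.0))
        np.testing.assert_array_equal(out, np.zeros((2, 3)))

    def test_sd_scale_bounded_and_matches_zscore_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(2.0, 5.0, size=(10, 10))
        vals[0, 0] = np.nan
        out = sd_scale(vals, k=2.5)
        assert np.nanmax(np.abs(out)) <= 2.5
        assert np.isnan(out[0, 0])
        finite = np.isfinite(vals)
        z = (vals[finite] - vals[finite].mean()) / vals[finite].std()
        np.testing.assert_allclose(out[finite], np.clip(z, -2.5, 2.5))


class TestPredictorSet:
    def build(self):
        ps = PredictorSet()
        for d in DECADES:
            ps.add(Layer("pop", np.full((2, 4), float(d)), str(d)))
        ps.add(Layer("forest", np.ones((2, 4)), "static"))
        for d0, d1 in zip(DECADES[:-1], DECADES[1:]):
            ps.add(Layer("pop_change", np.full((2, 4), float(d1)),
                         f"{d0}-{d1}"))
        return ps

    def test_resolution_rules(self):
        ps = self.build()
        assert ps.resolve("pop", 1975).values[0, 0] == 1980
        assert ps.resolve("pop", 2004).values[0, 0] == 2000
        assert ps.resolve("forest", 1971).values[0, 0] == 1.0
        assert ps.resolve("pop_change", 1972).temporal == "1970-1980"
        assert ps.resolve("pop_change", 2008).temporal == "1990-2000"

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            self.build().resolve("nope", 2000)

    def test_decade_set_invariant(self):
        ps = self.build()
        ps.validate()
        ps.add(Layer("cropland", np.ones((2, 4)), "1970"))
        with pytest.raises(ValueError, match="different decade sets"):
            ps.validate()

    def test_complete_mask_excludes_any_missing(self):
        ps = self.build()
        grid = GridSpec(n_lon=4, n_lat=2)
        lay = ps.layers_for("forest")["static"]
        lay.values[1, 2] = np.nan
        mask = ps.complete_mask(grid)
        assert not mask[1, 2] and mask.sum() == 7


class TestIO:
    def test_csv_roundtrip_lossless(self, tmp_path):
        rng = np.random.default_rng(6)
        grid = GridSpec(n_lon=8, n_lat=4)
        vals = rng.normal(size=grid.shape)
        vals[0, 0] = np.nan
        layers = [Layer("a", vals, "1990"), Layer("b", vals * 2, "static")]
        path = tmp_path / "layers.csv"
        layers_to_csv(layers, grid, path)
        back = {(l.name, l.temporal): l for l in layers_from_csv(path, grid)}
        for lay in layers:
            got = back[(lay.name, lay.temporal)]
            np.testing.assert_array_equal(got.values, lay.values)

    def test_tiff_roundtrip_lossless(self, tmp_path):
        rng = np.random.default_rng(7)
        lay = Layer("x", rng.normal(size=(4, 8)), "static")
        path = tmp_path / "x.tif"
        layer_to_tiff(lay, path)
        back = layer_from_tiff(path, "x")
        np.testing.assert_array_equal(back.values, lay.values)
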