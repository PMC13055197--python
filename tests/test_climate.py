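"""Climate extraction, seasonal summaries, PCA reduction, hull volumes, CEP."""

import math

import numpy as np
import pytest

import fernexpand as fx
from fernexpand.climate import (ClimateLayerSet, ClimatePartition, ClimateVariable,
                                EnvSample, Grid, MonthlySeries, points_in_hull,
                                summaries_to_layerset)

GRID = Grid(lon_min=0.0, lat_min=0.0, cell_size_deg=1.0, nx=10, ny=8)


def gradient_layers():
    lon_idx = np.tile(np.arange(10, dtype=float), (8, 1))
    lat_idx = np.tile(np.arange(8, dtype=float)[:, None], (1, 10))
    return ClimateLayerSet(grid=GRID, variables=[
        (ClimateVariable("a", "temperature", "air"), lon_idx),
        (ClimateVariable("b", "water", "air"), lat_idx),
    ])


class TestExtractEnv:
    def test_cell_center_returns_cell_value(self):
        sample = fx.extract_env([(3.5, 2.5)], gradient_layers())
        np.testing.assert_allclose(sample.matrix, [[3.0, 2.0]])

    def test_nodata_row_dropped_and_logged(self):
        layers = gradient_layers()
        layers.variables[0][1][2, 3] = np.nan
        sample = fx.extract_env([(3.5, 2.5), (0.5, 0.5)], layers)
        assert sample.matrix.shape == (1, 2)
        assert sample.dropped_rows == [(0, "nodata")]

    def test_outside_extent_dropped(self):
        sample = fx.extract_env([(50.0, 50.0)], gradient_layers())
        assert sample.matrix.shape[0] == 0
        assert sample.dropped_rows == [(0, "outside grid")]

    def test_random_points_match_index_arithmetic(self):
        rng = np.random.default_rng(0)
        pts = list(zip(rng.uniform(0, 10, 50), rng.uniform(0, 8, 50)))
        sample = fx.extract_env(pts, gradient_layers())
        expected = np.array([[np.floor(lon), np.floor(lat)] for lon, lat in pts])
        np.testing.assert_allclose(sample.matrix, expected)


class TestSeasonalSummaries:
    def _series(self, vector, quantity="air_temperature"):
        layers = np.array(vector, dtype=float)[:, None, None] * np.ones((1, 1))
        grid = Grid(0, 0, 1.0, 1, 1)
        return MonthlySeries(quantity=quantity, grid=grid, layers=layers)

    def test_constant_months(self):
        out = fx.derive_seasonal_summaries(self._series([10.0] * 12))
        assert out["annual_mean"][0, 0] == 10.0
        assert out["max_quarter"][0, 0] == 10.0
        assert out["min_quarter"][0, 0] == 10.0
        assert out["annual_range"][0, 0] == 0.0

    def test_precipitation_spike_defines_wettest_quarter_and_range(self):
        months = [100.0] * 12
        months[6] = 400.0  # July
        out = fx.derive_seasonal_summaries(self._series(months, "precipitation"))
        assert out["annual_mean"][0, 0] == sum(months)  # annual total
        assert out["max_quarter"][0, 0] == 600.0  # window containing July
        assert out["annual_range"][0, 0] == 300.0

    @pytest.mark.parametrize("quantity", ["air_temperature", "precipitation"])
    def test_arbitrary_vector_matches_exhaustive_window_oracle(self, quantity):
        rng = np.random.default_rng(1)
        months = rng.uniform(0, 50, 12)
        out = fx.derive_seasonal_summaries(self._series(months, quantity))
        agg = np.sum if quantity == "precipitation" else np.mean
        windows = [agg(months[[q, (q + 1) % 12, (q + 2) % 12]]) for q in range(12)]
        assert out["max_quarter"][0, 0] == pytest.approx(max(windows))
        assert out["min_quarter"][0, 0] == pytest.approx(min(windows))
        assert out["annual_range"][0, 0] == pytest.approx(months.max() - months.min())

    def test_nodata_month_poisons_all_summaries(self):
        months = [10.0] * 12
        months[4] = np.nan
        out = fx.derive_seasonal_summaries(self._series(months))
        assert all(np.isnan(v[0, 0]) for v in out.values())


class TestSelectVariables:
    meta = [
        ClimateVariable("air_t", "temperature", "air"),
        ClimateVariable("soil_t", "temperature", "soil"),
        ClimateVariable("precip", "water", "air"),
        ClimateVariable("soil_w", "water", "soil"),
        ClimateVariable("pet", "temperature_water", "air"),
    ]

    def test_terrestrial_temperature_includes_soil(self):
        names = [v.name for v in fx.select_variables(self.meta, "terrestrial",
                                                     "temperature")]
        assert names == ["air_t", "soil_t"]

    def test_epiphytic_water_excludes_soil(self):
        names = [v.name for v in fx.select_variables(self.meta, "epiphytic", "water")]
        assert names == ["precip"]

    def test_category_all_matches_set_filter_oracle(self):
        got = fx.select_variables(self.meta, "epiphytic", "all")
        assert got == [v for v in self.meta if v.medium != "soil"]

    def test_empty_selection_is_an_error(self):
        with pytest.raises(ValueError, match="no variables"):
            fx.select_variables([self.meta[1]], "epiphytic", "temperature")


class TestHabitSynthesis:
    def _sample(self, soil_t=12.0, air_t=15.0):
        meta = [ClimateVariable("air_temperature_annual_mean", "temperature", "air"),
                ClimateVariable("soil_temperature_annual_mean", "temperature", "soil")]
        mat = np.array([[air_t, soil_t]] * 3)
        return EnvSample(matrix=mat, variable_meta=meta)

    def test_terrestrial_uses_soil_medium(self):
        out = fx.synthesize_habit_environment(self._sample(), "terrestrial")
        assert out["mat"] == 12.0

    def test_epiphytic_uses_air_medium(self):
        out = fx.synthesize_habit_environment(self._sample(), "epiphytic")
        assert out["mat"] == 15.0

    def test_missing_soil_layer_falls_back_to_air_with_warning(self):
        meta = [ClimateVariable("air_temperature_annual_mean", "temperature", "air")]
        sample = EnvSample(matrix=np.full((3, 1), 15.0), variable_meta=meta)
        warnings = []
        out = fx.synthesize_habit_environment(sample, "terrestrial", warnings=warnings)
        assert out["mat"] == 15.0 and warnings

    def test_summary_equals_row_means(self, default_climate):
        scenario = fx.SyntheticScenario(seed=11, n_species=1, n_zero_cep=0)
        recs = fx.simulate_species_occurrences(default_climate, scenario, 0)[:3]
        pts = [(r.longitude, r.latitude) for r in recs]
        sample = fx.extract_env(pts, default_climate.summaries)
        out = fx.synthesize_habit_environment(sample, "epiphytic")
        names = [v.name for v in sample.variable_meta]
        expected = sample.matrix[:, names.index("pet_annual_mean")].mean()
        assert out["mapet"] == pytest.approx(expected)


class TestPcaReduce:
    def _sample(self, X):
        meta = [ClimateVariable(f"v{i}", "temperature", "air")
                for i in range(X.shape[1])]
        return EnvSample(matrix=X, variable_meta=meta)

    def test_perfectly_correlated_pair_needs_one_axis(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        red = fx.pca_reduce(self._sample(np.column_stack([x, 2 * x + 1])))
        assert red.k == 1 and red.cumvar_at_k == pytest.approx(1.0)

    def test_five_independent_variables_need_four_axes(self):
        rng = np.random.default_rng(1)
        red = fx.pca_reduce(self._sample(rng.standard_normal((4000, 5))))
        assert red.k == 4  # cumulative variance at 4 axes is closest to 80%

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 6)) @ rng.standard_normal((6, 6))
        sample = self._sample(X)
        red = fx.pca_reduce(sample, target_cumvar=1.0)
        Z = (X - X.mean(0)) / X.std(0)
        evals, evecs = np.linalg.eigh(np.cov(Z.T, bias=True))
        order = np.argsort(evals)[::-1]
        scores = Z @ evecs[:, order[:red.k]]
        # same subspace up to per-axis sign
        for j in range(red.k):
            dots = np.abs(scores.T @ red.scores[:, j]) / (
                np.linalg.norm(scores, axis=0) * np.linalg.norm(red.scores[:, j]))
            assert dots.max() == pytest.approx(1.0, abs=1e-8)

    def test_zero_variance_variable_dropped(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.standard_normal(30), np.full(30, 7.0),
                             rng.standard_normal(30)])
        red = fx.pca_reduce(self._sample(X))
        assert red.dropped_variables == ["v1"]

    def test_all_constant_matrix_is_an_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            fx.pca_reduce(self._sample(np.ones((5, 3))))


class TestHullVolume:
    def test_unit_square(self):
        sq = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        vol, degen = fx.hull_volume(sq)
        assert vol == pytest.approx(1.0) and not degen

    @pytest.mark.parametrize("d", [2, 3, 4, 5])
    def test_unit_simplex_volume(self, d):
        pts = np.vstack([np.zeros(d), np.eye(d)])
        vol, _ = fx.hull_volume(pts)
        assert vol == pytest.approx(1.0 / math.factorial(d), rel=1e-9)

    def test_one_dimensional_interval(self):
        vol, _ = fx.hull_volume(np.array([[2.0], [5.0], [3.0]]))
        assert vol == 3.0

    def test_degenerate_cloud_flagged(self):
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        vol, degen = fx.hull_volume(line)
        assert vol == 0.0 and degen

    def test_monte_carlo_rejection_oracle_3d(self):
        rng = np.random.default_rng(8)
        pts = rng.standard_normal((200, 3))
        vol, _ = fx.hull_volume(pts)
        lo, hi = pts.min(0), pts.max(0)
        n = 300_000
        u = rng.uniform(lo, hi, (n, 3))
        frac = points_in_hull(u, pts).mean()
        assert vol == pytest.approx(frac * np.prod(hi - lo), rel=0.01)

    def test_hull_monotone_under_point_addition(self):
        rng = np.random.default_rng(9)
        pts = rng.standard_normal((30, 3))
        v0, _ = fx.hull_volume(pts)
        for _ in range(10):
            extra = rng.standard_normal((1, 3))
            v1, _ = fx.hull_volume(np.vstack([pts, extra]))
            assert v1 >= v0 - 1e-12
            pts, v0 = np.vstack([pts, extra]), v1


class TestClimatePartitionAndCep:
    def test_identical_clouds_give_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((30, 2))
        part = fx.partition_climate_volume(pts, pts)
        assert part.g_env == 0.0 and fx.compute_cep(part) == 0.0

    def test_stretched_hull_areas_match_shoelace(self):
        spor = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        allpts = np.vstack([spor, [[3.0, 0.5]]])  # adds a base-1 height-2 triangle
        part = fx.partition_climate_volume(allpts, spor)
        assert part.s_env == pytest.approx(1.0)
        assert part.g_env == pytest.approx(1.0)

    def test_erroneous_sporophyte_volume_always_zero_for_exact_hulls(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            k = rng.integers(1, 4)
            spor = rng.standard_normal((12, k))
            extra = rng.standard_normal((5, k))
            part = fx.partition_climate_volume(np.vstack([spor, extra]), spor)
            assert part.erroneous_sporophyte_volume == 0.0

    def test_no_sporophytes_gives_cep_one(self):
        rng = np.random.default_rng(2)
        part = fx.partition_climate_volume(rng.standard_normal((10, 2)), [])
        assert fx.compute_cep(part) == 1.0

    def test_degenerate_partition_gives_zero_with_flag(self):
        part = ClimatePartition(g_env=0.0, s_env=0.0,
                                erroneous_sporophyte_volume=0.0, k_dims=0,
                                degenerate=True)
        assert fx.compute_cep(part) == 0.0

    @pytest.mark.parametrize("g,s,expected", [(0, 5, 0.0), (5, 0, 1.0),
                                              (1, 3, 0.25)])
    def test_cep_arithmetic(self, g, s, expected):
        part = ClimatePartition(g_env=g, s_env=s, erroneous_sporophyte_volume=0.0,
                                k_dims=2)
        assert fx.compute_cep(part) == pytest.approx(expected)

    def test_nested_interior_points_snap_to_exact_zero(self):
        rng = np.random.default_rng(3)
        spor = rng.standard_normal((40, 3))
        interior = 0.3 * rng.standard_normal((10, 3))
        part = fx.partition_climate_volume(np.vstack([spor, interior]), spor)
        assert part.g_env == 0.0


class TestPerVariableCep:
    def _sample(self, mat, stages):
        mat = np.asarray(mat, float)
        meta = [ClimateVariable(f"v{i}", "temperature", "air")
                for i in range(mat.shape[1])]
        return EnvSample(matrix=mat, variable_meta=meta,
                         stage_labels=np.asarray(stages))

    def test_equal_ranges_give_zero(self):
        mat = [[0.0, 1.0], [1.0, 0.0], [0.5, 0.5]]
        sample = self._sample(mat, ["sporophyte", "sporophyte", "gametophyte"])
        assert fx.per_variable_cep(sample) == 0.0

    def test_one_dimensional_interval_arithmetic(self):
        mat = [[0.0], [1.0], [3.0]]
        sample = self._sample(mat, ["sporophyte", "sporophyte", "gametophyte"])
        assert fx.per_variable_cep(sample) == pytest.approx(2.0 / 3.0)

    def test_constant_variable_contributes_zero_to_mean(self):
        mat = [[0.0, 5.0], [1.0, 5.0], [3.0, 5.0]]
        sample = self._sample(mat, ["sporophyte", "sporophyte", "gametophyte"])
        assert fx.per_variable_cep(sample) == pytest.approx(1.0 / 3.0)

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(4)
        mat = rng.standard_normal((20, 3))
        stages = np.where(rng.uniform(size=20) < 0.6, "sporophyte", "gametophyte")
        stages[0] = "sporophyte"
        base = fx.per_variable_cep(self._sample(mat, stages))
        scaled = mat * np.array([3.0, 0.1, 42.0]) + np.array([-5.0, 2.0, 0.0])
        assert fx.per_variable_cep(self._sample(scaled, stages)) == pytest.approx(base)


class TestCepByAxis:
    def test_no_expansion_means_all_axes_zero(self, default_climate):
        scenario = fx.SyntheticScenario(seed=11, n_species=1, n_zero_cep=0)
        recs = fx.simulate_species_occurrences(default_climate, scenario, 0)
        pts = [(r.longitude, r.latitude) for r in recs]
        stages = [r.life_stage for r in recs]
        sample = fx.extract_env(pts, default_climate.summaries, stage_labels=stages)
        ceps = fx.cep_by_axis(sample, "terrestrial")
        assert ceps["cep_all"] == 0.0
        assert ceps["cep_temperature"] == 0.0
        assert ceps["cep_water"] == 0.0
        assert ceps["cep_interaction"] == 0.0

    def test_cep_invariant_to_affine_variable_rescaling(self, default_climate):
        scenario = fx.SyntheticScenario(seed=13, n_species=1, n_zero_cep=0,
                                        expansion_category="temperature_water",
                                        expansion_delta=3.0)
        clim = fx.simulate_climate_layers(scenario)
        recs = fx.simulate_species_occurrences(clim, scenario, 0)
        pts = [(r.longitude, r.latitude) for r in recs]
        stages = [r.life_stage for r in recs]
        sample = fx.extract_env(pts, clim.summaries, stage_labels=stages)
        base = fx.cep_by_axis(sample, "terrestrial")
        rng = np.random.default_rng(5)
        scale = rng.uniform(0.1, 10, sample.matrix.shape[1])
        shift = rng.uniform(-5, 5, sample.matrix.shape[1])
        rescaled = EnvSample(matrix=sample.matrix * scale + shift,
                             variable_meta=sample.variable_meta,
                             stage_labels=sample.stage_labels)
        other = fx.cep_by_axis(rescaled, "terrestrial")
        for key in ("cep_all", "cep_temperature", "cep_water", "cep_interaction"):
            assert other[key] == pytest.approx(base[key], abs=1e-9)


class TestRasterTextFormat:
    def test_roundtrip(self, tmp_path, default_climate):
        layers = default_climate.summaries
        layers.to_dir(tmp_path / "rasters")
        back = ClimateLayerSet.from_dir(tmp_path / "rasters")
        assert back.names == layers.names
        assert back.grid == layers.grid
        for name in layers.names[:3]:
            np.testing.assert_allclose(back.get(name), layers.get(name))
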