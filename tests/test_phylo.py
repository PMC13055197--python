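"""Phylogenetic covariance, Pagel's lambda, GLS and RMA fits."""

import numpy as np
import pytest

import fernexpand as fx
from fernexpand.climate import ExpansionResult
from fernexpand.phylo import (estimate_lambda, _profile_loglik, phylo_covariance,
                              simulate_brownian, tip_labels, write_newick)


def star_tree(n):
    inner = ",".join(f"t{i}:1" for i in range(n))
    return fx.read_newick(f"({inner});")


class TestTreeOps:
    def test_prune_to_all_tips_preserves_patristic_distances(self, yule_tree_100):
        labels = tip_labels(yule_tree_100)
        pruned, missing = fx.prune_tree(yule_tree_100, labels)
        assert missing == []
        C0, _ = phylo_covariance(yule_tree_100, labels)
        C1, _ = phylo_covariance(pruned, labels)
        np.testing.assert_allclose(C0, C1, atol=1e-9)

    def test_prune_balanced_tree_to_sisters_sums_branches(self, balanced_tree):
        pruned, _ = fx.prune_tree(balanced_tree, ["A", "B", "C"])
        C, labels = phylo_covariance(pruned, ["A", "B", "C"])
        # A and B share depth-1 history; C shares nothing with them
        assert C[0, 1] == pytest.approx(1.0)
        assert C[0, 2] == pytest.approx(0.0)
        assert C[0, 0] == pytest.approx(2.0)

    def test_pruned_patristic_matrix_is_submatrix_of_original(self):
        tree = fx.simulate_tree(50, seed=5)
        labels = tip_labels(tree)
        rng = np.random.default_rng(0)
        subset = sorted(rng.choice(labels, 10, replace=False))
        C_full, _ = phylo_covariance(tree, subset)
        pruned, _ = fx.prune_tree(tree, subset)
        C_sub, _ = phylo_covariance(pruned, subset)
        np.testing.assert_allclose(C_full, C_sub, atol=1e-9)

    def test_missing_taxa_reported(self, balanced_tree):
        pruned, missing = fx.prune_tree(balanced_tree, ["A", "B", "C", "ZZZ"])
        assert missing == ["ZZZ"]
        with pytest.raises(ValueError, match="fewer than 3"):
            fx.prune_tree(balanced_tree, ["A", "B", "nope"])

    def test_newick_roundtrip_keeps_labels(self, yule_tree_100):
        back = fx.read_newick(write_newick(yule_tree_100))
        assert sorted(tip_labels(back)) == sorted(tip_labels(yule_tree_100))


class TestLambdaTransform:
    C = np.array([[2.0, 1.0, 0.5],
                  [1.0, 2.0, 0.5],
                  [0.5, 0.5, 1.5]])

    def test_lambda_one_is_identity(self):
        np.testing.assert_array_equal(fx.lambda_transform(self.C, 1.0), self.C)

    def test_lambda_zero_is_diagonal(self):
        V = fx.lambda_transform(self.C, 0.0)
        np.testing.assert_array_equal(V, np.diag([2.0, 2.0, 1.5]))

    def test_half_lambda_elementwise(self):
        V = fx.lambda_transform(self.C, 0.5)
        assert V[0, 1] == 0.5 and V[0, 2] == 0.25 and V[0, 0] == 2.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fx.lambda_transform(self.C, 1.5)


class TestPhyloLm:
    def test_star_phylogeny_equals_ols(self):
        tree = star_tree(20)
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        y = 2 * x + rng.standard_normal(20)
        fit = fx.fit_phylo_lm(y, x, tree, labels=[f"t{i}" for i in range(20)],
                              fix_lambda=0.0)
        beta = np.polyfit(x, y, 1)
        assert fit.slope == pytest.approx(beta[0], abs=1e-8)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-8)

    def test_lambda_zero_fit_equals_ols_on_ultrametric_tree(self, yule_tree_100):
        labels = tip_labels(yule_tree_100)
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        y = 1.5 * x + rng.standard_normal(100)
        fit = fx.fit_phylo_lm(y, x, yule_tree_100, labels=labels, fix_lambda=0.0)
        beta = np.polyfit(x, y, 1)
        assert fit.slope == pytest.approx(beta[0], abs=1e-8)

    def test_noiseless_line_recovered_exactly(self, yule_tree_100):
        labels = tip_labels(yule_tree_100)
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        fit = fx.fit_phylo_lm(3 * x + 1, x, yule_tree_100, labels=labels)
        assert fit.slope == pytest.approx(3.0, abs=1e-6)
        assert fit.intercept == pytest.approx(1.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_brownian_response_recovers_high_lambda(self, yule_tree_100):
        labels = tip_labels(yule_tree_100)
        C, _ = phylo_covariance(yule_tree_100, labels)
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = simulate_brownian(C, 1.0, rng, lam=1.0)
            x = rng.standard_normal(100)
            fit = fx.fit_phylo_lm(y, x, yule_tree_100, labels=labels)
            hits += fit.lam >= 0.8
        assert hits >= 40  # >= 80% of replicates

    def test_singular_design_rejected(self, yule_tree_100):
        labels = tip_labels(yule_tree_100)
        x = np.ones(100)
        with pytest.raises(ValueError, match="singular"):
            fx.fit_phylo_lm(x, x, yule_tree_100, labels=labels)

    def test_optimizer_beats_grid_candidates(self, yule_tree_100):
        labels = tip_labels(yule_tree_100)
        C, _ = phylo_covariance(yule_tree_100, labels)
        rng = np.random.default_rng(3)
        y = simulate_brownian(C, 1.0, rng, lam=0.6) + 0.3 * rng.standard_normal(100)
        X = np.column_stack([np.ones(100), rng.standard_normal(100)])
        lam_hat, grid = estimate_lambda(y, X, C)
        best = _profile_loglik(lam_hat, y, X, C)
        for lam, ll in grid:
            assert best >= ll - 1e-6


class TestPhyloRma:
    def test_noiseless_proportionality(self, yule_tree_100):
        labels = tip_labels(yule_tree_100)
        rng = np.random.default_rng(4)
        x = rng.standard_normal(100)
        fit = fx.fit_phylo_rma(x, 2 * x, yule_tree_100, labels=labels,
                               fix_lambda=0.0)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_negative_covariance_gives_negative_slope(self, yule_tree_100):
        labels = tip_labels(yule_tree_100)
        rng = np.random.default_rng(5)
        x = rng.standard_normal(100)
        y = -x + 0.1 * rng.standard_normal(100)
        fit = fx.fit_phylo_rma(x, y, yule_tree_100, labels=labels)
        assert fit.slope < 0

    def test_slope_reciprocal_under_axis_exchange(self, yule_tree_100):
        labels = tip_labels(yule_tree_100)
        rng = np.random.default_rng(6)
        x = rng.standard_normal(100)
        y = 0.5 * x + rng.standard_normal(100)
        f_xy = fx.fit_phylo_rma(x, y, yule_tree_100, labels=labels, fix_lambda=0.5)
        f_yx = fx.fit_phylo_rma(y, x, yule_tree_100, labels=labels, fix_lambda=0.5)
        assert f_xy.slope * f_yx.slope == pytest.approx(1.0, abs=1e-9)

    def test_bivariate_brownian_recovers_sd_ratio(self, yule_tree_100):
        labels = tip_labels(yule_tree_100)
        C, _ = phylo_covariance(yule_tree_100, labels)
        slopes = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = simulate_brownian(C, 1.0, rng)
            y = simulate_brownian(C, 2.0, rng)
            slopes.append(abs(fx.fit_phylo_rma(x, y, yule_tree_100,
                                               labels=labels).slope))
        assert 1.8 <= np.median(slopes) <= 2.2

    def test_zero_variance_predictor_rejected(self, yule_tree_100):
        labels = tip_labels(yule_tree_100)
        with pytest.raises(ValueError, match="RMA undefined"):
            fx.fit_phylo_rma(np.zeros(100), np.arange(100.0), yule_tree_100,
                             labels=labels)


class TestLambdaRecovery:
    @pytest.mark.parametrize("lam_true", [0.0, 0.5, 1.0])
    def test_mean_bias_below_tenth(self, yule_tree_100, lam_true):
        labels = tip_labels(yule_tree_100)
        C, _ = phylo_covariance(yule_tree_100, labels)
        lams = []
        for seed in range(50):
            rng = np.random.default_rng([seed, 5])
            y = simulate_brownian(C, 1.0, rng, lam=lam_true)
            x = rng.standard_normal(100)
            lams.append(fx.fit_phylo_lm(y, x, yule_tree_100, labels=labels).lam)
        assert abs(np.mean(lams) - lam_true) < 0.1


def _expansion(species, gep, cep):
    return ExpansionResult(species_id=species, habit="terrestrial",
                           gep_percent=gep, cep_percent=cep,
                           cep_temperature_percent=0.0, cep_water_percent=0.0,
                           cep_interaction_percent=cep,
                           per_variable_mean_cep_percent=cep, n_gam=5, n_spor=20)


class TestRegressGepCep:
    def test_positive_gep_zero_cep_species_excluded(self):
        tree = fx.simulate_tree(23, seed=3)
        rng = np.random.default_rng(0)
        results = []
        for i in range(23):
            sp = f"sp_{i + 1:03d}"
            if i < 13:
                gep = rng.uniform(10, 40)
                results.append(_expansion(sp, gep, 0.8 * gep + rng.normal(0, 2)))
            else:
                results.append(_expansion(sp, rng.uniform(10, 40), 0.0))
        fit, used = fx.regress_gep_cep(results, tree)
        assert fit.n == 13 and len(used) == 13

    def test_all_zero_cep_is_an_error(self):
        tree = fx.simulate_tree(5, seed=1)
        results = [_expansion(f"sp_{i + 1:03d}", 10.0, 0.0) for i in range(5)]
        with pytest.raises(ValueError, match="fewer than 3"):
            fx.regress_gep_cep(results, tree)

    def test_proportional_coupling_recovers_generating_slope(self):
        tree = fx.simulate_tree(30, seed=7)
        slopes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            gep = rng.uniform(5, 45, 30)
            cep = 0.7 * gep + rng.normal(0, 1.5, 30)
            results = [_expansion(f"sp_{i + 1:03d}", gep[i], max(cep[i], 0.1))
                       for i in range(30)]
            fit, _ = fx.regress_gep_cep(results, tree)
            slopes.append(fit.slope)
        assert abs(np.median(slopes) - 0.7) / 0.7 < 0.15
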