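"""Forest contracts: nuisance OOB fits, honest trees, merging, importance."""

import numpy as np
import pytest

import hteforest as ht
from hteforest import _tree
from hteforest.forest import (
    CausalForest,
    ForestParams,
    fit_causal_forest,
    fit_nuisance,
    fit_seed_ensemble,
    merge_forests,
    variable_importance,
)

from conftest import small_spec


class TestNuisance:
    def test_randomized_treatment_propensity_near_half(self):
        spec = small_spec(propensity_coefs={}, seed=41)
        table, _ = ht.generate_cohort(spec)
        nui = fit_nuisance(table, seed=1)
        assert abs(nui.e_hat.mean() - 0.5) < 0.05

    def test_constant_outcome_gives_constant_m_hat(self, linear_cohort):
        table, _ = linear_cohort
        const = ht.CohortTable(
            X=table.X, W=table.W, Y=np.full(table.n, 7.0), cluster=table.cluster,
            covariate_names=table.covariate_names, covariate_kind=table.covariate_kind,
        )
        nui = fit_nuisance(const, n_estimators=50, seed=1)
        np.testing.assert_allclose(nui.m_hat, 7.0, atol=1e-9)

    def test_oracle_mode_bypasses_fitting(self, linear_cohort):
        table, truth = linear_cohort
        nui = fit_nuisance(table, oracle_e=truth.propensity, oracle_m=lambda X: np.zeros(len(X)))
        np.testing.assert_allclose(nui.e_hat, truth.propensity(table.X))
        np.testing.assert_allclose(nui.m_hat, 0.0)

    def test_single_arm_raises_no_overlap(self, linear_cohort):
        table, _ = linear_cohort
        mono = ht.CohortTable(
            X=table.X, W=np.ones(table.n, dtype=int), Y=table.Y, cluster=table.cluster,
            covariate_names=table.covariate_names, covariate_kind=table.covariate_kind,
        )
        with pytest.raises(ValueError, match="overlap"):
            fit_nuisance(mono)

    def test_propensity_clipped(self, linear_cohort):
        table, _ = linear_cohort
        nui = fit_nuisance(table, oracle_e=lambda X: np.full(len(X), 0.999))
        assert nui.e_hat.max() <= 0.95


class TestCausalForest:
    def test_null_effect_mean_near_zero(self, null_cohort):
        table, _ = null_cohort
        shifted = ht.CohortTable(
            X=table.X, W=table.W, Y=table.Y - table.W * 1.0, cluster=table.cluster,
            covariate_names=table.covariate_names, covariate_kind=table.covariate_kind,
        )  # removes the homogeneous effect: tau(x) = 0 everywhere
        nui = fit_nuisance(shifted, n_estimators=100, seed=2)
        cf = fit_causal_forest(shifted, nui, ForestParams(num_trees=100), seed=3)
        oob = cf.oob_tau[np.isfinite(cf.oob_tau)]
        assert abs(oob.mean()) < 3 * oob.std() / np.sqrt(len(oob)) + 0.05

    def test_strong_signal_recovers_cate_ranking(self, linear_cohort, linear_fit):
        table, truth = linear_cohort
        _, cf = linear_fit
        m = np.isfinite(cf.oob_tau)
        corr = np.corrcoef(cf.oob_tau[m], truth.tau_values[m])[0, 1]
        assert corr > 0.5

    def test_single_tree_oob_defined_only_outside_subsample(self, linear_cohort):
        table, _ = linear_cohort
        nui = fit_nuisance(table, n_estimators=50, seed=1)
        cf = fit_causal_forest(table, nui, ForestParams(num_trees=1), seed=9)
        inside = cf.in_sample[0]
        assert np.isnan(cf.oob_tau[inside]).all()
        assert np.isfinite(cf.oob_tau[~inside]).mean() > 0.9

    def test_min_node_exceeding_subsample_raises(self, linear_cohort):
        table, _ = linear_cohort
        nui = fit_nuisance(table, n_estimators=50, seed=1)
        with pytest.raises(ValueError, match="min_node_size"):
            fit_causal_forest(table, nui, ForestParams(min_node_size=10**6), seed=0)

    def test_fit_deterministic_for_seed(self, linear_cohort):
        table, _ = linear_cohort
        nui = fit_nuisance(table, n_estimators=50, seed=1)
        a = fit_causal_forest(table, nui, ForestParams(num_trees=20), seed=4)
        b = fit_causal_forest(table, nui, ForestParams(num_trees=20), seed=4)
        np.testing.assert_array_equal(a.oob_tau, b.oob_tau)

    def test_more_trees_shrink_oob_spread_under_homogeneous_effect(self, null_cohort):
        table, _ = null_cohort
        nui = fit_nuisance(table, n_estimators=100, seed=2)
        small = fit_causal_forest(table, nui, ForestParams(num_trees=30), seed=5)
        big = fit_causal_forest(table, nui, ForestParams(num_trees=300), seed=5)
        assert np.nanstd(big.oob_tau) < np.nanstd(small.oob_tau)

    def test_honest_splits_ignore_estimation_half(self, linear_cohort):
        # changing the estimation half must not change any split
        table, _ = linear_cohort
        nui = fit_nuisance(table, n_estimators=50, seed=1)
        A = (table.W - nui.e_hat).astype(float)
        R = (table.Y - nui.m_hat).astype(float)
        X = np.ascontiguousarray(table.X)
        rows = np.arange(table.n, dtype=np.int64)
        split = rows[:700]
        t1 = _tree.grow_tree(X, A, R, split, rows[700:1400], 10, 5, 123)
        t2 = _tree.grow_tree(X, A, R, split, rows[1400:2000], 10, 5, 123)
        np.testing.assert_array_equal(t1[0], t2[0])  # features
        np.testing.assert_array_equal(t1[1], t2[1])  # thresholds


class TestMerge:
    def test_merge_single_forest_is_identity(self, linear_cohort):
        table, _ = linear_cohort
        nui = fit_nuisance(table, n_estimators=50, seed=1)
        f = fit_causal_forest(table, nui, ForestParams(num_trees=25), seed=6)
        merged = merge_forests([f], table)
        np.testing.assert_array_equal(merged.oob_tau, f.oob_tau)
        grid = table.X[:50]
        np.testing.assert_allclose(merged.predict(grid), f.predict(grid))

    def test_merge_concatenates_trees_and_counts(self, linear_fit):
        _, cf = linear_fit
        assert cf.num_trees == 150
        assert cf.seeds == [1, 2, 3]
        # split-count totals equal the number of internal nodes over all trees
        internal = sum(int((tr[0] >= 0).sum()) for tr in cf.trees)
        assert cf.split_counts.sum() == internal

    def test_merge_rejects_mismatched_params(self, linear_cohort):
        table, _ = linear_cohort
        nui = fit_nuisance(table, n_estimators=50, seed=1)
        a = fit_causal_forest(table, nui, ForestParams(num_trees=10), seed=1)
        b = fit_causal_forest(table, nui, ForestParams(num_trees=10, min_node_size=25), seed=2)
        with pytest.raises(ValueError, match="params"):
            merge_forests([a, b], table)

    def test_merge_rejects_other_table(self, linear_cohort, null_cohort):
        table, _ = linear_cohort
        other, _ = null_cohort
        nui = fit_nuisance(table, n_estimators=50, seed=1)
        f = fit_causal_forest(table, nui, ForestParams(num_trees=10), seed=1)
        with pytest.raises(ValueError, match="table"):
            merge_forests([f], other)

    def test_seed_ensemble_reduces_mean_oob_variance(self):
        # variance over independent seed-ensembles <= variance over single forests
        spec = small_spec(n_participants=1000, n_sites=10, seed=55)
        table, _ = ht.generate_cohort(spec)
        nui = fit_nuisance(table, n_estimators=50, seed=1)
        singles = [
            np.nanmean(fit_causal_forest(table, nui, ForestParams(num_trees=10), seed=s).oob_tau)
            for s in range(10)
        ]
        ensembles = [
            np.nanmean(
                fit_seed_ensemble(
                    table, nui, ForestParams(num_trees=10), seeds=(100 + 3 * s, 101 + 3 * s, 102 + 3 * s)
                ).oob_tau
            )
            for s in range(10)
        ]
        assert np.var(ensembles) <= np.var(singles)


class TestImportance:
    def test_importance_sums_to_one_and_targets_modifier(self, linear_cohort, linear_fit):
        table, _ = linear_cohort
        _, cf = linear_fit
        imp = variable_importance(cf)
        assert imp.sum() == pytest.approx(1.0)
        assert table.covariate_names[int(np.argmax(imp))] == "environment__env01"

    def test_stump_forest_returns_zero_vector_with_warning(self, linear_cohort):
        table, _ = linear_cohort
        nui = fit_nuisance(table, n_estimators=50, seed=1)
        cf = fit_causal_forest(table, nui, ForestParams(num_trees=5, min_node_size=400), seed=1)
        if cf.split_counts.sum() == 0:
            with pytest.warns(UserWarning, match="no internal nodes"):
                imp = variable_importance(cf)
            assert np.all(imp == 0)

    def test_permuting_split_counts_permutes_importance(self, linear_fit):
        _, cf = linear_fit
        imp = variable_importance(cf)
        perm = np.random.default_rng(0).permutation(cf.p)
        shuffled = CausalForest(
            trees=cf.trees, params=cf.params, seeds=cf.seeds,
            covariate_names=[cf.covariate_names[j] for j in perm],
            oob_tau=cf.oob_tau, split_counts=cf.split_counts[perm],
            in_sample=cf.in_sample, fingerprint=cf.fingerprint,
        )
        np.testing.assert_allclose(variable_importance(shuffled), imp[perm])


class TestSerialization:
    def test_npz_round_trip_preserves_predictions(self, tmp_path, linear_cohort, linear_fit):
        table, _ = linear_cohort
        _, cf = linear_fit
        path = tmp_path / "forest.npz"
        cf.save(path)
        back = CausalForest.load(path)
        grid = table.X[:100]
        np.testing.assert_allclose(back.predict(grid), cf.predict(grid))
        np.testing.assert_array_equal(back.oob_tau, cf.oob_tau)
        assert back.params == cf.params
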