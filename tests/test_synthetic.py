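"""Generator contracts: truth-ledger consistency, scaling, determinism, missingness."""

import numpy as np
import pytest
import statsmodels.api as sm

import hteforest as ht
from hteforest.prep import complete_case_filter

from conftest import small_spec


class TestSpecValidation:
    def test_unknown_modifier_covariate_rejected(self):
        with pytest.raises(Exception, match="modifier_terms"):
            small_spec(modifier_terms=[{"covariate": "nope", "form": "linear", "coefficient": 1}])

    def test_unknown_propensity_covariate_rejected(self):
        with pytest.raises(Exception, match="propensity_coefs"):
            small_spec(propensity_coefs={"ghost": 0.5})

    def test_too_few_participants_per_site_rejected(self):
        with pytest.raises(Exception, match="n_participants"):
            small_spec(n_participants=100, n_sites=21)


class TestGroundTruth:
    def test_no_modifiers_gives_constant_tau(self):
        table, truth = ht.generate_cohort(small_spec(tau_intercept=1.0, seed=3))
        assert truth.true_ate == pytest.approx(1.0)
        assert np.all(truth.true_tau(table.X) == 1.0)

    def test_zero_propensity_coefs_is_unconfounded(self):
        spec = small_spec(propensity_coefs={}, n_participants=4000, seed=4)
        table, _ = ht.generate_cohort(spec)
        assert abs(table.W.mean() - 0.5) < 3 * np.sqrt(0.25 / 4000)

    def test_linear_modifier_population_mean(self):
        # tau(x) = 1 + 0.8 * x1 with x1 standard normal: E[tau] = 1
        spec = small_spec(
            n_participants=4000,
            seed=5,
            modifier_terms=[
                {"covariate": "environment__env01", "form": "linear", "coefficient": 0.8}
            ],
        )
        table, truth = ht.generate_cohort(spec)
        assert abs(truth.true_ate - 1.0) < 3 * 0.8 / np.sqrt(4000)

    def test_true_ate_is_empirical_mean_of_tau(self, linear_cohort):
        table, truth = linear_cohort
        assert truth.true_ate == pytest.approx(truth.true_tau(table.X).mean(), abs=1e-12)
        assert np.allclose(truth.tau_values, truth.true_tau(table.X))

    def test_propensity_values_bounded(self, linear_cohort):
        _, truth = linear_cohort
        assert truth.propensity_values.min() >= 0.05
        assert truth.propensity_values.max() <= 0.95


class TestTableInvariants:
    def test_continuous_columns_z_scaled(self, linear_cohort):
        table, _ = linear_cohort
        for j, kind in enumerate(table.covariate_kind):
            col = table.X[:, j]
            if kind == "continuous":
                assert abs(col.mean()) < 0.1
                assert abs(col.std() - 1) < 0.1
            else:
                assert set(np.unique(col)) <= {0.0, 1.0}

    def test_validate_passes_and_clusters_populated(self, linear_cohort):
        table, _ = linear_cohort
        table.validate()
        _, counts = np.unique(table.cluster, return_counts=True)
        assert len(counts) == 21
        assert counts.min() >= 2

    def test_baseline_coefs_recovered_by_regression(self):
        # regressing Y - tau(X) * W on X recovers the generating main effects
        spec = small_spec(n_participants=4000, seed=9, site_sd=0.0)
        table, truth = ht.generate_cohort(spec)
        resid = table.Y - truth.true_tau(table.X) * table.W
        fit = sm.OLS(resid, sm.add_constant(table.X)).fit()
        for name, coef in spec.baseline_coefs.items():
            j = table.covariate_names.index(name) + 1
            assert abs(fit.params[j] - coef) < 3 * fit.bse[j]

    def test_treated_fraction_monotone_in_propensity_coef(self):
        fracs = []
        for b in (-0.5, 0.0, 0.5):
            spec = small_spec(propensity_coefs={"environment__env01": b}, seed=2)
            spec = ht.CohortSpec.model_validate(
                {**spec.model_dump(), "baseline_coefs": {}}
            )
            table, truth = ht.generate_cohort(spec)
            # compare expected propensity for a fixed positive covariate value
            row = np.zeros(table.p)
            row[0] = 1.0
            fracs.append(truth.propensity(row)[0])
        assert fracs[0] < fracs[1] < fracs[2]

    def test_same_seed_bit_identical_different_seed_differs(self):
        t1, _ = ht.generate_cohort(small_spec(seed=7))
        t2, _ = ht.generate_cohort(small_spec(seed=7))
        t3, _ = ht.generate_cohort(small_spec(seed=8))
        assert np.array_equal(t1.X, t2.X) and np.array_equal(t1.Y, t2.Y)
        assert not np.array_equal(t1.Y, t3.Y)


class TestMissingness:
    def test_rate_zero_is_identity(self, linear_cohort):
        table, _ = linear_cohort
        assert ht.apply_missingness(table, 0.0, seed=1) is table

    def test_rate_one_rejected(self, linear_cohort):
        table, _ = linear_cohort
        with pytest.raises(ValueError):
            ht.apply_missingness(table, 1.0, seed=1)

    def test_masked_cell_count_binomial(self):
        spec = small_spec(n_participants=1000, seed=6)
        table, _ = ht.generate_cohort(spec)
        gappy = ht.apply_missingness(table, 0.05, seed=2)
        n_cells = table.n * table.p
        expected = 0.05 * n_cells
        tol = 3 * np.sqrt(n_cells * 0.05 * 0.95)
        assert abs(np.isnan(gappy.X).sum() - expected) < tol
        # treatment, outcome and cluster are never masked
        assert np.isfinite(gappy.Y).all()
        assert np.isfinite(gappy.W).all()

    def test_complete_case_filter_leaves_no_gaps(self, linear_cohort):
        table, _ = linear_cohort
        gappy = ht.apply_missingness(table, 0.03, seed=3)
        filtered, removed = complete_case_filter(gappy)
        assert removed > 0
        assert not np.isnan(filtered.X).any()


class TestRoundTrip:
    def test_csv_round_trip(self, tmp_path, linear_cohort):
        table, _ = linear_cohort
        path = tmp_path / "cohort.csv"
        table.to_csv(path)
        back = ht.CohortTable.read_csv(path)
        assert back.covariate_names == table.covariate_names
        assert back.covariate_kind == table.covariate_kind
        np.testing.assert_allclose(back.X, table.X, rtol=0, atol=1e-12)
        assert np.array_equal(back.W, table.W)
        assert np.array_equal(back.cluster, table.cluster)

    def test_truth_sidecar_json(self, tmp_path, linear_cohort):
        import json

        _, truth = linear_cohort
        path = tmp_path / "truth.json"
        truth.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["true_ate"] == pytest.approx(truth.true_ate)
        assert payload["modifier_names"] == ["environment__env01"]


class TestMultiOutcomeFrame:
    def test_outcomes_share_covariates_and_differ_in_truth(self):
        spec = small_spec(seed=31, n_participants=1200, n_sites=12)
        frame, truths = ht.generate_cohort_frame(
            spec,
            {
                "adhd": ht.synthetic.OutcomeSpec(
                    tau_intercept=1.0,
                    modifier_terms=[
                        ht.synthetic.ModifierTerm(
                            covariate="environment__env01", form="linear", coefficient=0.8
                        )
                    ],
                ),
                "anxiety": ht.synthetic.OutcomeSpec(tau_intercept=0.5),
            },
        )
        assert {"adhd", "anxiety"} <= set(frame.columns)
        assert truths["adhd"].modifier_names == ["environment__env01"]
        assert truths["anxiety"].modifier_names == []
        assert truths["anxiety"].true_ate == pytest.approx(0.5)
        assert np.var(truths["adhd"].tau_values) > 0
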