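import pytest

import hteforest as ht
from hteforest.forest import ForestParams, fit_nuisance, fit_seed_ensemble


def small_spec(**overrides):
    """20-covariate cohort spec used by most unit tests (fast to fit)."""
    defaults = dict(
        n_participants=2000,
        n_sites=21,
        covariate_blocks=[
            {"name": "environment", "count": 10, "kind": "continuous"},
            {"name": "prs", "count": 5, "kind": "continuous"},
            {"name": "brain", "count": 4, "kind": "continuous"},
            {"name": "environment", "count": 1, "kind": "binary"},
        ],
        propensity_coefs={"environment__env02": 0.4},
        baseline_coefs={"environment__env02": 0.5, "prs__prs01": 0.4},
        tau_intercept=1.0,
        noise_sd=1.0,
        site_sd=0.2,
        seed=0,
    )
    defaults.update(overrides)
    return ht.CohortSpec.model_validate(defaults)


@pytest.fixture(scope="session")
def linear_cohort():
    """n=2000 cohort whose treatment effect is 1 + 0.8 * env01."""
    spec = small_spec(
        seed=11,
        modifier_terms=[
            {"covariate": "environment__env01", "form": "linear", "coefficient": 0.8}
        ],
    )
    return ht.generate_cohort(spec)


@pytest.fixture(scope="session")
def linear_fit(linear_cohort):
    """Nuisance fits plus a 150-tree seed-ensemble forest on the linear cohort."""
    table, _ = linear_cohort
    nuisance = fit_nuisance(table, n_estimators=150, seed=5)
    forest = fit_seed_ensemble(table, nuisance, ForestParams(num_trees=50), seeds=(1, 2, 3))
    return nuisance, forest


@pytest.fixture(scope="session")
def null_cohort():
    """n=1500 cohort with a homogeneous treatment effect of 1."""
    spec = small_spec(n_participants=1500, seed=23)
    return ht.generate_cohort(spec)
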