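"""Synthetic multi-site cohort generator with known treatment-effect ground truth.

Emulates the design of a large developmental cohort: ~6,300 children
recruited at 21 sites, a binary stress-exposure "treatment" whose
assignment is confounded by observed covariates, a continuous symptom
outcome, and standardized covariates organised in three blocks
(``environment``, ``prs``, ``brain``).  The generating model is

    Y = mu(X) + tau(X) * W + site_effect + eps,
    W ~ Bernoulli(e(X)),   e(X) = clip(logistic(b' X), 0.05, 0.95),

so every downstream estimator (ATE, CATE, GATE, calibration) has a
recoverable truth: the generator returns a :class:`GroundTruth` ledger
holding the exact ``tau`` and propensity functions evaluated on the
generated rows.

Conditional effects ``tau(x)`` are the homogeneous intercept plus a sum of
modifier terms, each of one of three forms: ``linear`` (g*x), ``threshold``
(g*1[x>0]) or ``saturating`` (g*tanh(x)) — nonlinearities a forest can
represent but a linear model cannot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

BlockName = Literal["environment", "prs", "brain"]
CovariateKind = Literal["continuous", "binary"]
ModifierForm = Literal["linear", "threshold", "saturating"]

#: probability of a 1 for generated binary covariates (kept away from 0.5 so
#: near-zero-variance filtering is exercised only when configured).
BINARY_P = 0.3


class CovariateBlock(BaseModel):
    """A named group of covariates of homogeneous kind."""

    name: BlockName
    count: int = Field(gt=0)
    kind: CovariateKind = "continuous"

    def column_names(self, offset: int = 0) -> list[str]:
        return [f"{self.name}__{self.name[:3]}{offset + i + 1:02d}" for i in range(self.count)]


class ModifierTerm(BaseModel):
    covariate: str
    form: ModifierForm = "linear"
    coefficient: float


class CohortSpec(BaseModel):
    """Full description of a synthetic cohort draw.

    ``propensity_coefs`` control confounding of treatment assignment,
    ``baseline_coefs`` the prognostic main effects mu(x), ``tau_intercept``
    and ``modifier_terms`` the conditional treatment effect tau(x).
    """

    n_participants: int = Field(gt=0)
    n_sites: int = Field(default=21, gt=0)
    covariate_blocks: list[CovariateBlock]
    propensity_coefs: dict[str, float] = Field(default_factory=dict)
    baseline_coefs: dict[str, float] = Field(default_factory=dict)
    tau_intercept: float = 0.0
    modifier_terms: list[ModifierTerm] = Field(default_factory=list)
    noise_sd: float = Field(default=1.0, gt=0)
    site_sd: float = Field(default=0.0, ge=0)
    block_correlation: float = Field(default=0.0, ge=0, lt=1)
    missing_rate: float = Field(default=0.0, ge=0, lt=1)
    seed: int = 0

    @property
    def covariate_names(self) -> list[str]:
        names: list[str] = []
        seen: dict[str, int] = {}
        for block in self.covariate_blocks:
            offset = seen.get(block.name, 0)
            names.extend(block.column_names(offset))
            seen[block.name] = offset + block.count
        return names

    @property
    def covariate_kinds(self) -> list[str]:
        return [b.kind for b in self.covariate_blocks for _ in range(b.count)]

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        names = set(self.covariate_names)
        if not names:
            raise ValueError("covariate_blocks: at least one covariate is required")
        for label, referenced in (
            ("propensity_coefs", self.propensity_coefs),
            ("baseline_coefs", self.baseline_coefs),
        ):
            unknown = set(referenced) - names
            if unknown:
                raise ValueError(f"{label}: unknown covariates {sorted(unknown)}")
        unknown = {t.covariate for t in self.modifier_terms} - names
        if unknown:
            raise ValueError(f"modifier_terms: unknown covariates {sorted(unknown)}")
        if self.n_participants < 10 * self.n_sites:
            raise ValueError(
                f"n_participants: need at least 10 per site "
                f"({self.n_participants} < 10 * {self.n_sites})"
            )
        return self


@dataclass
class CohortTable:
    """Rectangular cohort: covariates X, treatment W, outcome Y, site labels.

    Continuous covariate columns are z-scaled; binary columns are {0, 1}
    and left unscaled.  ``cluster`` holds site labels as strings.
    """

    X: np.ndarray
    W: np.ndarray
    Y: np.ndarray
    cluster: np.ndarray
    covariate_names: list[str]
    covariate_kind: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.covariate_names.index(name)]

    def select_covariates(self, names: Sequence[str]) -> "CohortTable":
        """Restrict to a covariate subset, preserving the given order."""
        idx = [self.covariate_names.index(n) for n in names]
        return CohortTable(
            X=self.X[:, idx],
            W=self.W,
            Y=self.Y,
            cluster=self.cluster,
            covariate_names=[self.covariate_names[i] for i in idx],
            covariate_kind=[self.covariate_kind[i] for i in idx],
        )

    def subset_rows(self, rows: np.ndarray) -> "CohortTable":
        return CohortTable(
            X=self.X[rows],
            W=self.W[rows],
            Y=self.Y[rows],
            cluster=self.cluster[rows],
            covariate_names=list(self.covariate_names),
            covariate_kind=list(self.covariate_kind),
        )

    def validate(self) -> None:
        if np.isnan(self.X).any() or np.isnan(self.Y).any():
            raise ValueError("table contains missing values; run complete_case_filter first")
        if not (set(np.unique(self.W)) <= {0, 1}) or len(np.unique(self.W)) < 2:
            raise ValueError("treatment must be binary with both arms present")
        _, counts = np.unique(self.cluster, return_counts=True)
        if (counts < 2).any():
            raise ValueError("every cluster must have at least 2 members")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.covariate_names)
        frame.insert(0, "outcome", self.Y)
        frame.insert(0, "treatment", self.W)
        frame.insert(0, "cluster", self.cluster.astype(str))
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        treatment: str = "treatment",
        outcome: str = "outcome",
        cluster: str = "cluster",
        covariates: Sequence[str] | None = None,
    ) -> "CohortTable":
        if covariates is None:
            covariates = [c for c in frame.columns if c not in (treatment, outcome, cluster)]
        X = frame[list(covariates)].to_numpy(dtype=float)
        kinds = [
            "binary" if set(np.unique(col[~np.isnan(col)])) <= {0.0, 1.0} else "continuous"
            for col in X.T
        ]
        return cls(
            X=X,
            W=frame[treatment].to_numpy(dtype=int),
            Y=frame[outcome].to_numpy(dtype=float),
            cluster=frame[cluster].astype(str).to_numpy(),
            covariate_names=list(covariates),
            covariate_kind=kinds,
        )

    @classmethod
    def read_csv(cls, path, **kwargs) -> "CohortTable":
        return cls.from_frame(pd.read_csv(path), **kwargs)


@dataclass
class GroundTruth:
    """Truth ledger for recovery tests.

    ``true_tau`` and ``propensity`` take the covariate matrix (or a single
    row) on the table's final, z-scaled coordinates, so their values on the
    generated rows are exactly the effects used to draw the data.
    """

    true_ate: float
    true_tau: Callable[[np.ndarray], np.ndarray]
    modifier_names: list[str]
    propensity: Callable[[np.ndarray], np.ndarray]
    tau_values: np.ndarray = field(repr=False)
    propensity_values: np.ndarray = field(repr=False)

    def to_json(self, path, spec: CohortSpec | None = None) -> None:
        payload = {
            "true_ate": self.true_ate,
            "modifier_names": self.modifier_names,
            "tau_values": self.tau_values.tolist(),
            "propensity_values": self.propensity_values.tolist(),
        }
        if spec is not None:
            payload["spec"] = spec.model_dump()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _modifier_basis(values: np.ndarray, form: str) -> np.ndarray:
    if form == "linear":
        return values
    if form == "threshold":
        return (values > 0).astype(float)
    if form == "saturating":
        return np.tanh(values)
    raise ValueError(f"unknown modifier form {form!r}")


def _tau_function(spec: CohortSpec, names: list[str]) -> Callable[[np.ndarray], np.ndarray]:
    terms = [(names.index(t.covariate), t.form, t.coefficient) for t in spec.modifier_terms]
    intercept = spec.tau_intercept

    def tau(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.full(X.shape[0], intercept, dtype=float)
        for j, form, coef in terms:
            out += coef * _modifier_basis(X[:, j], form)
        return out

    return tau


def _linear_index(X: np.ndarray, names: list[str], coefs: dict[str, float]) -> np.ndarray:
    out = np.zeros(X.shape[0])
    for name, coef in coefs.items():
        out += coef * X[:, names.index(name)]
    return out


def _propensity_function(spec: CohortSpec, names: list[str]) -> Callable[[np.ndarray], np.ndarray]:
    def e(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lin = _linear_index(X, names, spec.propensity_coefs)
        return np.clip(1.0 / (1.0 + np.exp(-lin)), 0.05, 0.95)

    return e


def _draw_covariates(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_participants
    cols = []
    for block in spec.covariate_blocks:
        if block.kind == "continuous":
            raw = rng.standard_normal((n, block.count))
            rho = spec.block_correlation
            if rho > 0:
                # equicorrelated within a block via a shared factor, as real
                # covariate blocks (scales, regional metrics) are correlated
                factor = rng.standard_normal((n, 1))
                raw = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * raw
            # z-scale on the empirical moments so the table invariant holds
            # and the truth functions operate on the final coordinates
            raw = (raw - raw.mean(axis=0)) / raw.std(axis=0)
        else:
            raw = (rng.random((n, block.count)) < BINARY_P).astype(float)
        cols.append(raw)
    return np.hstack(cols)


def _assign_sites(n: int, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    base = np.repeat(np.arange(n_sites), int(np.ceil(n / n_sites)))[:n]
    rng.shuffle(base)
    return base


def generate_cohort(spec: CohortSpec) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort and its truth ledger; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    names = spec.covariate_names
    kinds = spec.covariate_kinds

    X = _draw_covariates(spec, rng)
    sites = _assign_sites(spec.n_participants, spec.n_sites, rng)

    e_fn = _propensity_function(spec, names)
    tau_fn = _tau_function(spec, names)
    e = e_fn(X)
    W = (rng.random(spec.n_participants) < e).astype(int)
    tau = tau_fn(X)
    mu = _linear_index(X, names, spec.baseline_coefs)
    site_effects = rng.normal(0.0, spec.site_sd, size=spec.n_sites)
    eps = rng.normal(0.0, spec.noise_sd, size=spec.n_participants)
    Y = mu + tau * W + site_effects[sites] + eps

    table = CohortTable(
        X=X,
        W=W,
        Y=Y,
        cluster=np.array([f"site{s + 1:02d}" for s in sites]),
        covariate_names=list(names),
        covariate_kind=list(kinds),
    )
    truth = GroundTruth(
        true_ate=float(tau.mean()),
        true_tau=tau_fn,
        modifier_names=[t.covariate for t in spec.modifier_terms],
        propensity=e_fn,
        tau_values=tau,
        propensity_values=e,
    )
    if spec.missing_rate > 0:
        table = apply_missingness(table, spec.missing_rate, seed=rng.integers(2**31))
    return table, truth


@dataclass
class OutcomeSpec:
    """Outcome-generating parameters for one extra outcome column."""

    baseline_coefs: dict[str, float] = field(default_factory=dict)
    tau_intercept: float = 0.0
    modifier_terms: list[ModifierTerm] = field(default_factory=list)
    noise_sd: float = 1.0
    site_sd: float = 0.0


def generate_cohort_frame(
    spec: CohortSpec, outcomes: dict[str, OutcomeSpec]
) -> tuple[pd.DataFrame, dict[str, GroundTruth]]:
    """Shared covariates/treatment/sites with one outcome column per entry.

    Used for specificity-style analyses where several outcome scales are
    measured on the same participants but only some carry heterogeneous
    treatment effects.
    """
    table, _ = generate_cohort(
        spec.model_copy(update={"missing_rate": 0.0, "modifier_terms": [], "tau_intercept": 0.0})
    )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 815]))
    names = table.covariate_names
    sites = pd.factorize(table.cluster)[0]
    frame = table.to_frame().drop(columns=["outcome"])
    truths: dict[str, GroundTruth] = {}
    for col, ospec in outcomes.items():
        sub = CohortSpec.model_validate(
            {
                **spec.model_dump(),
                "baseline_coefs": ospec.baseline_coefs,
                "tau_intercept": ospec.tau_intercept,
                "modifier_terms": [
                    t if isinstance(t, dict) else t.model_dump() for t in ospec.modifier_terms
                ],
            }
        )
        tau_fn = _tau_function(sub, names)
        tau = tau_fn(table.X)
        mu = _linear_index(table.X, names, ospec.baseline_coefs)
        site_effects = rng.normal(0.0, ospec.site_sd, size=spec.n_sites)
        eps = rng.normal(0.0, ospec.noise_sd, size=table.n)
        frame[col] = mu + tau * table.W + site_effects[sites] + eps
        truths[col] = GroundTruth(
            true_ate=float(tau.mean()),
            true_tau=tau_fn,
            modifier_names=[t.covariate for t in ospec.modifier_terms],
            propensity=_propensity_function(spec, names),
            tau_values=tau,
            propensity_values=_propensity_function(spec, names)(table.X),
        )
    return frame, truths


def apply_missingness(table: CohortTable, rate: float, seed: int) -> CohortTable:
    """MCAR-mask covariate cells at the given rate (treatment/outcome/cluster kept)."""
    if not 0 <= rate < 1:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    if rate == 0:
        return table
    rng = np.random.default_rng(seed)
    mask = rng.random(table.X.shape) < rate
    X = table.X.copy()
    X[mask] = np.nan
    return CohortTable(
        X=X,
        W=table.W,
        Y=table.Y,
        cluster=table.cluster,
        covariate_names=list(table.covariate_names),
        covariate_kind=list(table.covariate_kind),
    )


def default_cohort_spec(
    n_participants: int = 6300,
    n_sites: int = 21,
    n_environment: int = 26,
    n_prs: int = 9,
    n_brain: int = 20,
    seed: int = 0,
    **overrides,
) -> CohortSpec:
    """Default multi-site cohort: 55 standardized covariates in three blocks.

    Six of the environment covariates are binary (demographic indicators);
    the rest, all PRS and all brain features are continuous.  Confounding,
    prognostic and modifier coefficients default to moderate values on the
    standardized scale and can be overridden.
    """
    n_env_binary = min(6, n_environment // 4)
    blocks = [
        CovariateBlock(name="environment", count=n_environment - n_env_binary, kind="continuous"),
        CovariateBlock(name="environment", count=n_env_binary, kind="binary")
        if n_env_binary
        else None,
        CovariateBlock(name="prs", count=n_prs, kind="continuous"),
        CovariateBlock(name="brain", count=n_brain, kind="continuous"),
    ]
    blocks = [b for b in blocks if b is not None]
    spec = CohortSpec(n_participants=n_participants, n_sites=n_sites, covariate_blocks=blocks, seed=seed)
    names = spec.covariate_names
    defaults = dict(
        propensity_coefs={names[0]: 0.4, names[1]: 0.3, names[2]: -0.3},
        baseline_coefs={names[0]: 0.5, names[3]: 0.4, names[4]: -0.3},
        tau_intercept=1.0,
        noise_sd=1.0,
        site_sd=0.2,
        block_correlation=0.3,
    )
    defaults.update(overrides)
    return CohortSpec.model_validate({**spec.model_dump(), **defaults})


def three_modifier_spec(
    n_participants: int = 4000,
    coefficient: float = 0.5,
    seed: int = 0,
    **overrides,
) -> CohortSpec:
    """Reference heterogeneous cohort: three true effect modifiers among 55 covariates.

    One linear, one threshold and one saturating modifier of moderate size
    (0.5 SD of outcome per SD of covariate), confounded exposure, additive
    site intercepts, and within-block covariate correlation 0.6 (covariates
    from the same instrument family co-vary, so non-modifier siblings stay
    weakly informative — the regime in which progressive importance-based
    pruning is meaningful).  Used by the recovery experiments throughout.
    """
    defaults = dict(
        block_correlation=0.6,
        propensity_coefs={"environment__env05": 0.4, "environment__env02": 0.3},
        baseline_coefs={"environment__env02": 0.5, "prs__prs01": 0.4},
        modifier_terms=[
            {"covariate": "environment__env01", "form": "linear", "coefficient": coefficient},
            {"covariate": "environment__env03", "form": "threshold", "coefficient": coefficient},
            {"covariate": "prs__prs02", "form": "saturating", "coefficient": -coefficient},
        ],
    )
    defaults.update(overrides)
    return default_cohort_spec(n_participants=n_participants, seed=seed, **defaults)
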