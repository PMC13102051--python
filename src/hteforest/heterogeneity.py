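"""Heterogeneity diagnostics: GATE test, risk-group profiling, partial dependence.

The group-average-treatment-effect (GATE) test ranks participants by their
predicted individual treatment effect, cuts the ranking into near-equal
groups (tertiles by default: low / middle / high risk), and estimates each
group's ATE from the doubly robust scores.  Real heterogeneity shows up as
a monotone increase in group ATEs and a significant high-minus-low
contrast; a forest that merely ranks noise produces flat group ATEs.

Risk-group profiling compares covariate distributions between the low- and
high-risk groups (Welch t-test for continuous covariates, two-proportion
z-test for binary ones) to describe who the vulnerable participants are.

Partial-dependence simulation sweeps one covariate across its empirical
percentile grid while pinning all other covariates at their central values
(median / mode), feeds the synthetic rows to the forest, and classifies the
covariate as a *risk* factor (predicted effect increases), *protective*
(decreases) or *flat* via the Spearman rank correlation of the curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .estimands import AIPWScores, AteResult, average_treatment_effect, bh_fdr
from .forest import CausalForest
from .synthetic import CohortTable


@dataclass
class PairwiseContrast:
    pair: tuple[str, str]  # e.g. ("Q3", "Q1")
    difference: float
    t_stat: float
    p_value: float
    fdr_q: float


@dataclass
class GateResult:
    group_labels: list[str]
    group_assignment: np.ndarray  # per-row label
    group_ates: dict[str, AteResult]
    contrasts: list[PairwiseContrast]
    monotonic: bool
    no_ranking_signal: bool = False

    @property
    def headline(self) -> PairwiseContrast | None:
        """The high-minus-low contrast (Qk - Q1)."""
        for c in self.contrasts:
            if c.pair == (self.group_labels[-1], self.group_labels[0]):
                return c
        return None


def gate_test(scores: AIPWScores, oob_tau: np.ndarray, n_groups: int = 3) -> GateResult:
    """Rank by predicted ITE, split into near-equal groups, compare group ATEs."""
    oob_tau = np.asarray(oob_tau, dtype=float)
    n = len(scores.gamma)
    if len(oob_tau) != n:
        raise ValueError("scores and oob_tau are not aligned")
    if n < 3 * n_groups:
        raise ValueError(f"need at least {3 * n_groups} rows for {n_groups} groups")

    no_signal = bool(np.var(oob_tau) < 1e-12)
    order = np.argsort(oob_tau, kind="stable")  # ties broken by row index
    labels = [f"Q{g + 1}" for g in range(n_groups)]
    assignment = np.empty(n, dtype=object)
    chunks = np.array_split(order, n_groups)
    for lab, chunk in zip(labels, chunks):
        assignment[chunk] = lab

    group_ates = {}
    for lab, chunk in zip(labels, chunks):
        sub = AIPWScores(gamma=scores.gamma[chunk], cluster=scores.cluster[chunk])
        if len(np.unique(sub.cluster)) < 2:
            # tiny groups may land in one site; fall back to iid rows
            sub = AIPWScores(gamma=sub.gamma, cluster=np.arange(len(chunk)).astype(str))
        group_ates[lab] = average_treatment_effect(sub)

    contrasts = []
    pairs = [(hi, lo) for i, lo in enumerate(labels) for hi in labels[i + 1 :]]
    pvals = []
    raw = []
    for hi, lo in pairs:
        g_hi = scores.gamma[assignment == hi]
        g_lo = scores.gamma[assignment == lo]
        t, p = stats.ttest_ind(g_hi, g_lo, equal_var=False)
        raw.append((hi, lo, float(g_hi.mean() - g_lo.mean()), float(t), float(p)))
        pvals.append(float(p))
    qvals = bh_fdr(pvals)
    for (hi, lo, diff, t, p), q in zip(raw, qvals):
        contrasts.append(PairwiseContrast(pair=(hi, lo), difference=diff, t_stat=t, p_value=p, fdr_q=float(q)))

    estimates = [group_ates[lab].estimate for lab in labels]
    monotonic = all(a < b for a, b in zip(estimates, estimates[1:]))
    return GateResult(
        group_labels=labels,
        group_assignment=assignment,
        group_ates=group_ates,
        contrasts=contrasts,
        monotonic=monotonic,
        no_ranking_signal=no_signal,
    )


@dataclass
class CovariateContrast:
    covariate: str
    kind: str
    mean_low: float
    mean_high: float
    statistic: float
    p_value: float
    fdr_q: float


@dataclass
class GroupProfile:
    low_label: str
    high_label: str
    contrasts: list[CovariateContrast]

    def significant(self, alpha: float = 0.05) -> list[CovariateContrast]:
        return [c for c in self.contrasts if np.isfinite(c.fdr_q) and c.fdr_q < alpha]


def compare_risk_groups(
    table: CohortTable, gate: GateResult, final_covariates: Sequence[str]
) -> GroupProfile:
    """Covariate-wise comparison of the lowest vs highest risk group."""
    if len(gate.group_labels) < 2:
        raise ValueError("need at least two groups to compare")
    lo_lab, hi_lab = gate.group_labels[0], gate.group_labels[-1]
    lo = gate.group_assignment == lo_lab
    hi = gate.group_assignment == hi_lab
    if lo.sum() == 0 or hi.sum() == 0:
        raise ValueError("empty risk group")

    rows = []
    pvals = []
    for name in final_covariates:
        j = table.covariate_names.index(name)
        kind = table.covariate_kind[j]
        x_lo, x_hi = table.X[lo, j], table.X[hi, j]
        if np.allclose(x_lo.mean(), x_hi.mean()) and np.isclose(x_lo.var() + x_hi.var(), 0):
            stat, p = 0.0, 1.0
        elif kind == "binary":
            counts = np.array([x_hi.sum(), x_lo.sum()])
            nobs = np.array([hi.sum(), lo.sum()])
            stat, p = proportions_ztest(counts, nobs)
            if not np.isfinite(stat):
                stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(x_hi, x_lo, equal_var=False)
        rows.append((name, kind, float(x_lo.mean()), float(x_hi.mean()), float(stat), float(p)))
        pvals.append(float(p))
    qvals = bh_fdr(pvals)
    contrasts = [
        CovariateContrast(
            covariate=name, kind=kind, mean_low=ml, mean_high=mh,
            statistic=stat, p_value=p, fdr_q=float(q),
        )
        for (name, kind, ml, mh, stat, p), q in zip(rows, qvals)
    ]
    return GroupProfile(low_label=lo_lab, high_label=hi_lab, contrasts=contrasts)


@dataclass
class PDPCurve:
    covariate: str
    grid: np.ndarray
    percentiles: np.ndarray
    simulated_ite: np.ndarray
    trend: str  # "risk" | "protective" | "flat"
    trend_stat: float


def classify_trend(
    grid: np.ndarray,
    simulated_ite: np.ndarray,
    rho_threshold: float = 0.5,
    eps: float = 0.05,
) -> tuple[str, float]:
    """Classify a PDP curve: risk (rising), protective (falling) or flat.

    A covariate only counts as a risk/protective factor when the curve both
    moves (range > eps on the ITE scale) and moves consistently (|Spearman
    rho| >= rho_threshold).
    """
    simulated_ite = np.asarray(simulated_ite, dtype=float)
    rng_ = simulated_ite.max() - simulated_ite.min()
    if rng_ <= eps or np.var(simulated_ite) == 0 or np.var(grid) == 0:
        return "flat", 0.0
    rho = stats.spearmanr(grid, simulated_ite).statistic
    if not np.isfinite(rho):
        return "flat", 0.0
    if rho >= rho_threshold:
        return "risk", float(rho)
    if rho <= -rho_threshold:
        return "protective", float(rho)
    return "flat", float(rho)


def partial_dependence(
    forest: CausalForest,
    table: CohortTable,
    covariate: str,
    n_points: int = 100,
    rho_threshold: float = 0.5,
    eps: float = 0.05,
) -> PDPCurve:
    """Sweep one covariate over its percentile grid, others pinned at center.

    Continuous covariates use the empirical quantiles at ``n_points``
    equispaced probabilities (0.5%..99.5%); binary covariates use the
    two-point grid {0, 1}.  The synthetic rows are scored with the forest's
    plain (non-out-of-bag) prediction path.
    """
    if covariate not in forest.covariate_names:
        raise ValueError(f"covariate {covariate!r} is not in the forest's covariate space")
    cols = forest.covariate_names
    j = cols.index(covariate)

    ref = table.select_covariates(cols)
    center = np.empty(len(cols))
    for k, name in enumerate(cols):
        col = ref.X[:, k]
        if ref.covariate_kind[k] == "binary":
            center[k] = float(np.round(col.mean()) if not np.isclose(col.mean(), 0.5) else 0.0)
        else:
            center[k] = float(np.median(col))

    if ref.covariate_kind[j] == "binary":
        grid = np.array([0.0, 1.0])
        percentiles = np.array([0.0, 100.0])
    else:
        probs = np.linspace(0.005, 0.995, n_points)
        grid = np.quantile(ref.X[:, j], probs)
        percentiles = probs * 100

    M = np.tile(center, (len(grid), 1))
    M[:, j] = grid
    ite = forest.predict(M)
    trend, rho = classify_trend(grid, ite, rho_threshold=rho_threshold, eps=eps)
    return PDPCurve(
        covariate=covariate, grid=grid, percentiles=percentiles,
        simulated_ite=ite, trend=trend, trend_stat=rho,
    )
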