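"""Doubly robust estimands: AIPW scores, cluster-robust ATE, calibration test.

The augmented inverse-propensity weighting (AIPW) score of participant i is

    Gamma_i = tau_hat(X_i)
            + (W_i - e_hat_i) / (e_hat_i (1 - e_hat_i))
              * (Y_i - m_hat_i - (W_i - e_hat_i) * tau_hat(X_i))

where tau_hat is the forest's out-of-bag CATE prediction and e_hat, m_hat
are out-of-bag nuisance estimates.  The sample mean of Gamma estimates the
ATE and is consistent if *either* nuisance is correct (double robustness).
Inference aggregates influence within sites: with G clusters and cluster
sums of the centered scores U_g, Var(ATE-hat) = sum_g U_g^2 / n^2.

The calibration test is the best-linear-predictor regression of the
residualized outcome on the mean forest prediction and the demeaned
prediction, both interacted with the residualized treatment:

    Y - m_hat  ~  alpha * taubar (W - e_hat)  +  beta * (tau_hat - taubar)(W - e_hat)

alpha ("model fit") near 1 means the average prediction is well calibrated;
beta ("heterogeneity index") near 1 means the differential predictions track
real effect heterogeneity; a one-sided test of beta > 0 is the evidence that
heterogeneity exists at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .forest import NuisanceFits
from .synthetic import CohortTable


@dataclass
class AIPWScores:
    """Per-participant doubly robust influence scores with site labels."""

    gamma: np.ndarray
    cluster: np.ndarray

    def __post_init__(self):
        if len(self.gamma) != len(self.cluster):
            raise ValueError("gamma and cluster must be aligned")
        if not np.all(np.isfinite(self.gamma)):
            raise ValueError("non-finite AIPW scores")


@dataclass
class AteResult:
    estimate: float
    se: float
    p_value: float
    n: int
    n_clusters: int
    fdr_q: float | None = None
    degenerate: bool = False


@dataclass
class CalibrationResult:
    model_fit_coef: float
    heterogeneity_index: float
    se_alpha: float
    se_beta: float
    p_alpha: float  # one-sided, coef > 0
    p_beta: float
    degenerate: bool = False
    fdr_q_alpha: float | None = None
    fdr_q_beta: float | None = None


def aipw_scores(table: CohortTable, nuisance: NuisanceFits, oob_tau: np.ndarray) -> AIPWScores:
    """Compute the AIPW score row-wise from the formula above."""
    oob_tau = np.asarray(oob_tau, dtype=float)
    missing = np.flatnonzero(~np.isfinite(oob_tau))
    if missing.size:
        raise ValueError(
            f"out-of-bag tau is undefined for rows {missing[:10].tolist()}"
            + ("..." if missing.size > 10 else "")
        )
    e = nuisance.e_hat
    resid = table.Y - nuisance.m_hat - (table.W - e) * oob_tau
    gamma = oob_tau + (table.W - e) / (e * (1.0 - e)) * resid
    return AIPWScores(gamma=gamma, cluster=np.asarray(table.cluster))


def _cluster_se(values: np.ndarray, cluster: np.ndarray) -> tuple[float, int]:
    """SE of the mean with influence aggregated within clusters."""
    n = len(values)
    centered = values - values.mean()
    sums = {}
    for v, c in zip(centered, cluster):
        sums[c] = sums.get(c, 0.0) + v
    u = np.array(list(sums.values()))
    return float(np.sqrt((u**2).sum()) / n), len(u)


def average_treatment_effect(scores: AIPWScores) -> AteResult:
    """ATE = mean(Gamma) with cluster-robust SE and two-sided normal p-value."""
    clusters = np.unique(scores.cluster)
    if len(clusters) < 2:
        raise ValueError(
            "only one cluster present; pass per-row unique labels for an unclustered analysis"
        )
    est = float(scores.gamma.mean())
    se, n_clusters = _cluster_se(scores.gamma, scores.cluster)
    if se == 0.0:
        return AteResult(
            estimate=est, se=0.0, p_value=float("nan"),
            n=len(scores.gamma), n_clusters=n_clusters, degenerate=True,
        )
    z = est / se
    p = 2.0 * stats.norm.sf(abs(z))
    return AteResult(estimate=est, se=se, p_value=float(p), n=len(scores.gamma), n_clusters=n_clusters)


def calibration_test(
    table: CohortTable,
    nuisance: NuisanceFits,
    oob_tau: np.ndarray,
    clusters: np.ndarray | None = None,
) -> CalibrationResult:
    """Best-linear-predictor calibration of the forest's CATE predictions."""
    oob_tau = np.asarray(oob_tau, dtype=float)
    if not np.all(np.isfinite(oob_tau)):
        raise ValueError("out-of-bag tau contains undefined entries")
    if clusters is None:
        clusters = table.cluster
    taubar = oob_tau.mean()
    if np.var(oob_tau) < 1e-12:
        return CalibrationResult(
            model_fit_coef=float("nan"), heterogeneity_index=float("nan"),
            se_alpha=float("nan"), se_beta=float("nan"),
            p_alpha=float("nan"), p_beta=float("nan"), degenerate=True,
        )
    wres = table.W - nuisance.e_hat
    design = np.column_stack([taubar * wres, (oob_tau - taubar) * wres])
    yres = table.Y - nuisance.m_hat
    model = sm.OLS(yres, design)
    fit = model.fit(cov_type="cluster", cov_kwds={"groups": clusters})
    alpha, beta = fit.params
    se_a, se_b = fit.bse
    # one-sided p-values for coef > 0 using the cluster-robust normal approx
    p_a = float(stats.norm.sf(alpha / se_a)) if se_a > 0 else float("nan")
    p_b = float(stats.norm.sf(beta / se_b)) if se_b > 0 else float("nan")
    return CalibrationResult(
        model_fit_coef=float(alpha), heterogeneity_index=float(beta),
        se_alpha=float(se_a), se_beta=float(se_b), p_alpha=p_a, p_beta=p_b,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values for one declared family of tests."""
    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    q = np.full(p.shape, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
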