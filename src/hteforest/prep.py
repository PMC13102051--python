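"""Data preparation: complete-case filtering, near-zero-variance removal,
and covariate screening by adjusted regression.

Screening mirrors a common dimensionality-reduction step for large feature
blocks (e.g. brain metrics): each candidate is regressed on the outcome
together with a fixed adjustment set (sociodemographics, polygenic scores),
p-values of the candidate coefficients are Benjamini-Hochberg adjusted
across the block, and only candidates with q below the threshold enter the
causal-forest stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimands import bh_fdr
from .synthetic import CohortTable


def complete_case_filter(table: CohortTable) -> tuple[CohortTable, int]:
    """Drop every row with a missing covariate, treatment or outcome.

    No imputation is performed.  Returns the filtered table and the number
    of rows removed.
    """
    ok = (
        ~np.isnan(table.X).any(axis=1)
        & np.isfinite(table.Y)
        & np.isfinite(table.W.astype(float))
    )
    removed = int((~ok).sum())
    if not ok.any():
        raise ValueError("complete-case filtering removed every row")
    return table.subset_rows(np.flatnonzero(ok)), removed


def drop_near_zero_variance(
    table: CohortTable, freq_ratio: float = 19.0, unique_pct: float = 0.1
) -> tuple[CohortTable, list[str]]:
    """Remove covariates whose distribution is too degenerate to split on.

    A covariate is dropped when the ratio of the most to the second most
    frequent value exceeds ``freq_ratio`` AND the fraction of distinct
    values is below ``unique_pct``; constant columns are always dropped.
    """
    dropped = []
    for j, name in enumerate(table.covariate_names):
        col = table.X[:, j]
        col = col[~np.isnan(col)]
        values, counts = np.unique(col, return_counts=True)
        if len(values) <= 1:
            dropped.append(name)
            continue
        counts = np.sort(counts)[::-1]
        ratio = counts[0] / counts[1]
        unique_frac = len(values) / len(col)
        if ratio > freq_ratio and unique_frac < unique_pct:
            dropped.append(name)
    keep = [n for n in table.covariate_names if n not in dropped]
    return table.select_covariates(keep), dropped


@dataclass
class ScreenResult:
    """Per-candidate adjusted-regression screening results."""

    table: pd.DataFrame  # columns: feature, coefficient, p_value, fdr_q, selected
    alpha: float

    @property
    def selected(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "feature"])


def screen_features(
    table: CohortTable,
    candidate_features: Sequence[str],
    adjustment_set: Sequence[str],
    alpha: float = 0.05,
    outcome: np.ndarray | None = None,
) -> ScreenResult:
    """OLS screen of each candidate against the outcome, given the adjustment set.

    Raises when the adjustment set is collinear (including a candidate that
    duplicates an adjustment covariate), naming the offending columns.
    """
    overlap = set(candidate_features) & set(adjustment_set)
    if overlap:
        raise ValueError(f"candidates overlap the adjustment set: {sorted(overlap)}")
    y = table.Y if outcome is None else np.asarray(outcome, dtype=float)

    adj_idx = [table.covariate_names.index(a) for a in adjustment_set]
    Z = table.X[:, adj_idx]
    base = np.column_stack([np.ones(table.n), Z])
    if np.linalg.matrix_rank(base) < base.shape[1]:
        raise ValueError(f"collinear adjustment set: {list(adjustment_set)}")

    rows = []
    pvals = []
    for name in candidate_features:
        x = table.X[:, table.covariate_names.index(name)]
        design = np.column_stack([base, x])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(
                f"candidate {name!r} is collinear with the adjustment set {list(adjustment_set)}"
            )
        fit = sm.OLS(y, design).fit()
        rows.append((name, float(fit.params[-1]), float(fit.pvalues[-1])))
        pvals.append(float(fit.pvalues[-1]))
    q = bh_fdr(pvals)
    frame = pd.DataFrame(
        {
            "feature": [r[0] for r in rows],
            "coefficient": [r[1] for r in rows],
            "p_value": [r[2] for r in rows],
            "fdr_q": q,
            "selected": q < alpha,
        }
    )
    return ScreenResult(table=frame, alpha=alpha)
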