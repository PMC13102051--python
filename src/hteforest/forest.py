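"""Honest causal forests with seed-ensemble merging and split-frequency importance.

The forest estimates the conditional average treatment effect tau(x) from a
cohort with binary treatment W, continuous outcome Y and site clustering.
Estimation follows the generalized-random-forest recipe:

1. *Nuisance orthogonalization*: out-of-bag regression forests estimate the
   propensity e(x) = P(W=1 | X=x) and the conditional mean m(x) = E[Y | X=x];
   trees are then grown on the residuals W - e(X) and Y - m(X).
2. *Honesty*: each tree's subsample is split in half — one half chooses the
   splits, the disjoint half estimates the leaf effects — removing the
   adaptive-split bias of naive recursive partitioning.
3. *Cluster-aware subsampling*: whole sites are subsampled, not rows, so
   forest variability reflects between-site variability.

``oob_tau`` holds the out-of-bag prediction for each training row (averaging
only trees whose subsample excluded that row's site), the quantity all
downstream doubly-robust machinery consumes.  Variable importance is the
depth-weighted split frequency per covariate.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from . import _tree
from .synthetic import CohortTable

#: propensity estimates are clipped to this interval to protect
#: inverse-propensity weights from extreme values (overlap safeguard)
PROPENSITY_CLIP = (0.05, 0.95)


@dataclass(frozen=True)
class ForestParams:
    """Tuning parameters of one causal forest (before seed-ensembling)."""

    num_trees: int = 500
    honesty_fraction: float = 0.5
    subsample_rate: float = 0.5
    min_node_size: int = 5
    mtry: int | None = None  # default: ceil(sqrt(p)) + 20, capped at p
    importance_decay: float = 2.0
    depth_cap: int = 4

    def resolve_mtry(self, p: int) -> int:
        if self.mtry is not None:
            return min(self.mtry, p)
        return min(int(np.ceil(np.sqrt(p))) + 20, p)


@dataclass
class NuisanceFits:
    """Out-of-bag nuisance estimates: propensity e_hat and outcome mean m_hat."""

    e_hat: np.ndarray
    m_hat: np.ndarray

    def __post_init__(self):
        lo, hi = PROPENSITY_CLIP
        self.e_hat = np.clip(np.asarray(self.e_hat, dtype=float), lo, hi)
        self.m_hat = np.asarray(self.m_hat, dtype=float)
        if self.e_hat.shape != self.m_hat.shape:
            raise ValueError("e_hat and m_hat must have equal length")


def fit_nuisance(
    table: CohortTable,
    n_estimators: int = 200,
    min_samples_leaf: int = 5,
    seed: int = 0,
    oracle_e: Callable[[np.ndarray], np.ndarray] | None = None,
    oracle_m: Callable[[np.ndarray], np.ndarray] | None = None,
) -> NuisanceFits:
    """Out-of-bag random-forest estimates of e(x) and m(x).

    Row i's estimate never uses row i (bagging out-of-bag predictions).
    ``oracle_e`` / ``oracle_m`` bypass fitting and evaluate a user-supplied
    function row-wise — used when the true nuisances are known (simulation).
    """
    arms = np.unique(table.W)
    if len(arms) < 2:
        raise ValueError("no overlap: only one treatment arm present")

    def _oob_regression(target: np.ndarray, offset: int) -> np.ndarray:
        rf = RandomForestRegressor(
            n_estimators=n_estimators,
            min_samples_leaf=min_samples_leaf,
            max_features="sqrt",
            oob_score=True,
            bootstrap=True,
            random_state=seed + offset,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rows never OOB warn; handled below
            rf.fit(table.X, target)
        pred = rf.oob_prediction_
        bad = ~np.isfinite(pred)
        if bad.any():
            pred = pred.copy()
            pred[bad] = target.mean()
        return pred

    e_hat = oracle_e(table.X) if oracle_e is not None else _oob_regression(table.W.astype(float), 0)
    m_hat = oracle_m(table.X) if oracle_m is not None else _oob_regression(table.Y, 1)
    return NuisanceFits(e_hat=e_hat, m_hat=m_hat)


@dataclass
class CausalForest:
    """A fitted honest causal forest (possibly a merged seed ensemble)."""

    trees: list[tuple]
    params: ForestParams
    seeds: list[int]
    covariate_names: list[str]
    oob_tau: np.ndarray
    split_counts: np.ndarray  # p x MAX_DEPTH_BINS
    in_sample: np.ndarray = field(repr=False)  # num_trees x n bool
    fingerprint: str = ""

    @property
    def num_trees(self) -> int:
        return len(self.trees)

    @property
    def p(self) -> int:
        return len(self.covariate_names)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """tau-hat(x): kernel-weighted Cov(A,R)/Var(A) aggregated over all trees."""
        X = np.ascontiguousarray(np.atleast_2d(X), dtype=float)
        rows = np.arange(X.shape[0], dtype=np.int64)
        return _kernel_predict(self.trees, X, [rows] * len(self.trees))

    def save(self, path) -> None:
        arrays = {}
        for t, tr in enumerate(self.trees):
            for name, arr in zip(TREE_FIELDS, tr):
                arrays[f"tree{t}_{name}"] = arr
        np.savez_compressed(
            path,
            __num_trees=np.array([len(self.trees)]),
            __seeds=np.array(self.seeds),
            __oob_tau=self.oob_tau,
            __split_counts=self.split_counts,
            __in_sample=self.in_sample,
            __names=np.array(self.covariate_names),
            __params=np.array(
                [
                    self.params.num_trees,
                    self.params.honesty_fraction,
                    self.params.subsample_rate,
                    self.params.min_node_size,
                    -1 if self.params.mtry is None else self.params.mtry,
                    self.params.importance_decay,
                    self.params.depth_cap,
                ]
            ),
            __fingerprint=np.array([self.fingerprint]),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "CausalForest":
        bundle = np.load(path, allow_pickle=False)
        n_trees = int(bundle["__num_trees"][0])
        trees = [
            tuple(bundle[f"tree{t}_{name}"] for name in TREE_FIELDS) for t in range(n_trees)
        ]
        pv = bundle["__params"]
        params = ForestParams(
            num_trees=int(pv[0]),
            honesty_fraction=float(pv[1]),
            subsample_rate=float(pv[2]),
            min_node_size=int(pv[3]),
            mtry=None if pv[4] < 0 else int(pv[4]),
            importance_decay=float(pv[5]),
            depth_cap=int(pv[6]),
        )
        return cls(
            trees=trees,
            params=params,
            seeds=[int(s) for s in bundle["__seeds"]],
            covariate_names=[str(s) for s in bundle["__names"]],
            oob_tau=bundle["__oob_tau"],
            split_counts=bundle["__split_counts"],
            in_sample=bundle["__in_sample"],
            fingerprint=str(bundle["__fingerprint"][0]),
        )


def _table_fingerprint(table: CohortTable) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(table.X).tobytes())
    h.update(np.ascontiguousarray(table.W).tobytes())
    h.update(np.ascontiguousarray(table.Y).tobytes())
    h.update("|".join(map(str, table.cluster)).encode())
    return h.hexdigest()


TREE_FIELDS = ("feature", "threshold", "left", "right", "depth", "sa", "sr", "sar", "saa", "cnt")


def _kernel_predict(trees, X, row_lists) -> np.ndarray:
    """Aggregate leaf moments across trees and solve the weighted moment equation."""
    n = X.shape[0]
    acc = [np.zeros(n) for _ in range(5)]
    acc_trees = np.zeros(n, dtype=np.int64)
    for tr, rows in zip(trees, row_lists):
        feature, threshold, left, right, _depth, sa, sr, sar, saa, cnt = tr
        _tree.accumulate_kernel(
            feature, threshold, left, right, sa, sr, sar, saa, cnt,
            X, rows, acc[0], acc[1], acc[2], acc[3], acc[4], acc_trees,
        )
    out = np.empty(n)
    _tree.solve_kernel(acc[0], acc[1], acc[2], acc[3], acc[4], acc_trees, out)
    return out


def _recompute_oob(trees, in_sample, X) -> np.ndarray:
    row_lists = [np.flatnonzero(~mask).astype(np.int64) for mask in in_sample]
    return _kernel_predict(trees, np.ascontiguousarray(X, dtype=float), row_lists)


def fit_causal_forest(
    table: CohortTable,
    nuisance: NuisanceFits,
    params: ForestParams = ForestParams(),
    seed: int = 0,
) -> CausalForest:
    """Fit one honest causal forest on residualized treatment and outcome."""
    n = table.n
    if len(nuisance.e_hat) != n:
        raise ValueError("nuisance fits not aligned with table")
    A = table.W - nuisance.e_hat
    R = table.Y - nuisance.m_hat
    X = np.ascontiguousarray(table.X, dtype=float)
    mtry = params.resolve_mtry(table.p)

    cluster_codes, cluster_index = _factorize(table.cluster)
    n_clusters = len(cluster_index)
    n_sub_clusters = max(1, int(round(params.subsample_rate * n_clusters)))
    cluster_rows = [np.flatnonzero(cluster_codes == c) for c in range(n_clusters)]

    # rough subsample size check for min_node_size
    approx_sub = int(params.subsample_rate * n * params.honesty_fraction)
    if params.min_node_size > max(approx_sub, 1):
        raise ValueError(
            f"min_node_size={params.min_node_size} exceeds the expected "
            f"honest subsample size (~{approx_sub})"
        )

    root = np.random.SeedSequence([seed & 0x7FFFFFFF, 0x5EED])
    tree_seeds = root.generate_state(2 * params.num_trees, dtype=np.uint32)
    trees = []
    in_sample = np.zeros((params.num_trees, n), dtype=bool)
    split_counts = np.zeros((table.p, _tree.MAX_DEPTH_BINS), dtype=np.int64)
    for t in range(params.num_trees):
        rng = np.random.default_rng(int(tree_seeds[2 * t]))
        chosen = rng.choice(n_clusters, size=n_sub_clusters, replace=False)
        rows = np.concatenate([cluster_rows[c] for c in np.sort(chosen)])
        rng.shuffle(rows)
        n_split = max(2 * params.min_node_size, int(round(params.honesty_fraction * len(rows))))
        n_split = min(n_split, len(rows) - 1)
        split_rows = np.sort(rows[:n_split]).astype(np.int64)
        est_rows = np.sort(rows[n_split:]).astype(np.int64)
        tr = _tree.grow_tree(
            X, A, R, split_rows, est_rows, mtry, params.min_node_size,
            int(tree_seeds[2 * t + 1]) & 0x7FFFFFFF,
        )
        trees.append(tr)
        in_sample[t, rows] = True
        split_counts += _tree.split_count_matrix(tr[0], tr[4], table.p)

    oob = _recompute_oob(trees, in_sample, X)
    return CausalForest(
        trees=trees,
        params=params,
        seeds=[seed],
        covariate_names=list(table.covariate_names),
        oob_tau=oob,
        split_counts=split_counts,
        in_sample=in_sample,
        fingerprint=_table_fingerprint(table),
    )


def _factorize(labels: np.ndarray) -> tuple[np.ndarray, list]:
    uniq, codes = np.unique(labels, return_inverse=True)
    return codes, list(uniq)


def merge_forests(forests: Sequence[CausalForest], table: CohortTable) -> CausalForest:
    """Concatenate seed-ensemble forests fitted on the identical table.

    Out-of-bag predictions are recomputed over the union of trees, so the
    merged forest behaves exactly like one big forest.
    """
    if not forests:
        raise ValueError("no forests to merge")
    head = forests[0]
    fp = _table_fingerprint(table)
    for f in forests:
        if f.fingerprint != fp:
            raise ValueError("forests were not fitted on the given table")
        if f.params != head.params:
            raise ValueError("forests have mismatched params")
        if f.covariate_names != head.covariate_names:
            raise ValueError("forests have mismatched covariates")
    trees = [t for f in forests for t in f.trees]
    in_sample = np.vstack([f.in_sample for f in forests])
    X = np.ascontiguousarray(table.X, dtype=float)
    return CausalForest(
        trees=trees,
        params=head.params,
        seeds=[s for f in forests for s in f.seeds],
        covariate_names=list(head.covariate_names),
        oob_tau=_recompute_oob(trees, in_sample, X),
        split_counts=sum(f.split_counts for f in forests),
        in_sample=in_sample,
        fingerprint=fp,
    )


def fit_seed_ensemble(
    table: CohortTable,
    nuisance: NuisanceFits,
    params: ForestParams = ForestParams(),
    seeds: Sequence[int] = (1, 2, 3),
) -> CausalForest:
    """Fit one forest per seed and merge them into a single big forest."""
    return merge_forests(
        [fit_causal_forest(table, nuisance, params, seed=s) for s in seeds], table
    )


def variable_importance(forest: CausalForest) -> np.ndarray:
    """Depth-weighted split-frequency importance, normalized to sum to 1.

    importance_j ∝ sum_d d^(-decay) * (#splits on covariate j at depth d),
    for depths 1..depth_cap.  Deeper splits are ignored, mirroring the
    convention that early splits matter most.
    """
    decay = forest.params.importance_decay
    cap = min(forest.params.depth_cap, forest.split_counts.shape[1])
    weights = np.arange(1, cap + 1, dtype=float) ** (-decay)
    raw = forest.split_counts[:, :cap] @ weights
    total = raw.sum()
    if total <= 0:
        warnings.warn("forest has no internal nodes; importance is a zero vector")
        return np.zeros(forest.p)
    return raw / total
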