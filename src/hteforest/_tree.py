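"""Low-level honest tree growing for the causal forest.

A tree is grown on the *split half* of a subsample only; leaf effects are
then estimated on the disjoint *estimation half* (honesty).  Splitting uses
gradient-style pseudo-outcomes: within a node with residualized treatment
``A = W - e(X)`` and outcome ``R = Y - m(X)``, the node effect is
``tau = Cov(A, R) / Var(A)`` and each observation contributes

    rho_i = (A_i - Abar) * ((R_i - Rbar) - (A_i - Abar) * tau)

a first-order influence on tau.  A CART scan on rho (maximizing
``S_L^2/n_L + S_R^2/n_R``) then picks the split that most separates the
children's effect estimates.  Ties break to the lowest feature index and
lowest threshold, which keeps runs reproducible under column shuffles.

Each node stores the estimation-half moment sums (sum A, sum R, sum A*R,
sum A^2, count).  Prediction does not average per-leaf ratios — tiny honest
leaves make that ratio unstable — but aggregates the moments across trees
with forest kernel weights (each tree's leaf contributes its moments scaled
by 1/|leaf|) and solves the weighted moment equation

    tau(x) = Cov_w(A, R) / Var_w(A)

once per target point, the locally-weighted estimator the forest defines.

All functions here are numba-compiled and operate on flat arrays; the
public forest API lives in :mod:`hteforest.forest`.
"""

import numpy as np
from numba import njit

#: split depths deeper than this are tallied in the last bin of the
#: per-depth split-count matrix (totals stay exact).
MAX_DEPTH_BINS = 32


@njit(cache=True)
def grow_tree(X, A, R, split_rows, est_rows, mtry, min_node, seed):
    """Grow one honest tree; returns flat node arrays.

    feature[k] == -1 marks a leaf.  Node moment arrays (sa, sr, sar, saa,
    cnt) hold estimation-half sums for the kernel-weighted prediction.
    """
    np.random.seed(seed)
    n_s_total = split_rows.shape[0]
    p = X.shape[1]
    max_nodes = 4 * (n_s_total // min_node) + 8

    feature = np.full(max_nodes, -1, np.int32)
    threshold = np.zeros(max_nodes)
    left = np.full(max_nodes, -1, np.int32)
    right = np.full(max_nodes, -1, np.int32)
    depth_arr = np.zeros(max_nodes, np.int32)
    node_sa = np.zeros(max_nodes)
    node_sr = np.zeros(max_nodes)
    node_sar = np.zeros(max_nodes)
    node_saa = np.zeros(max_nodes)
    node_cnt = np.zeros(max_nodes, np.int64)

    srows = split_rows.copy()
    erows = est_rows.copy()
    rho = np.zeros(n_s_total)
    vals = np.zeros(n_s_total)
    tmp = np.empty(max(n_s_total, erows.shape[0]), np.int64)
    perm = np.arange(p)

    # stack of (node_id, s_lo, s_hi, e_lo, e_hi, depth)
    cap = max_nodes
    st_node = np.zeros(cap, np.int32)
    st_slo = np.zeros(cap, np.int64)
    st_shi = np.zeros(cap, np.int64)
    st_elo = np.zeros(cap, np.int64)
    st_ehi = np.zeros(cap, np.int64)
    st_depth = np.zeros(cap, np.int32)

    n_nodes = 1
    st_node[0] = 0
    st_slo[0] = 0
    st_shi[0] = n_s_total
    st_elo[0] = 0
    st_ehi[0] = erows.shape[0]
    st_depth[0] = 0
    top = 1

    while top > 0:
        top -= 1
        node = st_node[top]
        s_lo = st_slo[top]
        s_hi = st_shi[top]
        e_lo = st_elo[top]
        e_hi = st_ehi[top]
        depth = st_depth[top]

        # estimation-half moments of this node
        for k in range(e_lo, e_hi):
            i = erows[k]
            node_sa[node] += A[i]
            node_sr[node] += R[i]
            node_sar[node] += A[i] * R[i]
            node_saa[node] += A[i] * A[i]
        node_cnt[node] = e_hi - e_lo
        depth_arr[node] = depth

        # stopping depends on the split half only: the estimation half must
        # never influence tree structure (honesty)
        n_s = s_hi - s_lo
        if n_s < 2 * min_node or n_nodes + 2 > max_nodes:
            continue

        # node pseudo-outcomes on the split half
        sa = 0.0
        sr = 0.0
        for k in range(s_lo, s_hi):
            i = srows[k]
            sa += A[i]
            sr += R[i]
        ma = sa / n_s
        mr = sr / n_s
        num = 0.0
        den = 0.0
        for k in range(s_lo, s_hi):
            i = srows[k]
            da = A[i] - ma
            num += da * (R[i] - mr)
            den += da * da
        if den < 1e-12:
            continue
        tau_s = num / den
        st_rho = 0.0
        for k in range(s_lo, s_hi):
            i = srows[k]
            da = A[i] - ma
            rho[k] = da * ((R[i] - mr) - da * tau_s)
            st_rho += rho[k]

        # draw mtry candidate features without replacement, scan in index
        # order so equal gains resolve to the lowest feature index
        m = mtry if mtry < p else p
        for j in range(m):
            r = j + np.random.randint(p - j)
            perm[j], perm[r] = perm[r], perm[j]
        cand = np.sort(perm[:m])

        base_gain = st_rho * st_rho / n_s
        best_gain = base_gain + 1e-10
        best_f = -1
        best_thr = 0.0
        for cidx in range(m):
            f = cand[cidx]
            for k in range(s_lo, s_hi):
                vals[k - s_lo] = X[srows[k], f]
            order = np.argsort(vals[:n_s], kind="mergesort")
            sl = 0.0
            for i in range(n_s - min_node):
                sl += rho[s_lo + order[i]]
                nl = i + 1
                if nl < min_node:
                    continue
                vlo = vals[order[i]]
                vhi = vals[order[i + 1]]
                if vlo >= vhi:
                    continue
                nr = n_s - nl
                srr = st_rho - sl
                gain = sl * sl / nl + srr * srr / nr
                if gain > best_gain:
                    best_gain = gain
                    best_f = f
                    best_thr = 0.5 * (vlo + vhi)

        if best_f < 0:
            continue

        # stable partition of both halves on the chosen split
        s_mid = _partition(X, srows, s_lo, s_hi, best_f, best_thr, tmp)
        e_mid = _partition(X, erows, e_lo, e_hi, best_f, best_thr, tmp)
        if s_mid == s_lo or s_mid == s_hi:
            continue

        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        feature[node] = best_f
        threshold[node] = best_thr
        left[node] = lid
        right[node] = rid

        st_node[top] = rid
        st_slo[top] = s_mid
        st_shi[top] = s_hi
        st_elo[top] = e_mid
        st_ehi[top] = e_hi
        st_depth[top] = depth + 1
        top += 1
        st_node[top] = lid
        st_slo[top] = s_lo
        st_shi[top] = s_mid
        st_elo[top] = e_lo
        st_ehi[top] = e_mid
        st_depth[top] = depth + 1
        top += 1

    return (
        feature[:n_nodes],
        threshold[:n_nodes],
        left[:n_nodes],
        right[:n_nodes],
        depth_arr[:n_nodes],
        node_sa[:n_nodes],
        node_sr[:n_nodes],
        node_sar[:n_nodes],
        node_saa[:n_nodes],
        node_cnt[:n_nodes],
    )


@njit(cache=True)
def _partition(X, rows, lo, hi, f, thr, tmp):
    """Stable in-place partition of rows[lo:hi]: <= thr first; returns the cut."""
    nl = 0
    nr = 0
    for k in range(lo, hi):
        i = rows[k]
        if X[i, f] <= thr:
            rows[lo + nl] = i
            nl += 1
        else:
            tmp[nr] = i
            nr += 1
    for k in range(nr):
        rows[lo + nl + k] = tmp[k]
    return lo + nl


@njit(cache=True)
def accumulate_kernel(
    feature, threshold, left, right, sa, sr, sar, saa, cnt,
    X, rows, acc_wa, acc_wr, acc_war, acc_waa, acc_w, acc_trees,
):
    """Add one tree's leaf moments (weighted by 1/|leaf|) for the given rows."""
    for k in range(rows.shape[0]):
        i = rows[k]
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        c = cnt[node]
        if c > 0:
            w = 1.0 / c
            acc_wa[i] += w * sa[node]
            acc_wr[i] += w * sr[node]
            acc_war[i] += w * sar[node]
            acc_waa[i] += w * saa[node]
            acc_w[i] += 1.0
            acc_trees[i] += 1


@njit(cache=True)
def solve_kernel(acc_wa, acc_wr, acc_war, acc_waa, acc_w, acc_trees, out):
    """tau(x) = Cov_w(A,R) / Var_w(A) from the accumulated weighted moments."""
    for i in range(out.shape[0]):
        if acc_trees[i] == 0:
            out[i] = np.nan
            continue
        w = acc_w[i]
        var = acc_waa[i] - acc_wa[i] * acc_wa[i] / w
        if var < 1e-12:
            out[i] = np.nan
            continue
        cov = acc_war[i] - acc_wa[i] * acc_wr[i] / w
        out[i] = cov / var


@njit(cache=True)
def split_count_matrix(feature, depth_arr, p):
    """p x MAX_DEPTH_BINS matrix of split counts; bin d-1 holds depth-d splits."""
    counts = np.zeros((p, MAX_DEPTH_BINS), np.int64)
    for k in range(feature.shape[0]):
        f = feature[k]
        if f >= 0:
            d = depth_arr[k] + 1  # root split has depth 1
            if d > MAX_DEPTH_BINS:
                d = MAX_DEPTH_BINS
            counts[f, d - 1] += 1
    return counts
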