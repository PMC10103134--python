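"""Compiled CART kernels: entropy split search, tree growth, prediction.

These numba kernels are the single implementation of the split criterion and
tree induction; the public functions in :mod:`gagir.forest` are thin wrappers
around them.  All randomness inside a kernel (per-node candidate-feature
draws) comes from a 64-bit LCG seeded per tree, so growth is bit-reproducible
across runs and platforms.

Conventions (fixed for reproducibility):
 - thresholds are midpoints between consecutive distinct sorted values,
 - rows with feature value ≤ threshold go left,
 - split ties are broken toward the lower feature index, then the lower
   threshold (candidates are scanned in ascending index / threshold order
   and only strict gain improvements > 1e-12 replace the incumbent),
 - leaves with tied class counts predict class 0.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: sentinel feature index marking a leaf node
LEAF = -1

_LCG_MULT = np.uint64(6364136223846793005)
_LCG_INC = np.uint64(1442695040888963407)


@njit(cache=True)
def _lcg_next(state):
    return state * _LCG_MULT + _LCG_INC


@njit(cache=True)
def _lcg_below(state, bound):
    """Advance the LCG; return (new_state, uniform integer in [0, bound))."""
    state = _lcg_next(state)
    return state, np.int64((state >> np.uint64(33)) % np.uint64(bound))


@njit(cache=True)
def _entropy2(c0, c1):
    """Shannon entropy in bits of a two-class count pair."""
    n = c0 + c1
    h = 0.0
    if c0 > 0:
        p = c0 / n
        h -= p * np.log2(p)
    if c1 > 0:
        p = c1 / n
        h -= p * np.log2(p)
    return h


@njit(cache=True)
def _scan_split(X, y, samples, start, end, cand, ncand):
    """Best entropy split for rows samples[start:end] over cand[:ncand].

    Returns (feature, threshold, gain); feature is LEAF when no split has
    positive information gain.  cand[:ncand] must be sorted ascending.
    """
    n = end - start
    c0 = 0
    c1 = 0
    for p in range(start, end):
        if y[samples[p]] == 0:
            c0 += 1
        else:
            c1 += 1
    best_gain = 0.0
    best_feat = LEAF
    best_thr = 0.0
    if c0 == 0 or c1 == 0:
        return best_feat, best_thr, best_gain
    parent_h = _entropy2(c0, c1)
    vv = np.empty(n)
    for ci in range(ncand):
        fi = cand[ci]
        for p in range(n):
            vv[p] = X[samples[start + p], fi]
        order = np.argsort(vv)
        l0 = 0
        l1 = 0
        for i in range(n - 1):
            s = samples[start + order[i]]
            if y[s] == 0:
                l0 += 1
            else:
                l1 += 1
            lo_v = vv[order[i]]
            hi_v = vv[order[i + 1]]
            if lo_v < hi_v:
                nl = i + 1
                nr = n - nl
                child_h = (nl * _entropy2(l0, l1) + nr * _entropy2(c0 - l0, c1 - l1)) / n
                gain = parent_h - child_h
                if gain > best_gain + 1e-12:
                    best_gain = gain
                    best_feat = fi
                    best_thr = 0.5 * (lo_v + hi_v)
    return best_feat, best_thr, best_gain


@njit(cache=True)
def _grow_tree(
    X,
    y,
    samples,
    n_candidates,
    max_depth,
    min_samples_split,
    seed,
    feat,
    thr,
    left,
    right,
    cnt0,
    cnt1,
):
    """Grow one tree in place on ``samples`` (a bootstrap index array).

    Node arrays (feat/thr/left/right/cnt0/cnt1) must hold 2*len(samples)+1
    entries.  Returns the number of nodes used.
    """
    m = samples.shape[0]
    f = X.shape[1]
    state = _lcg_next(np.uint64(seed) ^ np.uint64(0x9E3779B97F4A7C15))

    perm = np.arange(f)
    cand = np.empty(n_candidates, dtype=np.int64)
    max_nodes = feat.shape[0]
    stack_start = np.empty(max_nodes, dtype=np.int64)
    stack_end = np.empty(max_nodes, dtype=np.int64)
    stack_depth = np.empty(max_nodes, dtype=np.int64)
    stack_node = np.empty(max_nodes, dtype=np.int64)
    tmp = np.empty(m, dtype=np.int64)

    next_node = 1
    top = 0
    stack_start[0] = 0
    stack_end[0] = m
    stack_depth[0] = 0
    stack_node[0] = 0

    while top >= 0:
        start = stack_start[top]
        end = stack_end[top]
        depth = stack_depth[top]
        node = stack_node[top]
        top -= 1

        c0 = 0
        c1 = 0
        for p in range(start, end):
            if y[samples[p]] == 0:
                c0 += 1
            else:
                c1 += 1
        cnt0[node] = c0
        cnt1[node] = c1
        feat[node] = LEAF
        thr[node] = 0.0
        left[node] = LEAF
        right[node] = LEAF

        n = end - start
        if c0 == 0 or c1 == 0 or n < min_samples_split:
            continue
        if max_depth >= 0 and depth >= max_depth:
            continue

        # draw candidate features without replacement (partial Fisher-Yates)
        nc = n_candidates if n_candidates < f else f
        for i in range(nc):
            state, r = _lcg_below(state, f - i)
            j = i + r
            t = perm[i]
            perm[i] = perm[j]
            perm[j] = t
            cand[i] = perm[i]
        # ascending index order so the tie-break is well defined
        for i in range(1, nc):
            key = cand[i]
            j = i - 1
            while j >= 0 and cand[j] > key:
                cand[j + 1] = cand[j]
                j -= 1
            cand[j + 1] = key

        bf, bt, bg = _scan_split(X, y, samples, start, end, cand, nc)
        if bf == LEAF:
            continue

        # stable partition: ≤ threshold left
        nl = 0
        nr = 0
        for p in range(start, end):
            s = samples[p]
            if X[s, bf] <= bt:
                samples[start + nl] = s
                nl += 1
            else:
                tmp[nr] = s
                nr += 1
        for i in range(nr):
            samples[start + nl + i] = tmp[i]

        feat[node] = bf
        thr[node] = bt
        lchild = next_node
        rchild = next_node + 1
        next_node += 2
        left[node] = lchild
        right[node] = rchild

        top += 1
        stack_start[top] = start
        stack_end[top] = start + nl
        stack_depth[top] = depth + 1
        stack_node[top] = lchild
        top += 1
        stack_start[top] = start + nl
        stack_end[top] = end
        stack_depth[top] = depth + 1
        stack_node[top] = rchild

    return next_node


@njit(cache=True)
def _grow_forest(
    X,
    y,
    boot,
    seeds,
    n_candidates,
    max_depth,
    min_samples_split,
    feat,
    thr,
    left,
    right,
    cnt0,
    cnt1,
    node_counts,
):
    """Grow all trees of a forest; boot is the (n_trees, m) bootstrap matrix."""
    n_trees = boot.shape[0]
    for t in range(n_trees):
        samples = boot[t].copy()
        node_counts[t] = _grow_tree(
            X,
            y,
            samples,
            n_candidates,
            max_depth,
            min_samples_split,
            seeds[t],
            feat[t],
            thr[t],
            left[t],
            right[t],
            cnt0[t],
            cnt1[t],
        )


@njit(cache=True)
def _predict_votes(feat, thr, left, right, cnt0, cnt1, X):
    """Per-tree class votes for every row of X: (n_rows, n_trees) int8."""
    n_trees = feat.shape[0]
    n = X.shape[0]
    votes = np.empty((n, n_trees), dtype=np.int8)
    for i in range(n):
        for t in range(n_trees):
            node = 0
            while feat[t, node] != LEAF:
                if X[i, feat[t, node]] <= thr[t, node]:
                    node = left[t, node]
                else:
                    node = right[t, node]
            votes[i, t] = 0 if cnt0[t, node] >= cnt1[t, node] else 1
    return votes


@njit(cache=True)
def _cv_accuracy(X, y, fold_of, n_trees, n_candidates, max_depth, min_samples_split, seed):
    """Cross-validated forest accuracy, entirely in-kernel.

    For every fold, a forest of ``n_trees`` trees is grown on the remaining
    rows (bootstraps drawn by the kernel LCG) and the held-out rows are
    predicted by majority vote (ties to class 0).  Deterministic given
    ``seed``; used as the fitness estimator of the evolutionary search.
    """
    n = X.shape[0]
    max_nodes = 2 * n + 1
    feat = np.empty(max_nodes, dtype=np.int32)
    thr = np.empty(max_nodes)
    left = np.empty(max_nodes, dtype=np.int32)
    right = np.empty(max_nodes, dtype=np.int32)
    cnt0 = np.empty(max_nodes, dtype=np.int32)
    cnt1 = np.empty(max_nodes, dtype=np.int32)
    train_rows = np.empty(n, dtype=np.int64)

    state = _lcg_next(np.uint64(seed) ^ np.uint64(0xA5A5A5A55A5A5A5A))
    nfolds = np.int64(fold_of.max()) + 1
    correct = 0
    total = 0
    for f in range(nfolds):
        m = 0
        for i in range(n):
            if fold_of[i] != f:
                train_rows[m] = i
                m += 1
        if m == n or m == 0:
            continue
        votes1 = np.zeros(n, dtype=np.int64)
        for t in range(n_trees):
            samples = np.empty(m, dtype=np.int64)
            for j in range(m):
                state, r = _lcg_below(state, m)
                samples[j] = train_rows[r]
            state = _lcg_next(state)
            _grow_tree(
                X, y, samples, n_candidates, max_depth, min_samples_split,
                state, feat, thr, left, right, cnt0, cnt1,
            )
            for i in range(n):
                if fold_of[i] == f:
                    node = 0
                    while feat[node] != LEAF:
                        if X[i, feat[node]] <= thr[node]:
                            node = left[node]
                        else:
                            node = right[node]
                    if cnt1[node] > cnt0[node]:
                        votes1[i] += 1
        for i in range(n):
            if fold_of[i] == f:
                pred = 1 if 2 * votes1[i] > n_trees else 0
                total += 1
                if pred == y[i]:
                    correct += 1
    return correct / total
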