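"""Numba-compiled inner loops.

Two hot paths live here: the Gotoh affine-gap dynamic-programming fill used
by every pairwise alignment, and the greedy information-gain decision-tree
grower used by the random forest.  Everything else in the package is plain
numpy/pandas.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Sentinel for unreachable dynamic-programming states.
NEG = -1.0e30


@njit(cache=True)
def gotoh_fill(S, gap_open, gap_extend, local):  # pragma: no cover - numba
    """Fill the three Gotoh matrices for a position-score matrix ``S``.

    ``S[i, j]`` is the score of matching position ``i`` of the first input
    to position ``j`` of the second.  A gap of length ``g`` costs
    ``gap_open + (g - 1) * gap_extend``.  Returns ``(H, Ix, Iy)`` with
    shape ``(n + 1, m + 1)``: ``H`` best score ending in any state,
    ``Ix`` best score ending with a gap in the second input (vertical move),
    ``Iy`` with a gap in the first (horizontal move).
    """
    n, m = S.shape
    H = np.empty((n + 1, m + 1))
    Ix = np.empty((n + 1, m + 1))
    Iy = np.empty((n + 1, m + 1))
    H[0, 0] = 0.0
    Ix[0, 0] = NEG
    Iy[0, 0] = NEG
    for j in range(1, m + 1):
        Ix[0, j] = NEG
        if local:
            Iy[0, j] = NEG
            H[0, j] = 0.0
        else:
            Iy[0, j] = gap_open + (j - 1) * gap_extend
            H[0, j] = Iy[0, j]
    for i in range(1, n + 1):
        Iy[i, 0] = NEG
        if local:
            Ix[i, 0] = NEG
            H[i, 0] = 0.0
        else:
            Ix[i, 0] = gap_open + (i - 1) * gap_extend
            H[i, 0] = Ix[i, 0]
        for j in range(1, m + 1):
            ix = H[i - 1, j] + gap_open
            t = Ix[i - 1, j] + gap_extend
            if t > ix:
                ix = t
            Ix[i, j] = ix
            iy = H[i, j - 1] + gap_open
            t = Iy[i, j - 1] + gap_extend
            if t > iy:
                iy = t
            Iy[i, j] = iy
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if ix > h:
                h = ix
            if iy > h:
                h = iy
            if local and h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, Ix, Iy


@njit(cache=True)
def _entropy2(c0, c1):  # pragma: no cover - numba
    n = c0 + c1
    if n == 0:
        return 0.0
    e = 0.0
    if c0 > 0:
        p = c0 / n
        e -= p * np.log2(p)
    if c1 > 0:
        p = c1 / n
        e -= p * np.log2(p)
    return e


@njit(cache=True)
def grow_tree(X, y, candidates, per_split, k, min_leaf, max_depth, seed):  # pragma: no cover - numba
    """Grow a binary classification tree by greedy information gain.

    Parameters
    ----------
    X : float64 (n, p) feature matrix; y : int8 (n,) labels in {0, 1}.
    candidates : int64 array of feature indices available to this tree
        (sorted ascending).
    per_split : if True, a fresh subset of ``k`` candidates is drawn at every
        node (classic random-forest behaviour); otherwise every node sees all
        of ``candidates``.
    min_leaf : minimum samples per child; max_depth : maximum depth, or -1
        for unlimited; seed : seed for the node-level feature sampling.

    Split thresholds are midpoints between consecutive distinct sorted values;
    samples with ``x <= threshold`` go left.  Ties in gain keep the lowest
    feature index, then the lowest threshold.  Nodes stop when pure, too
    small, at max depth, or when no split has positive gain.  Returns flat
    arrays ``(feature, threshold, left, right, probs)``; ``feature == -1``
    marks a leaf and ``probs`` holds the class fractions of the node.
    """
    n, p = X.shape
    np.random.seed(seed)
    max_nodes = 2 * n + 1
    feat = np.full(max_nodes, -1, np.int64)
    thr = np.zeros(max_nodes, np.float64)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    probs = np.zeros((max_nodes, 2), np.float64)
    idx = np.arange(n)
    tmp = np.empty(n, np.int64)
    nc = candidates.shape[0]
    pool = np.empty(nc, np.int64)
    stack = np.empty((max_nodes, 4), np.int64)
    stack[0, 0] = 0
    stack[0, 1] = n
    stack[0, 2] = 0
    stack[0, 3] = 0
    sp = 1
    node_count = 1
    while sp > 0:
        sp -= 1
        s = stack[sp, 0]
        e = stack[sp, 1]
        depth = stack[sp, 2]
        node = stack[sp, 3]
        m = e - s
        c1 = 0
        for ii in range(s, e):
            c1 += y[idx[ii]]
        c0 = m - c1
        probs[node, 0] = c0 / m
        probs[node, 1] = c1 / m
        if c0 == 0 or c1 == 0 or m < 2 * min_leaf:
            continue
        if max_depth >= 0 and depth >= max_depth:
            continue
        if per_split:
            kk = k if k < nc else nc
            for ii in range(nc):
                pool[ii] = candidates[ii]
            for ii in range(kk):
                j = np.random.randint(ii, nc)
                t = pool[ii]
                pool[ii] = pool[j]
                pool[j] = t
            sel = np.sort(pool[:kk])
        else:
            sel = candidates
            kk = nc
        h_parent = _entropy2(c0, c1)
        best_gain = 0.0
        best_f = -1
        best_thr = 0.0
        v = np.empty(m, np.float64)
        for fi in range(kk):
            f = sel[fi]
            for ii in range(m):
                v[ii] = X[idx[s + ii], f]
            order = np.argsort(v)
            l1 = 0
            for ii in range(m - 1):
                o = order[ii]
                l1 += y[idx[s + o]]
                a = v[o]
                b = v[order[ii + 1]]
                if b <= a:
                    continue
                nl = ii + 1
                nr = m - nl
                if nl < min_leaf or nr < min_leaf:
                    continue
                l0 = nl - l1
                r1 = c1 - l1
                r0 = nr - r1
                gain = h_parent - (nl * _entropy2(l0, l1) + nr * _entropy2(r0, r1)) / m
                if gain > best_gain + 1e-12:
                    mid = 0.5 * (a + b)
                    # guard against the midpoint rounding onto b, which would
                    # desynchronise the <=-threshold partition from the scan
                    if mid >= b:
                        mid = a
                    best_gain = gain
                    best_f = f
                    best_thr = mid
        if best_f == -1:
            continue
        nl = 0
        for ii in range(s, e):
            if X[idx[ii], best_f] <= best_thr:
                tmp[nl] = idx[ii]
                nl += 1
        nr = nl
        for ii in range(s, e):
            if X[idx[ii], best_f] > best_thr:
                tmp[nr] = idx[ii]
                nr += 1
        for ii in range(m):
            idx[s + ii] = tmp[ii]
        feat[node] = best_f
        thr[node] = best_thr
        lnode = node_count
        rnode = node_count + 1
        node_count += 2
        left[node] = lnode
        right[node] = rnode
        stack[sp, 0] = s
        stack[sp, 1] = s + nl
        stack[sp, 2] = depth + 1
        stack[sp, 3] = lnode
        sp += 1
        stack[sp, 0] = s + nl
        stack[sp, 1] = e
        stack[sp, 2] = depth + 1
        stack[sp, 3] = rnode
        sp += 1
    return (
        feat[:node_count].copy(),
        thr[:node_count].copy(),
        left[:node_count].copy(),
        right[:node_count].copy(),
        probs[:node_count].copy(),
    )
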