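"""A compact CART regression forest with out-of-bag scoring.

The permutation test for continuous phenotypes refits a forest for every
phenotype permutation — tens of thousands of fits per simulation scenario —
on very small sample sizes (tens of samples).  The forest here is compiled
with numba so a 100-tree fit on n = 10..50 samples costs microseconds to a
few milliseconds, while following the classic randomForest regression
conventions: bootstrap of n samples per tree, ``mtry = floor(p/3)``
candidate features per split, variance-reduction (SSE) splits, and terminal
nodes of at most ``min_node = 5`` cases.

Only regression lives here; categorical phenotypes use scikit-learn's
RandomForestClassifier (see :mod:`permgsa.rf`).
"""

from __future__ import annotations

import warnings

import numpy as np
from numba import njit

__all__ = ["RegressionForest"]


@njit(cache=True)
def _build_forest(X, y, n_trees, mtry, min_node, seed):
    np.random.seed(seed)
    n, p = X.shape
    max_nodes = 2 * n + 1
    feat = np.full((n_trees, max_nodes), -1, np.int64)
    thr = np.zeros((n_trees, max_nodes))
    left = np.zeros((n_trees, max_nodes), np.int64)
    right = np.zeros((n_trees, max_nodes), np.int64)
    value = np.zeros((n_trees, max_nodes))
    in_bag = np.zeros((n_trees, n), np.bool_)

    idx = np.empty(n, np.int64)
    fidx = np.empty(p, np.int64)
    stack_node = np.empty(max_nodes, np.int64)
    stack_start = np.empty(max_nodes, np.int64)
    stack_end = np.empty(max_nodes, np.int64)
    v = np.empty(n)
    yv = np.empty(n)

    for t in range(n_trees):
        for i in range(n):
            j = np.random.randint(0, n)
            idx[i] = j
            in_bag[t, j] = True
        n_nodes = 1
        stack_node[0] = 0
        stack_start[0] = 0
        stack_end[0] = n
        top = 1
        while top > 0:
            top -= 1
            node = stack_node[top]
            start = stack_start[top]
            end = stack_end[top]
            nn = end - start
            ysum = 0.0
            for i in range(start, end):
                ysum += y[idx[i]]
            value[t, node] = ysum / nn
            if nn <= min_node:
                continue
            parent_score = ysum * ysum / nn
            best_gain = 1e-12
            best_f = -1
            best_thr = 0.0
            for i in range(p):
                fidx[i] = i
            for q in range(mtry):
                r = q + np.random.randint(0, p - q)
                tmp = fidx[q]
                fidx[q] = fidx[r]
                fidx[r] = tmp
                f = fidx[q]
                # insertion sort of (value, response) pairs; nodes are tiny
                for i in range(nn):
                    vi = X[idx[start + i], f]
                    yi = y[idx[start + i]]
                    j = i - 1
                    while j >= 0 and v[j] > vi:
                        v[j + 1] = v[j]
                        yv[j + 1] = yv[j]
                        j -= 1
                    v[j + 1] = vi
                    yv[j + 1] = yi
                suml = 0.0
                for s in range(nn - 1):
                    suml += yv[s]
                    if v[s + 1] > v[s]:
                        nl = s + 1
                        nr = nn - nl
                        sumr = ysum - suml
                        gain = suml * suml / nl + sumr * sumr / nr - parent_score
                        if gain > best_gain:
                            best_gain = gain
                            best_f = f
                            best_thr = 0.5 * (v[s] + v[s + 1])
            if best_f < 0:
                continue
            i = start
            j2 = end - 1
            while i <= j2:
                if X[idx[i], best_f] <= best_thr:
                    i += 1
                else:
                    tmp = idx[i]
                    idx[i] = idx[j2]
                    idx[j2] = tmp
                    j2 -= 1
            mid = i
            lnode = n_nodes
            rnode = n_nodes + 1
            n_nodes += 2
            feat[t, node] = best_f
            thr[t, node] = best_thr
            left[t, node] = lnode
            right[t, node] = rnode
            stack_node[top] = lnode
            stack_start[top] = start
            stack_end[top] = mid
            top += 1
            stack_node[top] = rnode
            stack_start[top] = mid
            stack_end[top] = end
            top += 1
    return feat, thr, left, right, value, in_bag


@njit(cache=True, inline="always")
def _predict_one(X, feat, thr, left, right, value, t, i):
    node = 0
    while feat[t, node] >= 0:
        if X[i, feat[t, node]] <= thr[t, node]:
            node = left[t, node]
        else:
            node = right[t, node]
    return value[t, node]


@njit(cache=True)
def _oob_predictions(X, feat, thr, left, right, value, in_bag):
    n_trees, n = in_bag.shape
    s = np.zeros(n)
    cnt = np.zeros(n)
    for t in range(n_trees):
        for i in range(n):
            if not in_bag[t, i]:
                s[i] += _predict_one(X, feat, thr, left, right, value, t, i)
                cnt[i] += 1.0
    return s, cnt


@njit(cache=True)
def _predict_matrix(X, feat, thr, left, right, value):
    n_trees = feat.shape[0]
    n = X.shape[0]
    out = np.zeros(n)
    for t in range(n_trees):
        for i in range(n):
            out[i] += _predict_one(X, feat, thr, left, right, value, t, i)
    return out / n_trees


@njit(cache=True)
def _oob_perm_importance(X, y, feat, thr, left, right, value, in_bag, seed):
    """Breiman permutation importance: mean increase in OOB MSE per feature."""
    np.random.seed(seed)
    n_trees, n = in_bag.shape
    p = X.shape[1]
    imp = np.zeros(p)
    used = 0
    oob = np.empty(n, np.int64)
    for t in range(n_trees):
        n_oob = 0
        for i in range(n):
            if not in_bag[t, i]:
                oob[n_oob] = i
                n_oob += 1
        if n_oob < 2:
            continue
        used += 1
        base = 0.0
        for k in range(n_oob):
            e = _predict_one(X, feat, thr, left, right, value, t, oob[k]) - y[oob[k]]
            base += e * e
        base /= n_oob
        for f in range(p):
            errsum = 0.0
            # reshuffle the OOB order, then let each sample borrow feature f
            # from its cyclic successor: a random permutation with no fixed
            # points, so the feature is always genuinely displaced
            for k in range(n_oob - 1, 0, -1):
                r = np.random.randint(0, k + 1)
                tmp = oob[k]
                oob[k] = oob[r]
                oob[r] = tmp
            for k in range(n_oob):
                i = oob[k]
                donor = oob[(k + 1) % n_oob]
                node = 0
                while feat[t, node] >= 0:
                    ff = feat[t, node]
                    xv = X[donor, ff] if ff == f else X[i, ff]
                    if xv <= thr[t, node]:
                        node = left[t, node]
                    else:
                        node = right[t, node]
                e = value[t, node] - y[i]
                errsum += e * e
            imp[f] += errsum / n_oob - base
    if used > 0:
        imp /= used
    return imp


class RegressionForest:
    """Bootstrap-aggregated regression trees with OOB mean squared error.

    Parameters
    ----------
    n_trees
        Number of trees (default 500).
    mtry
        Candidate features per split; default ``max(1, floor(p / 3))``.
    min_node
        Nodes of at most this many bootstrap cases are not split (default 5).
    seed
        Integer seed; the same seed reproduces the forest exactly.
    """

    def __init__(self, n_trees: int = 500, mtry: int | None = None, min_node: int = 5, seed: int | None = None):
        if n_trees < 1:
            raise ValueError("n_trees must be at least 1")
        self.n_trees = int(n_trees)
        self.mtry = mtry
        self.min_node = int(min_node)
        self.seed = seed
        self._forest = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RegressionForest":
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.ascontiguousarray(y, dtype=np.float64)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be samples x features with one response per sample")
        p = X.shape[1]
        mtry = self.mtry if self.mtry is not None else max(1, p // 3)
        mtry = min(mtry, p)
        seed = np.random.default_rng(self.seed).integers(0, 2**32 - 1) if self.seed is None else int(self.seed) % (2**32)
        self._X, self._y = X, y
        self._forest = _build_forest(X, y, self.n_trees, mtry, self.min_node, seed)
        return self

    def _require_fit(self):
        if self._forest is None:
            raise RuntimeError("fit() the forest first")

    @property
    def oob_prediction_(self) -> np.ndarray:
        """Per-sample OOB prediction; NaN for samples never out of bag."""
        self._require_fit()
        s, cnt = _oob_predictions(self._X, *self._forest)
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)

    def oob_mse(self, warn_uncovered: bool = True) -> float:
        """OOB mean squared error over samples seen out of bag at least once."""
        pred = self.oob_prediction_
        covered = ~np.isnan(pred)
        if warn_uncovered and not covered.all():
            warnings.warn(
                f"{int((~covered).sum())} sample(s) never out of bag; excluded from the OOB score",
                stacklevel=2,
            )
        if not covered.any():
            raise ValueError("no sample was ever out of bag; increase n_trees")
        return float(np.mean((pred[covered] - self._y[covered]) ** 2))

    def predict(self, X: np.ndarray) -> np.ndarray:
        self._require_fit()
        X = np.ascontiguousarray(X, dtype=np.float64)
        return _predict_matrix(X, *self._forest[:5])

    def permutation_importance(self, seed: int | None = None) -> np.ndarray:
        """Mean increase in OOB MSE when each feature is permuted out of bag."""
        self._require_fit()
        s = int(seed) % (2**32) if seed is not None else (int(self.seed) % (2**32) if self.seed is not None else 0)
        return _oob_perm_importance(self._X, self._y, *self._forest, s)
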