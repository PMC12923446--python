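"""Weight-aware regression trees and the shared-sample tree forest.

Trees are grown CART-style: at each node a random subset of features is
drawn, candidate thresholds are midpoints between consecutive distinct
sorted values, and the split maximizing the weighted variance reduction is
taken.  Unlike a standard random forest, all trees of one inner forest are
trained on the identical (bootstrap) example multiset and differ only
through per-node feature sampling.

Two variable-importance measures are provided: the classical
variance-reduction aggregate and a permutation ("random input") measure
based on the increase of weighted mean squared error when one input column
is shuffled.

The builder is numba-jitted when numba is available; all randomness is
drawn from the caller's ``numpy.random.Generator`` (a pre-drawn key table
selects per-node feature subsets), so jitted and interpreted runs produce
identical trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


__all__ = [
    "ForestParams",
    "RegressionTree",
    "fit_tree",
    "fit_genie3_forest",
    "variance_importance",
    "random_input_importance",
]

_LEAF = -1
_GAIN_TOL = 1e-12


@dataclass
class ForestParams:
    """Parameters of the tree-ensemble inference procedure.

    ``n_test=None`` defers to ``ceil(n_candidate_features / 3)`` at fit
    time (the recommended fraction-of-inputs rule).
    """

    n_tree: int = 1000
    n_subtree: int = 50
    n_test: int | None = None
    n_hmax: int = 32
    n_rnd: int = 100

    def __post_init__(self) -> None:
        if self.n_tree < 1:
            raise ValueError("n_tree must be >= 1")
        if self.n_subtree < 1:
            raise ValueError("n_subtree must be >= 1")
        if self.n_rnd < 1:
            raise ValueError("n_rnd must be >= 1")
        if self.n_hmax < 1:
            raise ValueError("n_hmax must be >= 1")
        if self.n_test is not None and self.n_test < 1:
            raise ValueError("n_test must be >= 1 when given")

    @classmethod
    def paper(cls) -> "ForestParams":
        """Published full-size profile."""
        return cls(n_tree=1000, n_subtree=50, n_test=None, n_hmax=32, n_rnd=100)

    @classmethod
    def reduced(cls) -> "ForestParams":
        """Reduced profile used as the test/CI default."""
        return cls(n_tree=100, n_subtree=20, n_test=None, n_hmax=32, n_rnd=10)

    def resolve_n_test(self, n_features: int) -> int:
        if self.n_test is not None:
            return min(self.n_test, n_features)
        return max(1, min(n_features, math.ceil(n_features / 3)))


@njit(cache=True)
def _build_core(X, y, w, keys, n_test, n_hmax, gain_tol):  # pragma: no cover
    n_samples, n_features = X.shape
    max_nodes = 2 * n_samples + 1
    feature = np.full(max_nodes, -1, np.int64)
    threshold = np.full(max_nodes, np.nan)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    value = np.zeros(max_nodes)
    gain = np.zeros(max_nodes)
    weight = np.zeros(max_nodes)

    idx = np.arange(n_samples)
    buf = np.empty(n_samples, np.int64)
    st_node = np.empty(max_nodes, np.int64)
    st_lo = np.empty(max_nodes, np.int64)
    st_hi = np.empty(max_nodes, np.int64)
    st_depth = np.empty(max_nodes, np.int64)
    sp = 0
    st_node[0] = 0
    st_lo[0] = 0
    st_hi[0] = n_samples
    st_depth[0] = 0
    n_nodes = 1

    chosen = np.empty(n_test, np.int64)
    while sp >= 0:
        node = st_node[sp]
        lo = st_lo[sp]
        hi = st_hi[sp]
        depth = st_depth[sp]
        sp -= 1
        m = hi - lo
        sw = 0.0
        swy = 0.0
        swy2 = 0.0
        for i in range(lo, hi):
            j = idx[i]
            sw += w[j]
            swy += w[j] * y[j]
            swy2 += w[j] * y[j] * y[j]
        if sw > 0.0:
            mean = swy / sw
        else:
            mean = 0.0
            for i in range(lo, hi):
                mean += y[idx[i]]
            mean /= m
        value[node] = mean
        weight[node] = sw
        if depth >= n_hmax or m < 2 or sw <= 0.0:
            continue
        total_sse = swy2 - swy * swy / sw
        ref = swy2 if swy2 > 1.0 else 1.0
        if total_sse <= gain_tol * ref:
            continue  # pure outputs

        # feature subset: the n_test smallest keys of this node's row
        kr = keys[node].copy()
        for t in range(n_test):
            bi = 0
            bv = kr[0]
            for f in range(1, n_features):
                if kr[f] < bv:
                    bv = kr[f]
                    bi = f
            chosen[t] = bi
            kr[bi] = np.inf
        chosen[:n_test].sort()  # ascending index -> deterministic tie-break

        best_gain = -1.0
        best_f = -1
        best_thr = 0.0
        xv = np.empty(m)
        for t in range(n_test):
            f = chosen[t]
            for i in range(m):
                xv[i] = X[idx[lo + i], f]
            order = np.argsort(xv)
            cw = 0.0
            cs = 0.0
            cq = 0.0
            f_gain = -1.0
            f_thr = 0.0
            for i in range(m - 1):
                j = idx[lo + order[i]]
                cw += w[j]
                cs += w[j] * y[j]
                cq += w[j] * y[j] * y[j]
                lo_x = xv[order[i]]
                hi_x = xv[order[i + 1]]
                if lo_x < hi_x:
                    wl = cw
                    wr = sw - cw
                    sse_l = cq - (cs * cs / wl if wl > 0.0 else 0.0)
                    sr = swy - cs
                    qr = swy2 - cq
                    sse_r = qr - (sr * sr / wr if wr > 0.0 else 0.0)
                    g = total_sse - sse_l - sse_r
                    if g > f_gain:  # first (= smallest threshold) wins ties
                        f_gain = g
                        f_thr = 0.5 * (lo_x + hi_x)
            if f_gain > best_gain:  # lowest feature index wins ties
                best_gain = f_gain
                best_f = f
                best_thr = f_thr

        ref_g = total_sse if total_sse > 1.0 else 1.0
        if best_f < 0 or best_gain <= gain_tol * ref_g:
            continue
        nl = 0
        pos = lo
        for i in range(lo, hi):
            if X[idx[i], best_f] <= best_thr:
                buf[pos] = idx[i]
                pos += 1
                nl += 1
        for i in range(lo, hi):
            if X[idx[i], best_f] > best_thr:
                buf[pos] = idx[i]
                pos += 1
        for i in range(lo, hi):
            idx[i] = buf[i]

        feature[node] = best_f
        threshold[node] = best_thr
        gain[node] = best_gain / sw
        lnode = n_nodes
        rnode = n_nodes + 1
        n_nodes += 2
        left[node] = lnode
        right[node] = rnode
        sp += 1
        st_node[sp] = lnode
        st_lo[sp] = lo
        st_hi[sp] = lo + nl
        st_depth[sp] = depth + 1
        sp += 1
        st_node[sp] = rnode
        st_lo[sp] = lo + nl
        st_hi[sp] = hi
        st_depth[sp] = depth + 1

    return (feature[:n_nodes], threshold[:n_nodes], left[:n_nodes],
            right[:n_nodes], value[:n_nodes], gain[:n_nodes],
            weight[:n_nodes])


@njit(cache=True)
def _predict_core(feature, threshold, left, right, value, X):  # pragma: no cover
    out = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        node = 0
        while feature[node] != -1:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = value[node]
    return out


class RegressionTree:
    """Binary regression tree in flat-array form.

    ``feature[i] == -1`` marks a leaf; ``value[i]`` is the weighted mean of
    the training outputs routed to node *i*, ``gain[i]`` the weighted
    variance reduction of the split at *i* and ``weight[i]`` the total
    example weight reaching *i*.
    """

    __slots__ = ("feature", "threshold", "left", "right", "value", "gain",
                 "weight", "n_features")

    def __init__(self, feature, threshold, left, right, value, gain, weight,
                 n_features: int):
        self.feature = np.ascontiguousarray(feature, dtype=np.int64)
        self.threshold = np.ascontiguousarray(threshold, dtype=float)
        self.left = np.ascontiguousarray(left, dtype=np.int64)
        self.right = np.ascontiguousarray(right, dtype=np.int64)
        self.value = np.ascontiguousarray(value, dtype=float)
        self.gain = np.ascontiguousarray(gain, dtype=float)
        self.weight = np.ascontiguousarray(weight, dtype=float)
        self.n_features = n_features

    @property
    def n_nodes(self) -> int:
        return self.feature.size

    def used_features(self) -> np.ndarray:
        """Distinct feature indices split on anywhere in the tree."""
        return np.unique(self.feature[self.feature != _LEAF])

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError("prediction input has wrong width")
        if _HAVE_NUMBA:
            return _predict_core(self.feature, self.threshold, self.left,
                                 self.right, self.value, X)
        return self._predict_vectorized(X)

    def _predict_vectorized(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(X.shape[0], dtype=np.int64)
        rows = np.arange(X.shape[0])
        while True:
            feat = self.feature[node]
            active = feat != _LEAF
            if not active.any():
                break
            r = rows[active]
            f = feat[active]
            goes_left = X[r, f] <= self.threshold[node[active]]
            node[r] = np.where(goes_left, self.left[node[active]],
                               self.right[node[active]])
        return self.value[node]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "value": self.value.tolist(),
            "gain": self.gain.tolist(),
            "weight": self.weight.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        return cls(d["feature"], d["threshold"], d["left"], d["right"],
                   d["value"], d["gain"], d["weight"], d["n_features"])


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    n_test: int,
    n_hmax: int = 32,
    rng: np.random.Generator | None = None,
) -> RegressionTree:
    """Grow one weighted regression tree.

    At each internal node ``n_test`` features are sampled without
    replacement; ties between equally good splits are broken toward the
    lowest feature index and then the smallest threshold.  Recursion stops
    at height ``n_hmax``, on pure outputs, or when no sampled feature
    admits a split.
    """
    rng = rng or np.random.default_rng()
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    w = np.ascontiguousarray(w, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-d array")
    if y.shape != (X.shape[0],) or w.shape != (X.shape[0],):
        raise ValueError("y and w must match the number of examples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))
            and np.all(np.isfinite(w))):
        raise ValueError("inputs must be finite")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    n_features = X.shape[1]
    n_test = max(1, min(n_test, n_features))

    # one uniform key row per potential node selects its feature subset
    keys = rng.random((2 * X.shape[0] + 1, n_features))
    arrays = _build_core(X, y, w, keys, n_test, n_hmax, _GAIN_TOL)
    return RegressionTree(*arrays, n_features=n_features)


def fit_genie3_forest(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    params: ForestParams,
    rng: np.random.Generator,
) -> list[RegressionTree]:
    """Train ``n_subtree`` trees on the identical weighted example multiset.

    ``X`` must already exclude the target gene's own column; trees differ
    only through per-node random feature selection.
    """
    if len(X) == 0:
        raise ValueError("cannot fit a forest on an empty sample")
    n_test = params.resolve_n_test(X.shape[1])
    return [
        fit_tree(X, y, w, n_test=n_test, n_hmax=params.n_hmax, rng=rng)
        for _ in range(params.n_subtree)
    ]


def variance_importance(trees: list[RegressionTree], n_features: int) -> np.ndarray:
    """Classical importance: split variance reduction times node weight,
    summed per feature and averaged over trees."""
    scores = np.zeros(n_features)
    for tree in trees:
        internal = tree.feature != _LEAF
        np.add.at(scores, tree.feature[internal],
                  tree.gain[internal] * tree.weight[internal])
    return scores / max(1, len(trees))


def _weighted_mse(pred: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    sw = w.sum()
    if sw <= 0:
        return 0.0
    return float((w * (pred - y) ** 2).sum() / sw)


def random_input_importance(
    trees: list[RegressionTree],
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation importance on a shared evaluation set.

    For each tree and each feature the tree actually splits on, the
    feature column is shuffled (fresh permutation per tree and feature)
    and the increase in weighted mean squared error over the unpermuted
    baseline is recorded; scores are averaged over trees.  Features unused
    by every tree score exactly 0.
    """
    if len(X) == 0:
        raise ValueError("evaluation data must be non-empty")
    X = np.ascontiguousarray(X, dtype=float)
    scores = np.zeros(X.shape[1])
    for tree in trees:
        base = _weighted_mse(tree.predict(X), y, w)
        for f in tree.used_features():
            perm = rng.permutation(X.shape[0])
            col = X[:, f].copy()
            X[:, f] = col[perm]
            scores[f] += _weighted_mse(tree.predict(X), y, w) - base
            X[:, f] = col
    return scores / max(1, len(trees))
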