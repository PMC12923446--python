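"""Tree-selection ensemble driven by sign-of-derivative labels.

For each target gene the procedure repeats: bootstrap the '0'-labeled
examples, train a small shared-sample forest on them, bootstrap the '+'
and '-' examples, equalize their weight masses by under-sampling, score
every candidate tree with a hinge penalty that counts sign
misclassifications, and keep the best tree.  The selected trees form a
random-forest-like ensemble whose permutation importances, averaged over
repeated randomizations, rank candidate regulators.

When no '+' or '-' examples exist the selection step is skipped and the
procedure reduces to a weighted bagged forest (modified GENIE3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import RankedNetwork
from .forest import (
    ForestParams,
    RegressionTree,
    fit_genie3_forest,
    random_input_importance,
)
from .labeling import (
    ExpressionDataset,
    LabeledSubproblem,
    LabelThresholds,
    build_subproblems,
)

__all__ = [
    "SubproblemResult",
    "bootstrap",
    "undersample_counts",
    "tree_penalty",
    "select_best_tree",
    "infer_subproblem",
    "compute_confidences",
    "infer_network",
]


@dataclass
class SubproblemResult:
    """Selected ensemble and bookkeeping for one target gene."""

    target: int
    target_name: str
    regulator_names: list[str]
    trees: list[RegressionTree]
    sample_indices: list[np.ndarray]    # per-tree bootstrap rows into D0
    penalties: np.ndarray               # selected tree's T value per iteration
    # evaluation data (D0, target column dropped) for importance scoring
    X0: np.ndarray = field(repr=False, default=None)
    y0: np.ndarray = field(repr=False, default=None)
    w0: np.ndarray = field(repr=False, default=None)
    confidences: np.ndarray | None = None


def bootstrap(n: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of a uniform with-replacement resample of size *n*."""
    if n <= 0:
        raise ValueError("cannot bootstrap an empty example set")
    return rng.integers(0, n, size=n)


def _prefix_count(weights: np.ndarray, target_mass: float) -> int:
    """Smallest K with ``sum(weights[:K]) >= target_mass`` (0 if mass <= 0)."""
    if target_mass <= 0:
        return 0
    csum = np.cumsum(weights)
    k = int(np.searchsorted(csum, target_mass, side="left")) + 1
    return min(k, weights.size)


def undersample_counts(
    w_plus: np.ndarray, w_minus: np.ndarray
) -> tuple[int, int]:
    """Under-sampling cutoffs equalizing '+' and '-' weight masses.

    Given the resampled weights in draw order, the side with the larger
    total mass is truncated to the shortest prefix whose mass reaches the
    other side's total; the smaller side is kept whole.
    """
    w_plus = np.asarray(w_plus, dtype=float)
    w_minus = np.asarray(w_minus, dtype=float)
    mass_plus = float(w_plus.sum()) if w_plus.size else 0.0
    mass_minus = float(w_minus.sum()) if w_minus.size else 0.0
    if mass_plus >= mass_minus:
        k_plus = _prefix_count(w_plus, mass_minus)
        k_minus = int(w_minus.size)
    else:
        k_minus = _prefix_count(w_minus, mass_plus)
        k_plus = int(w_plus.size)
    return k_plus, k_minus


def tree_penalty(
    tree: RegressionTree,
    X_plus: np.ndarray,
    t_plus: np.ndarray,
    w_plus: np.ndarray,
    X_minus: np.ndarray,
    t_minus: np.ndarray,
    w_minus: np.ndarray,
) -> float:
    """Weighted hinge penalty for sign misclassification.

    A '+' example contributes ``w * max(-(G(x) - x_n), 0)`` and a '-'
    example ``w * max(G(x) - x_n, 0)``; the penalty is 0 iff the tree's
    predicted sign of ``G(x) - x_n`` agrees with every example's label.
    ``X_plus``/``X_minus`` must already exclude the target column;
    ``t_plus``/``t_minus`` are the target gene's own expression levels.
    """
    total = 0.0
    if len(X_plus):
        gap = tree.predict(X_plus) - t_plus
        total += float((w_plus * np.maximum(-gap, 0.0)).sum())
    if len(X_minus):
        gap = tree.predict(X_minus) - t_minus
        total += float((w_minus * np.maximum(gap, 0.0)).sum())
    return total


def select_best_tree(penalties: np.ndarray) -> int:
    """Index of the smallest penalty; ties go to the lowest index."""
    penalties = np.asarray(penalties, dtype=float)
    if penalties.size == 0:
        raise ValueError("no candidate trees")
    return int(np.argmin(penalties))


def _candidate_columns(sub: LabeledSubproblem) -> tuple[list[int], list[str]]:
    cols = [i for i in range(len(sub.feature_names)) if i != sub.target]
    names = [sub.feature_names[i] for i in cols]
    return cols, names


def infer_subproblem(
    sub: LabeledSubproblem,
    params: ForestParams,
    rng: np.random.Generator,
    use_sign_labels: bool = True,
) -> SubproblemResult:
    """Build the selected tree ensemble for one target gene (Steps 1-6).

    Each of the ``n_tree`` iterations re-runs the full cycle: fresh
    bootstrap of the '0' set, fresh shared-sample forest, fresh '+'/'-'
    bootstraps and under-sampling, penalty scoring, selection.  With
    ``use_sign_labels=False`` (or when both the '+' and '-' sets are
    empty) selection is skipped and the first tree of each inner forest is
    kept, which reduces the procedure to a weighted bagged forest.
    """
    cols, names = _candidate_columns(sub)
    zero = sub.mask("0")
    if not zero.any():
        raise ValueError(
            "the inference method cannot function without gene expression "
            "data labeled '0'"
        )
    X0 = sub.inputs[np.ix_(zero, cols)]
    y0 = sub.inputs[zero, sub.target]
    w0 = sub.weights[zero]

    plus = sub.mask("+")
    minus = sub.mask("-")
    have_signs = use_sign_labels and (plus.any() or minus.any())
    if have_signs:
        Xp = sub.inputs[np.ix_(plus, cols)]
        tp = sub.inputs[plus, sub.target]
        wp_all = sub.weights[plus]
        Xm = sub.inputs[np.ix_(minus, cols)]
        tm = sub.inputs[minus, sub.target]
        wm_all = sub.weights[minus]

    trees: list[RegressionTree] = []
    samples: list[np.ndarray] = []
    penalties = np.full(params.n_tree, np.nan)
    n0 = X0.shape[0]
    for it in range(params.n_tree):
        i0 = bootstrap(n0, rng)
        forest = fit_genie3_forest(X0[i0], y0[i0], w0[i0], params, rng)
        if have_signs:
            ip = bootstrap(len(wp_all), rng) if len(wp_all) else np.array([], dtype=int)
            im = bootstrap(len(wm_all), rng) if len(wm_all) else np.array([], dtype=int)
            wp = wp_all[ip]
            wm = wm_all[im]
            k_plus, k_minus = undersample_counts(wp, wm)
            ip_k = ip[:k_plus]
            im_k = im[:k_minus]
            t_vals = np.array([
                tree_penalty(t, Xp[ip_k], tp[ip_k], wp[:k_plus],
                             Xm[im_k], tm[im_k], wm[:k_minus])
                for t in forest
            ])
            j = select_best_tree(t_vals)
            penalties[it] = t_vals[j]
        else:
            j = 0
        trees.append(forest[j])
        samples.append(i0)
    return SubproblemResult(
        target=sub.target,
        target_name=sub.target_name,
        regulator_names=names,
        trees=trees,
        sample_indices=samples,
        penalties=penalties,
        X0=X0,
        y0=y0,
        w0=w0,
    )


def compute_confidences(
    result: SubproblemResult,
    params: ForestParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Average random-input importances over ``n_rnd`` randomizations.

    Each tree is evaluated on its own bootstrap sample of the '0' set.
    The returned vector is aligned with ``result.regulator_names``; it is
    also stored on the result.
    """
    n_features = result.X0.shape[1]
    total = np.zeros(n_features)
    # per-tree evaluation data and baseline error are fixed across repeats
    evals = []
    for tree, idx in zip(result.trees, result.sample_indices):
        Xe = result.X0[idx]
        ye = result.y0[idx]
        we = result.w0[idx]
        evals.append((tree, Xe, ye, we))
    for _ in range(params.n_rnd):
        for tree, Xe, ye, we in evals:
            total += random_input_importance([tree], Xe, ye, we, rng)
    conf = total / (params.n_rnd * max(1, len(result.trees)))
    result.confidences = conf
    return conf


def infer_network(
    data: ExpressionDataset,
    weights: np.ndarray | None = None,
    params: ForestParams | None = None,
    seed: int | np.random.Generator | None = None,
    span: float = 0.3,
    thresholds: LabelThresholds | None = None,
    steady_from_pseudotime: bool = False,
    use_sign_labels: bool = True,
    progress: bool = False,
) -> RankedNetwork:
    """Infer a ranked directed network over all genes.

    The problem is decomposed into one subproblem per target gene; the
    subproblems are independent and each consumes its own random stream
    derived from ``seed``, so results do not depend on execution order.
    The stimulus column, when present, may act only as a regulator.
    """
    params = params or ForestParams.reduced()
    if isinstance(seed, np.random.Generator):
        base = int(seed.integers(0, 2**63))
    else:
        base = int(np.random.default_rng(seed).integers(0, 2**63))
    subproblems = build_subproblems(
        data,
        weights=weights,
        span=span,
        thresholds=thresholds,
        steady_from_pseudotime=steady_from_pseudotime,
    )
    edges: list[tuple[str, str, float]] = []
    for sub in subproblems:
        sub_rng = np.random.default_rng([base, sub.target])
        result = infer_subproblem(sub, params, sub_rng,
                                  use_sign_labels=use_sign_labels)
        conf = compute_confidences(result, params, sub_rng)
        if progress:  # pragma: no cover - cosmetic
            print(f"  subproblem {sub.target_name}: done")
        for name, c in zip(result.regulator_names, conf):
            edges.append((name, sub.target_name, float(c)))
    return RankedNetwork.from_edges(edges)
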