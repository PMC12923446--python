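"""Sign-of-derivative labeling of pseudo time-series and steady-state cells.

Expression snapshots ordered by pseudotime are smoothed gene-by-gene with
tricube local linear regression; each cell then receives a class label
('+', '-', '0' or 'X') for every target gene, encoding the estimated sign
of that gene's expression time derivative at the cell.  Steady-state cells
are always labeled '0'.  The labeled cells are packaged into one weighted
subproblem per target gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionDataset",
    "SmoothedTrajectory",
    "LabeledSubproblem",
    "LabelThresholds",
    "STIMULUS_NAME",
    "smooth_series",
    "smooth_dataset",
    "assign_label",
    "build_subproblems",
]

#: Feature name used for the optional stimulus indicator column.
STIMULUS_NAME = "stimulus"

LABELS = ("+", "-", "0", "X")


@dataclass
class ExpressionDataset:
    """Cells x genes expression matrix with per-cell trajectory annotations.

    Parameters
    ----------
    values:
        Nonnegative expression levels, one row per cell, one column per gene.
        Column order is the canonical gene order used by all downstream
        indices.
    gene_names:
        Gene identifiers, one per column.
    cell_ids:
        Cell identifiers, one per row.
    pseudotime:
        Per-cell pseudotime in [0, 1]; ``NaN`` marks a steady-state cell.
    stimulus:
        Optional per-cell stimulus indicator (conventionally 1.0 for
        pseudo time-series cells and 0.0 for steady-state cells).  When
        present it is appended as an extra input feature that may act as a
        regulator but never as a target.
    """

    values: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    pseudotime: np.ndarray
    stimulus: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n_cells, n_genes = self.values.shape
        if n_genes < 2:
            raise ValueError("at least 2 genes are required")
        if len(self.gene_names) != n_genes:
            raise ValueError("gene_names length does not match matrix width")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match matrix height")
        if len(set(self.gene_names)) != n_genes:
            raise ValueError("gene names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative")
        if self.pseudotime.shape != (n_cells,):
            raise ValueError("pseudotime must have one entry per cell")
        pt = self.pseudotime[~np.isnan(self.pseudotime)]
        if pt.size and (pt.min() < 0.0 or pt.max() > 1.0):
            warnings.warn(
                "pseudotime outside [0, 1]; rescaling to the unit interval",
                stacklevel=2,
            )
            lo, hi = pt.min(), pt.max()
            span = hi - lo if hi > lo else 1.0
            mask = ~np.isnan(self.pseudotime)
            self.pseudotime = self.pseudotime.copy()
            self.pseudotime[mask] = (self.pseudotime[mask] - lo) / span
        if self.stimulus is not None:
            self.stimulus = np.asarray(self.stimulus, dtype=float)
            if self.stimulus.shape != (n_cells,):
                raise ValueError("stimulus must have one entry per cell")
            if not np.all(np.isfinite(self.stimulus)):
                raise ValueError("stimulus values must be finite")

    # -- convenience views -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def is_steady(self) -> np.ndarray:
        """Boolean mask of steady-state cells."""
        return np.isnan(self.pseudotime)

    @property
    def is_pseudo(self) -> np.ndarray:
        """Boolean mask of pseudo time-series cells."""
        return ~self.is_steady

    def with_stimulus(self) -> "ExpressionDataset":
        """Return a copy carrying the canonical stimulus indicator column."""
        stim = np.where(self.is_pseudo, 1.0, 0.0)
        return ExpressionDataset(
            self.values.copy(),
            list(self.gene_names),
            list(self.cell_ids),
            self.pseudotime.copy(),
            stimulus=stim,
        )


@dataclass
class SmoothedTrajectory:
    """Smoothed levels and slopes of every gene at every pseudo-series cell.

    ``sm`` and ``sl`` are aligned with the pseudo time-series cells of the
    originating dataset (rows) and its genes (columns).  ``mean``, ``q05``
    and ``q95`` are per-gene statistics over the pseudo time-series cells
    only.
    """

    pt: np.ndarray          # pseudotime of each pseudo-series cell
    sm: np.ndarray          # smoothed level, (n_pseudo_cells, n_genes)
    sl: np.ndarray          # local slope, same shape
    mean: np.ndarray        # per-gene average over pseudo-series cells
    q05: np.ndarray
    q95: np.ndarray


@dataclass
class LabelThresholds:
    """Constants of the labeling rule; defaults are the published values."""

    quantile: float = 0.05      # top/bottom exclusion fraction
    low_band: float = 0.9       # x <= low_band * Sm required for '+'
    high_band: float = 1.1      # x >= high_band * Sm required for '-'
    slope_factor: float = 1.2   # |Sl| must exceed slope_factor * mean
    flat_factor: float = 0.6    # |Sl| below flat_factor * mean for '0'
    steady_pt: float = 0.85     # pt > steady_pt may be treated as steady


@dataclass
class LabeledSubproblem:
    """All labeled examples for one target gene.

    ``inputs`` keeps every gene column (plus the stimulus column, last, if
    present); the target's own column is dropped only when trees are
    trained.
    """

    target: int
    target_name: str
    feature_names: list[str]
    inputs: np.ndarray          # (n_examples, n_features)
    labels: np.ndarray          # array of '+', '-', '0', 'X'
    weights: np.ndarray
    cell_ids: list[str] = field(default_factory=list)

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def count(self, label: str) -> int:
        return int(np.count_nonzero(self.labels == label))

    @property
    def partition_sizes(self) -> dict[str, int]:
        return {lab: self.count(lab) for lab in LABELS}

    @property
    def target_values(self) -> np.ndarray:
        return self.inputs[:, self.target]


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def smooth_series(
    pt: np.ndarray,
    x: np.ndarray,
    span: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Tricube local linear regression of one gene along pseudotime.

    For each cell's pseudotime the nearest ``ceil(span * K)`` neighbours
    (by pseudotime distance) receive tricube weights and a weighted
    degree-1 polynomial is fitted; the fitted value and its slope
    coefficient are returned at every input pseudotime.

    Returns
    -------
    (sm, sl):
        Smoothed level and local slope, one entry per input cell.
    """
    pt = np.asarray(pt, dtype=float)
    x = np.asarray(x, dtype=float)
    if pt.ndim != 1 or pt.shape != x.shape:
        raise ValueError("pt and x must be 1-d arrays of equal length")
    if pt.size < 10:
        raise ValueError("smoothing requires at least 10 cells")
    if not (np.all(np.isfinite(pt)) and np.all(np.isfinite(x))):
        raise ValueError("pt and x must be finite")
    if np.unique(pt).size < 2:
        raise ValueError("degenerate input: fewer than 2 distinct pseudotimes")
    if not (0.0 < span <= 1.0):
        raise ValueError("span must lie in (0, 1]")

    k = max(2, int(np.ceil(span * pt.size)))
    k = min(k, pt.size)
    sm = np.empty_like(x)
    sl = np.empty_like(x)

    # chunked to keep the distance matrix small on large datasets
    chunk = 512
    for start in range(0, pt.size, chunk):
        sel = slice(start, min(start + chunk, pt.size))
        d = np.abs(pt[sel, None] - pt[None, :])          # (c, K)
        h = np.partition(d, k - 1, axis=1)[:, k - 1]     # k-th nearest distance
        h = np.where(h > 0, h, np.max(d, axis=1))
        h = np.where(h > 0, h, 1.0)                      # all-equal guard
        u = np.clip(d / h[:, None], 0.0, 1.0)
        w = (1.0 - u**3) ** 3
        xc = pt[None, :] - pt[sel, None]
        # degenerate local neighbourhoods fall back to uniform weights
        var_ok = (w * xc**2).sum(axis=1) > 0
        w[~var_ok] = 1.0

        sw = w.sum(axis=1)
        swx = (w * xc).sum(axis=1)
        swx2 = (w * xc * xc).sum(axis=1)
        swy = (w * x[None, :]).sum(axis=1)
        swxy = (w * xc * x[None, :]).sum(axis=1)
        denom = sw * swx2 - swx**2
        safe = np.abs(denom) > 1e-300
        slope = np.where(safe, (sw * swxy - swx * swy) / np.where(safe, denom, 1.0), 0.0)
        sm[sel] = (swy - slope * swx) / sw
        sl[sel] = slope
    return sm, sl


def smooth_dataset(data: ExpressionDataset, span: float = 0.3) -> SmoothedTrajectory:
    """Smooth every gene over the pseudo time-series cells of *data*."""
    mask = data.is_pseudo
    if not mask.any():
        raise ValueError("dataset contains no pseudo time-series cells")
    pt = data.pseudotime[mask]
    X = data.values[mask]
    sm = np.empty_like(X)
    sl = np.empty_like(X)
    for g in range(data.n_genes):
        sm[:, g], sl[:, g] = smooth_series(pt, X[:, g], span=span)
    return SmoothedTrajectory(
        pt=pt,
        sm=sm,
        sl=sl,
        mean=X.mean(axis=0),
        q05=np.quantile(X, 0.05, axis=0),
        q95=np.quantile(X, 0.95, axis=0),
    )


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------

def assign_label(
    x_val: float,
    sm: float,
    sl: float,
    x_avg: float,
    q05: float,
    q95: float,
    thresholds: LabelThresholds | None = None,
) -> str:
    """Class label of one pseudo-series cell for one target gene.

    The rules are applied in order: extreme expression first ('X'), then
    '+', '-', '0', and 'X' as the fallback.
    """
    th = thresholds or LabelThresholds()
    for v in (x_val, sm, sl, x_avg, q05, q95):
        if not np.isfinite(v):
            raise ValueError("all labeling inputs must be finite")
    if q05 > q95:
        raise ValueError("q05 must not exceed q95")
    if x_val <= q05 or x_val >= q95:
        return "X"
    if x_val <= th.low_band * sm and sl > th.slope_factor * x_avg:
        return "+"
    if x_val >= th.high_band * sm and sl < -th.slope_factor * x_avg:
        return "-"
    if th.low_band * sm <= x_val <= th.high_band * sm and abs(sl) < th.flat_factor * x_avg:
        return "0"
    return "X"


def _assign_labels_vector(
    x: np.ndarray,
    sm: np.ndarray,
    sl: np.ndarray,
    x_avg: float,
    q05: float,
    q95: float,
    th: LabelThresholds,
) -> np.ndarray:
    """Vectorized ``assign_label`` over the cells of one gene."""
    out = np.full(x.shape, "X", dtype="U1")
    extreme = (x <= q05) | (x >= q95)
    plus = (x <= th.low_band * sm) & (sl > th.slope_factor * x_avg)
    minus = (x >= th.high_band * sm) & (sl < -th.slope_factor * x_avg)
    zero = (
        (th.low_band * sm <= x)
        & (x <= th.high_band * sm)
        & (np.abs(sl) < th.flat_factor * x_avg)
    )
    out[zero] = "0"
    out[minus] = "-"
    out[plus] = "+"
    out[extreme] = "X"
    return out


def build_subproblems(
    data: ExpressionDataset,
    smoothed: SmoothedTrajectory | None = None,
    weights: np.ndarray | None = None,
    span: float = 0.3,
    thresholds: LabelThresholds | None = None,
    steady_from_pseudotime: bool = False,
) -> list[LabeledSubproblem]:
    """Build one labeled, weighted subproblem per target gene.

    Pseudo time-series cells are labeled by the sign rules; steady-state
    cells always carry '0'.  When the dataset has no steady-state cells and
    ``steady_from_pseudotime`` is set, cells with pseudotime above the
    steady threshold are copied into the steady-state cohort.

    Raises
    ------
    ValueError
        If no '0'-labeled steady-state cells are available; the inference
        method cannot function without them.
    """
    th = thresholds or LabelThresholds()
    if smoothed is None and data.is_pseudo.any():
        smoothed = smooth_dataset(data, span=span)
    if weights is None:
        weights = np.ones(data.n_cells)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (data.n_cells,):
        raise ValueError("weights must have one entry per cell")
    if np.any(weights < 0) or not np.all(np.isfinite(weights)):
        raise ValueError("weights must be finite and nonnegative")

    pseudo_idx = np.flatnonzero(data.is_pseudo)
    steady_idx = np.flatnonzero(data.is_steady)
    extra_steady = np.array([], dtype=int)
    if steady_idx.size == 0 and steady_from_pseudotime:
        extra_steady = pseudo_idx[data.pseudotime[pseudo_idx] > th.steady_pt]

    feature_names = list(data.gene_names)
    blocks = [data.values]
    if data.stimulus is not None:
        feature_names.append(STIMULUS_NAME)
        blocks.append(data.stimulus[:, None])
    full = np.hstack(blocks)

    row_order = np.concatenate([pseudo_idx, steady_idx, extra_steady])
    inputs = full[row_order]
    w = weights[row_order]
    cell_ids = [data.cell_ids[i] for i in row_order]

    subproblems: list[LabeledSubproblem] = []
    n_pt = pseudo_idx.size
    for n, name in enumerate(data.gene_names):
        labels = np.full(row_order.size, "0", dtype="U1")
        if n_pt:
            labels[:n_pt] = _assign_labels_vector(
                data.values[pseudo_idx, n],
                smoothed.sm[:, n],
                smoothed.sl[:, n],
                float(smoothed.mean[n]),
                float(smoothed.q05[n]),
                float(smoothed.q95[n]),
                th,
            )
        # steady rows (original and copied) keep '0'
        if not np.any(labels == "0"):
            raise ValueError(
                f"subproblem for gene {name!r} has no '0'-labeled cells: the "
                "inference method cannot function without expression data "
                "labeled '0'"
            )
        subproblems.append(
            LabeledSubproblem(
                target=n,
                target_name=name,
                feature_names=feature_names,
                inputs=inputs,
                labels=labels,
                weights=w,
                cell_ids=cell_ids,
            )
        )
    return subproblems
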