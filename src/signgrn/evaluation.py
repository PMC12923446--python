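"""Precision-recall scoring of ranked networks and random-expectation math."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RankedNetwork",
    "GoldStandard",
    "pr_curve",
    "auprc",
    "candidate_count",
    "expected_overlap",
    "top_k_overlap",
]


@dataclass
class RankedNetwork:
    """Directed regulator->target edges sorted by descending confidence."""

    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        seen = set()
        for reg, tgt, _ in self.edges:
            if reg == tgt:
                raise ValueError(f"self-edge not allowed: {reg}->{tgt}")
            if (reg, tgt) in seen:
                raise ValueError(f"duplicate edge: {reg}->{tgt}")
            seen.add((reg, tgt))
        confs = [c for _, _, c in self.edges]
        if any(c2 > c1 for c1, c2 in zip(confs, confs[1:])):
            raise ValueError("edges must be sorted by descending confidence")

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str, float]]) -> "RankedNetwork":
        """Sort (stably, by descending confidence) and wrap an edge list."""
        ordered = sorted(edges, key=lambda e: -e[2])
        return cls(ordered)

    def __len__(self) -> int:
        return len(self.edges)

    def top(self, k: int) -> list[tuple[str, str, float]]:
        return self.edges[:k]


@dataclass
class GoldStandard:
    """Known true directed regulations; self-edges are excluded."""

    genes: list[str]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        self.edges = {(r, t) for r, t in self.edges}
        for reg, tgt in self.edges:
            if reg == tgt:
                raise ValueError(f"gold standard contains self-edge {reg}->{tgt}")


def _undirected(edge: tuple[str, str]) -> frozenset:
    return frozenset(edge)


def pr_curve(
    ranked: RankedNetwork,
    gold: GoldStandard,
    ignore_direction: bool = False,
) -> list[tuple[float, float]]:
    """(recall, precision) points, one per distinct confidence threshold.

    Edges sharing a confidence value enter together.  With
    ``ignore_direction`` an edge counts as true when either orientation is
    in the gold standard, and recall is measured over undirected gold
    pairs.
    """
    if not ranked.edges:
        raise ValueError("ranked network is empty")
    if ignore_direction:
        positives = {_undirected(e) for e in gold.edges}
        def hit_key(reg, tgt):
            return _undirected((reg, tgt))
    else:
        positives = set(gold.edges)
        def hit_key(reg, tgt):
            return (reg, tgt)
    n_pos = len(positives)
    if n_pos == 0:
        raise ValueError("gold standard has no positive edges")

    points: list[tuple[float, float]] = []
    tp_keys: set = set()
    n_sel = 0
    n_true_sel = 0  # selected edges supported by the gold standard
    i = 0
    edges = ranked.edges
    while i < len(edges):
        conf = edges[i][2]
        j = i
        while j < len(edges) and edges[j][2] == conf:
            reg, tgt, _ = edges[j]
            key = hit_key(reg, tgt)
            if key in positives:
                tp_keys.add(key)
                n_true_sel += 1
            n_sel += 1
            j += 1
        precision = n_true_sel / n_sel
        recall = len(tp_keys) / n_pos
        points.append((recall, precision))
        i = j
    return points


def auprc(curve: list[tuple[float, float]]) -> float:
    """Trapezoidal area under a PR curve, anchored at recall 0 with the
    first point's precision."""
    if not curve:
        raise ValueError("empty curve")
    recalls = np.array([0.0] + [r for r, _ in curve])
    precisions = np.array([curve[0][1]] + [p for _, p in curve])
    return float(np.trapezoid(precisions, recalls))


def candidate_count(n: int) -> int:
    """Number of candidate regulations for *n* elements including a
    stimulus: self-regulations and regulations targeting the stimulus are
    excluded, giving ``n*(n-1) - (n-1) = (n-1)**2``."""
    if n < 2:
        raise ValueError("need at least 2 elements")
    return n * (n - 1) - (n - 1)


def expected_overlap(top_k: int, recorded: int, candidates: int) -> float:
    """Hypergeometric mean overlap ``k * m / M`` between a random size-k
    selection and *m* reference-supported edges among *M* candidates."""
    if candidates <= 0 or not (0 < top_k <= candidates):
        raise ValueError("need 0 < top_k <= candidates")
    if not (0 <= recorded <= candidates):
        raise ValueError("need 0 <= recorded <= candidates")
    return top_k * recorded / candidates


def top_k_overlap(
    ranked: RankedNetwork,
    reference: set[tuple[str, str]],
    k: int,
    ignore_direction: bool = False,
) -> int:
    """Number of the top-*k* ranked edges supported by *reference*."""
    if ignore_direction:
        ref = {_undirected(e) for e in reference}
        return sum(1 for r, t, _ in ranked.top(k) if _undirected((r, t)) in ref)
    return sum(1 for r, t, _ in ranked.top(k) if (r, t) in reference)
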