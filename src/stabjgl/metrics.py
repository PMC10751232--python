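"""Network-recovery metrics: precision, recall, sparsity and edge overlap."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .solver import GraphSet

__all__ = [
    "MetricsReport",
    "precision_recall",
    "pairwise_shared_fraction",
    "degree_sequence",
    "evaluate_result",
]


def _edge_set(g):
    """Accept a GraphSet (first graph), adjacency matrix, or set of pairs."""
    if isinstance(g, GraphSet):
        return g.edge_sets[0]
    if isinstance(g, (set, frozenset)):
        return {(min(i, j), max(i, j)) for i, j in g}
    a = np.asarray(g, dtype=bool)
    return {(int(i), int(j)) for i, j in zip(*np.nonzero(np.triu(a, 1)))}


@dataclass
class MetricsReport:
    """Per-group recovery metrics plus pairwise overlaps of the estimates.

    Precision is the fraction of predicted edges that are true; recall the
    fraction of true edges that were predicted.  An empty denominator with an
    empty numerator scores 1 by convention (an empty estimate of an empty
    graph is perfect; an empty estimate of a non-empty graph has precision 1
    and recall 0).
    """

    precision: list
    recall: list
    sparsity: list
    shared_fraction: list  # upper-triangle pair order (0,1), (0,2), ...
    lambda1: float | None = None
    lambda2: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def to_tsv_rows(self):
        """One flat (group, precision, recall, sparsity) row per group."""
        return [
            {
                "group": k + 1,
                "precision": self.precision[k],
                "recall": self.recall[k],
                "sparsity": self.sparsity[k],
            }
            for k in range(len(self.precision))
        ]


def _ratio(num: int, den: int) -> float:
    return 1.0 if den == 0 else num / den


def precision_recall(est: GraphSet, truth: GraphSet):
    """Per-group (precision, recall) of estimated versus true edge sets."""
    if est.K != truth.K or est.p != truth.p:
        raise ValueError("estimate and truth must share K and p")
    out = []
    for e_est, e_true in zip(est.edge_sets, truth.edge_sets):
        hits = len(e_est & e_true)
        out.append((_ratio(hits, len(e_est)), _ratio(hits, len(e_true))))
    return out


def pairwise_shared_fraction(g1, g2) -> float:
    """|E1 ∩ E2| / max(|E1|, |E2|); 1.0 when both graphs are empty."""
    e1, e2 = _edge_set(g1), _edge_set(g2)
    denom = max(len(e1), len(e2))
    return 1.0 if denom == 0 else len(e1 & e2) / denom


def degree_sequence(g) -> np.ndarray:
    """Node degrees; sums to 2|E|."""
    if isinstance(g, GraphSet):
        a = g.adjacency[0]
    else:
        a = np.asarray(g, dtype=bool)
    return a.sum(axis=1).astype(int)


def evaluate_result(
    est: GraphSet,
    truth: GraphSet,
    lambda1: float | None = None,
    lambda2: float | None = None,
) -> MetricsReport:
    """Bundle precision/recall, estimated sparsities and pairwise overlaps."""
    pr = precision_recall(est, truth)
    shared = [
        pairwise_shared_fraction(est.edge_sets[a], est.edge_sets[b])
        for a in range(est.K)
        for b in range(a + 1, est.K)
    ]
    return MetricsReport(
        precision=[p for p, _ in pr],
        recall=[r for _, r in pr],
        sparsity=[float(s) for s in est.sparsity],
        shared_fraction=shared,
        lambda1=lambda1,
        lambda2=lambda2,
    )
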