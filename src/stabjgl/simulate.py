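"""Synthetic multi-network scenarios: related scale-free Gaussian graphical models.

The generator emulates the benchmark conditions used throughout this package:
each group's true conditional-independence graph is a preferential-attachment
tree (scale-free degree distribution, exactly p-1 edges, hence sparsity 2/p);
the K graphs share a controllable fraction of edges; edge partial correlations
have magnitudes in [0.1, 0.2] (weak, realistic omics-scale associations) with
random signs, shared edges carrying the same signed value in every group; and
observations are i.i.d. zero-mean Gaussian with covariance Theta^{-1}.

Precision matrices are built directly on the partial-correlation scale: with
unit diagonal, theta_ij = -rho_ij makes every edge's partial correlation land
in the target range exactly and every non-edge exactly zero.  Positive
definiteness is checked by eigendecomposition and, in the rare case of a
violation, edge magnitudes are shrunk toward the lower bound of the range
until the smallest eigenvalue clears a margin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .metrics import pairwise_shared_fraction
from .solver import GraphSet, PrecisionSet

__all__ = [
    "SyntheticScenario",
    "scale_free_graph",
    "related_graphs",
    "precision_from_graph",
    "sample_gaussian",
    "make_scenario",
    "export_scenario",
]

_PD_MARGIN = 1e-3


@dataclass
class SyntheticScenario:
    """Ground truth plus sampled data for K related groups."""

    K: int
    p: int
    n: list
    fraction_shared: float
    pcor_range: tuple
    seed: int
    true_graphs: GraphSet
    true_precisions: PrecisionSet
    data: list
    realized_shared_fraction: float


def scale_free_graph(p: int, seed: int) -> GraphSet:
    """Preferential-attachment tree on p nodes: p-1 edges, sparsity 2/p."""
    if p < 3:
        raise ValueError("need p >= 3 nodes")
    g = nx.barabasi_albert_graph(p, 1, seed=int(seed))
    adj = nx.to_numpy_array(g, nodelist=range(p), dtype=float) > 0
    return GraphSet(adjacency=[adj])


def related_graphs(base: GraphSet, K: int, fraction_shared: float, seed: int) -> GraphSet:
    """K graphs sharing a protected core of the base graph's edges.

    round(fraction_shared * |E|) base edges are kept in every group; the rest
    are rewired independently per group, uniformly over vacant non-core node
    pairs, so each graph keeps exactly |E| edges.  Pairwise overlap therefore
    matches fraction_shared up to a small chance-overlap excess (~2/p).
    """
    if not 0.0 <= fraction_shared <= 1.0:
        raise ValueError("fraction_shared must lie in [0, 1]")
    p = base.p
    edges = sorted(base.edge_sets[0])
    n_edges = len(edges)
    rng = np.random.default_rng(seed)
    n_core = int(round(fraction_shared * n_edges))
    core_idx = rng.choice(n_edges, size=n_core, replace=False)
    core = {edges[i] for i in core_idx}
    adjacency = []
    for _ in range(K):
        chosen = set(core)
        while len(chosen) < n_edges:
            i, j = rng.integers(p), rng.integers(p)
            if i == j:
                continue
            e = (min(i, j), max(i, j))
            if e in chosen:
                continue
            chosen.add((int(e[0]), int(e[1])))
        a = np.zeros((p, p), dtype=bool)
        rows, cols = zip(*chosen)
        a[rows, cols] = True
        adjacency.append(a | a.T)
    return GraphSet(adjacency=adjacency)


def precision_from_graph(
    graph,
    pcor_range=(0.1, 0.2),
    seed: int = 0,
    values: dict | None = None,
    max_rounds: int = 200,
) -> np.ndarray:
    """Precision matrix whose edge partial correlations lie in ``pcor_range``.

    ``graph`` is an adjacency matrix or a single-graph GraphSet.  With unit
    diagonal the partial correlation of edge (i, j) is exactly -theta_ij, so
    entries are drawn as signed magnitudes in the range (or taken from
    ``values``, a {(i, j): rho} mapping used to share edge values across
    groups).  If the matrix is not positive definite with margin, magnitudes
    are shrunk by 10% steps, floored at the lower bound, for at most
    ``max_rounds`` rounds.
    """
    low, high = pcor_range
    if not 0 < low < high < 1:
        raise ValueError("pcor_range must satisfy 0 < low < high < 1")
    adj = graph.adjacency[0] if isinstance(graph, GraphSet) else np.asarray(graph, dtype=bool)
    p = adj.shape[0]
    rows, cols = np.nonzero(np.triu(adj, 1))
    rng = np.random.default_rng(seed)
    if values is None:
        rho = rng.uniform(low, high, size=rows.size) * rng.choice([-1.0, 1.0], size=rows.size)
    else:
        rho = np.array([values[(int(i), int(j))] for i, j in zip(rows, cols)], dtype=float)
    for _ in range(max_rounds):
        R = np.zeros((p, p))
        R[rows, cols] = rho
        R = R + R.T
        theta = np.eye(p) - R
        if rows.size == 0 or np.linalg.eigvalsh(theta)[0] > _PD_MARGIN:
            return theta
        if np.all(np.abs(rho) <= low):
            break
        rho = np.sign(rho) * np.maximum(low, 0.9 * np.abs(rho))
    raise RuntimeError(
        "could not reach positive definiteness within the partial-correlation range"
    )


def sample_gaussian(theta: np.ndarray, n: int, seed: int) -> np.ndarray:
    """n i.i.d. zero-mean Gaussian rows with covariance theta^{-1}."""
    theta = np.asarray(theta, dtype=float)
    if n < 1:
        raise ValueError("n must be positive")
    if np.linalg.eigvalsh(theta)[0] <= 0:
        raise ValueError("theta must be positive definite")
    sigma = np.linalg.inv(theta)
    sigma = (sigma + sigma.T) / 2.0
    L = np.linalg.cholesky(sigma)
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, theta.shape[0])) @ L.T


def make_scenario(
    K: int,
    p: int,
    n,
    fraction_shared: float = 1.0,
    seed: int = 0,
    pcor_range=(0.1, 0.2),
) -> SyntheticScenario:
    """Compose graphs, precision matrices and data into one scenario.

    Shared edges carry the same signed partial correlation in every group.
    The realized pairwise shared-edge fraction is validated against the
    nominal one with tolerance 0.05 + 2/p (the 2/p term covers the expected
    chance overlap of independently rewired edges) and stored in the result.
    """
    if isinstance(n, (int, np.integer)):
        n = [int(n)] * K
    n = [int(v) for v in n]
    if len(n) != K:
        raise ValueError("n must have one entry per group")
    ss = np.random.SeedSequence(seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3 + K)]
    base = scale_free_graph(p, child[0])
    graphs = related_graphs(base, K, fraction_shared, child[1]) if K > 1 else base
    # one signed value per node pair, reused wherever that edge appears
    rng = np.random.default_rng(child[2])
    low, high = pcor_range
    all_pairs = sorted(set().union(*graphs.edge_sets))
    values = {
        e: float(rng.uniform(low, high) * rng.choice([-1.0, 1.0])) for e in all_pairs
    }
    thetas = [
        precision_from_graph(graphs.adjacency[k], pcor_range, values=values)
        for k in range(K)
    ]
    data = [sample_gaussian(thetas[k], n[k], child[3 + k]) for k in range(K)]

    for k, e in enumerate(graphs.edge_sets):
        if len(e) != p - 1:
            raise RuntimeError(f"group {k}: expected {p - 1} edges, got {len(e)}")
    if K > 1:
        fracs = [
            pairwise_shared_fraction(graphs.edge_sets[a], graphs.edge_sets[b])
            for a in range(K)
            for b in range(a + 1, K)
        ]
        realized = float(np.mean(fracs))
        # tolerance: chance overlap of rewired edges (~2/p) plus 4 binomial sds
        chance = 2.0 / p
        tol = 0.05 + chance + 4.0 * np.sqrt(chance * (1 - chance) / (p - 1))
        if abs(realized - fraction_shared) > tol:
            raise RuntimeError(
                f"realized shared fraction {realized:.3f} too far from nominal {fraction_shared:.3f}"
            )
    else:
        realized = 1.0
    return SyntheticScenario(
        K=K,
        p=p,
        n=n,
        fraction_shared=fraction_shared,
        pcor_range=tuple(pcor_range),
        seed=seed,
        true_graphs=graphs,
        true_precisions=PrecisionSet(thetas),
        data=data,
        realized_shared_fraction=realized,
    )


def export_scenario(scn: SyntheticScenario, out_dir) -> None:
    """Write data matrices (TSV), true edge list (TSV) and metadata (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = [f"V{i + 1}" for i in range(scn.p)]
    header = "\t".join(names)
    for k, x in enumerate(scn.data):
        np.savetxt(
            out / f"data_group{k + 1}.tsv", x, delimiter="\t",
            header=header, comments="", fmt="%.10g",
        )
    with open(out / "true_edges.tsv", "w") as fh:
        fh.write("node_i\tnode_j\tgroup\tpartial_correlation\n")
        for k in range(scn.K):
            th = scn.true_precisions.theta[k]
            for i, j in sorted(scn.true_graphs.edge_sets[k]):
                rho = -th[i, j] / np.sqrt(th[i, i] * th[j, j])
                fh.write(f"{names[i]}\t{names[j]}\t{k + 1}\t{rho:.10g}\n")
    meta = {
        "K": scn.K,
        "p": scn.p,
        "n": scn.n,
        "fraction_shared": scn.fraction_shared,
        "realized_shared_fraction": scn.realized_shared_fraction,
        "pcor_range": list(scn.pcor_range),
        "seed": scn.seed,
        "true_sparsity": [float(s) for s in scn.true_graphs.sparsity],
    }
    with open(out / "scenario.json", "w") as fh:
        json.dump(meta, fh, indent=2)
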