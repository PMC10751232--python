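"""Sparsity-penalty selection by multi-network stability under subsampling.

Extends the StARS idea (stability approach to regularization selection) to K
jointly estimated networks: draw subsamples without replacement from every
group, refit the fused joint graphical lasso over a grid of lambda1 values
with lambda2 held at a small fixed value, and measure how reproducible each
edge call is across subsamples.  For edge (i, j) in group k let psi be the
fraction of subsamples in which it is selected; its instability is
xi = 2*psi*(1-psi) (twice the Bernoulli variance, in [0, 0.5]), graph
variability D(k) is the mean of xi over node pairs, and total variability D
is the mean over groups.  D is monotonized from the sparse end
(Dbar(lambda1) = sup_{t >= lambda1} D(t)) and the selected lambda1 is the
smallest grid value with Dbar <= beta1, i.e. the least penalization whose
graphs are reproducible to within the variability budget beta1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .solver import (
    DEFAULT_ZERO_TOL,
    PenaltyPair,
    empirical_covariance,
    fit_jgl,
    graph_from_precision,
)

__all__ = [
    "DEFAULT_LAMBDA1_GRID",
    "StabilityConfig",
    "StabilityProfile",
    "subsample_size",
    "draw_subsamples",
    "edge_probabilities",
    "edge_instability",
    "graph_variability",
    "total_variability",
    "monotonize",
    "select_lambda1",
    "lambda1_profile",
]

DEFAULT_LAMBDA1_GRID = np.linspace(0.01, 1.0, 20)


@dataclass
class StabilityConfig:
    """Settings for the lambda1 stability search.

    Defaults: 20 subsamples, 20 lambda1 values linear on [0.01, 1], lambda2
    fixed at 0.01 during the search, variability threshold beta1 = 0.1
    (accept 10% edge-assignment variability), subsample sizes
    b_k = min(floor(10*sqrt(n_k)), n_k - 1).
    """

    lambda1_grid: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDA1_GRID.copy())
    lambda2_fixed: float = 0.01
    n_subsamples: int = 20
    beta1: float = 0.1
    subsample_sizes: list | None = None
    seed: int = 0
    workers: int = 1
    standardize: bool = True
    zero_tol: float = DEFAULT_ZERO_TOL
    tol: float = 1e-5
    max_iter: int = 500
    step: float = 1.0

    def __post_init__(self) -> None:
        grid = np.asarray(self.lambda1_grid, dtype=float)
        if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("lambda1_grid must be a non-empty strictly increasing vector")
        self.lambda1_grid = grid
        if self.lambda2_fixed < 0:
            raise ValueError("lambda2_fixed must be non-negative")
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be positive")
        if not 0 < self.beta1 <= 0.5:
            raise ValueError("beta1 must lie in (0, 0.5]")


@dataclass
class StabilityProfile:
    """Edge probabilities, instabilities and variabilities along the grid."""

    lambda1_grid: np.ndarray  # (G,)
    psi: np.ndarray  # (G, K, p, p) edge selection probabilities
    xi: np.ndarray  # (G, K, p, p) instabilities 2*psi*(1-psi)
    d_per_group: np.ndarray  # (G, K)
    d_total: np.ndarray  # (G,)
    d_mono: np.ndarray  # (G,) monotonized variability
    selected_lambda1: float
    selected_index: int


def subsample_size(n_k: int) -> int:
    """StARS subsample size: floor(10*sqrt(n_k)), falling back to 80% of n_k.

    The 10*sqrt(n) rule is only meaningful when it is well below n (it
    reaches n at n = 100 and stays close to it until n ~ 200, where
    subsamples become near-copies of the data and edge variability
    degenerates to zero); below n = 144 the standard fallback of
    floor(0.8 * n_k) is used instead, capped at n_k - 1.
    """
    if n_k < 2:
        raise ValueError("need at least 2 observations")
    b = 10.0 * np.sqrt(n_k) if n_k > 144 else 0.8 * n_k
    return int(min(np.floor(b), n_k - 1))


def draw_subsamples(n, sizes, n_subsamples: int, seed: int):
    """Index subsets, without replacement, per replicate and group.

    Returns a list of ``n_subsamples`` entries, each a list of K index
    arrays.  Fully reproducible from ``seed``; the same subsamples are meant
    to be reused across the whole lambda1 grid.
    """
    for nk, bk in zip(n, sizes):
        if bk >= nk:
            raise ValueError(f"subsample size {bk} must be smaller than group size {nk}")
    rng = np.random.default_rng(seed)
    return [
        [np.sort(rng.choice(nk, size=bk, replace=False)) for nk, bk in zip(n, sizes)]
        for _ in range(n_subsamples)
    ]


def edge_probabilities(graphs) -> np.ndarray:
    """psi_ij(k) = fraction of replicate graphs containing edge (i, j).

    ``graphs`` is a sequence of GraphSets, one per subsample replicate.
    Returns an array of shape (K, p, p), symmetric with zero diagonal.
    """
    if not graphs:
        raise ValueError("need at least one replicate graph set")
    stacks = np.stack([np.stack([a for a in g.adjacency]) for g in graphs])
    return stacks.mean(axis=0)


def edge_instability(psi):
    """xi = 2*psi*(1-psi), twice the Bernoulli variance; lies in [0, 0.5]."""
    psi = np.asarray(psi, dtype=float)
    if np.any(psi < 0) or np.any(psi > 1):
        raise ValueError("psi must lie in [0, 1]")
    return 2.0 * psi * (1.0 - psi)


def graph_variability(xi) -> float:
    """Mean instability over the p-choose-2 node pairs of one group."""
    xi = np.asarray(xi, dtype=float)
    p = xi.shape[0]
    iu = np.triu_indices(p, 1)
    return float(xi[iu].mean())


def total_variability(d_per_group) -> float:
    """Mean of the per-group variabilities."""
    return float(np.mean(np.asarray(d_per_group, dtype=float)))


def monotonize(d_total) -> np.ndarray:
    """Running maximum from the sparse (large-lambda1) end of the grid.

    Dbar(lambda1_i) = max_{j >= i} D(lambda1_j); non-increasing in lambda1.
    """
    d = np.asarray(d_total, dtype=float)
    return np.maximum.accumulate(d[::-1])[::-1]


def select_lambda1(d_mono, grid, beta1: float) -> float:
    """Smallest grid value whose monotonized variability is <= beta1.

    Falls back to the largest grid value (sparsest available model), with a
    warning, when no grid point meets the threshold.
    """
    d_mono = np.asarray(d_mono, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda1 grid")
    ok = np.nonzero(d_mono <= beta1)[0]
    if ok.size == 0:
        warnings.warn(
            f"no lambda1 on the grid meets the variability threshold beta1={beta1}; "
            "returning the largest grid value",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(grid[-1])
    return float(grid[ok[0]])


def _replicate_adjacencies(X, indices, grid, lambda2, standardize, tol, max_iter, step, zero_tol):
    """Adjacency stack (G, K, p, p) for one subsample replicate.

    Fits are warm-started along the increasing lambda1 grid.
    """
    sub = [x[idx] for x, idx in zip(X, indices)]
    cov = empirical_covariance(sub, standardize=standardize)
    G = len(grid)
    out = np.zeros((G, cov.K, cov.p, cov.p), dtype=bool)
    state = None
    for g, lam1 in enumerate(grid):
        ps, state = fit_jgl(
            cov,
            PenaltyPair(lam1, lambda2),
            tol=tol,
            max_iter=max_iter,
            step=step,
            init=state,
            return_state=True,
        )
        gs = graph_from_precision(ps, zero_tol=zero_tol)
        out[g] = np.stack(gs.adjacency)
    return out


def lambda1_profile(X, cfg: StabilityConfig | None = None, **overrides) -> StabilityProfile:
    """Run the full stability search over the lambda1 grid.

    Subsamples are drawn once and reused for every grid value; replicates
    may run in parallel (``cfg.workers``) and the result is identical to the
    sequential one for a fixed seed because each replicate is independent
    and aggregation order is fixed.
    """
    if cfg is None:
        cfg = StabilityConfig(**overrides)
    elif overrides:
        raise TypeError("pass either cfg or keyword overrides, not both")
    X = [np.asarray(x, dtype=float) for x in X]
    n = [x.shape[0] for x in X]
    sizes = cfg.subsample_sizes or [subsample_size(nk) for nk in n]
    subs = draw_subsamples(n, sizes, cfg.n_subsamples, cfg.seed)
    grid = cfg.lambda1_grid
    jobs = (
        delayed(_replicate_adjacencies)(
            X, idx, grid, cfg.lambda2_fixed, cfg.standardize,
            cfg.tol, cfg.max_iter, cfg.step, cfg.zero_tol,
        )
        for idx in subs
    )
    stacks = Parallel(n_jobs=cfg.workers)(jobs)
    psi = np.stack(stacks).mean(axis=0)  # (G, K, p, p)
    xi = edge_instability(psi)
    p = psi.shape[-1]
    iu = np.triu_indices(p, 1)
    d_per_group = xi[:, :, iu[0], iu[1]].mean(axis=-1)  # (G, K)
    d_total = d_per_group.mean(axis=1)  # (G,)
    d_mono = monotonize(d_total)
    selected = select_lambda1(d_mono, grid, cfg.beta1)
    idx = int(np.nonzero(grid == selected)[0][0])
    return StabilityProfile(
        lambda1_grid=grid,
        psi=psi,
        xi=xi,
        d_per_group=d_per_group,
        d_total=d_total,
        d_mono=d_mono,
        selected_lambda1=selected,
        selected_index=idx,
    )
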