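"""Similarity-penalty selection by a multi-network extended BIC.

With the sparsity penalty lambda1 fixed (chosen by stability), lambda2 is
picked by minimizing

    BIC_gamma = sum_k [ n_k tr(S(k) Theta(k)) - n_k log det Theta(k)
                        + |E_k| log n_k + 4 |E_k| gamma log p ]

over a grid of lambda2 values, refitting the fused joint graphical lasso on
the full data at each grid point.  gamma = 0 recovers the ordinary BIC and is
the default: since the criterion compares graphs of similar sparsity (lambda1
is already fixed), the extra high-dimensionality penalty matters little here.
An AIC variant (edge penalty 2|E_k| in place of the BIC terms) is provided as
the baseline criterion traditionally used to tune the fused graphical lasso.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .solver import (
    DEFAULT_ZERO_TOL,
    CovarianceSet,
    PenaltyPair,
    PrecisionSet,
    empirical_covariance,
    fit_jgl,
    graph_from_precision,
)
from .stability import DEFAULT_LAMBDA1_GRID

__all__ = [
    "DEFAULT_LAMBDA2_GRID",
    "SimilarityProfile",
    "multinetwork_ebic",
    "aic_baseline",
    "select_lambda2",
    "select_by_aic",
]

DEFAULT_LAMBDA2_GRID = np.linspace(0.0, 0.1, 20)


@dataclass
class SimilarityProfile:
    """eBIC scores along the lambda2 grid and the selected value."""

    lambda2_grid: np.ndarray
    scores: np.ndarray
    gamma: float
    selected_lambda2: float
    selected_index: int


def _fit_terms(ps: PrecisionSet, cov: CovarianceSet, zero_tol: float):
    """Per-group (n*tr(S Theta) - n*logdet Theta, edge count)."""
    edge_counts = [len(e) for e in graph_from_precision(ps, zero_tol=zero_tol).edge_sets]
    terms = []
    for k in range(cov.K):
        th = np.asarray(ps.theta[k], dtype=float)
        sign, logdet = np.linalg.slogdet(th)
        if sign <= 0:
            raise ValueError(f"group {k}: precision matrix is not positive definite")
        nk = cov.n[k]
        terms.append(nk * float(np.trace(cov.S[k] @ th)) - nk * logdet)
    return terms, edge_counts


def multinetwork_ebic(
    ps: PrecisionSet,
    cov: CovarianceSet,
    gamma: float = 0.0,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> float:
    """Extended BIC summed over the K networks (see module docstring).

    Edge counts use the same ``zero_tol`` convention as edge calling, so the
    score is reproducible from a reported precision set.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    terms, edges = _fit_terms(ps, cov, zero_tol)
    p = cov.p
    score = 0.0
    for k in range(cov.K):
        score += terms[k] + edges[k] * np.log(cov.n[k]) + 4.0 * edges[k] * gamma * np.log(p)
    return float(score)


def aic_baseline(ps: PrecisionSet, cov: CovarianceSet, zero_tol: float = DEFAULT_ZERO_TOL) -> float:
    """AIC: same likelihood terms with a 2|E_k| complexity penalty per group."""
    terms, edges = _fit_terms(ps, cov, zero_tol)
    return float(sum(t + 2.0 * e for t, e in zip(terms, edges)))


def select_lambda2(
    X,
    lambda1: float,
    lambda2_grid=None,
    gamma: float = 0.0,
    standardize: bool = True,
    zero_tol: float = DEFAULT_ZERO_TOL,
    tol: float = 1e-5,
    max_iter: int = 500,
    step: float = 1.0,
) -> SimilarityProfile:
    """Pick lambda2 minimizing the multi-network eBIC at fixed lambda1.

    Fits on the full data (no subsampling) at every grid value, warm-starting
    along the grid.  Ties break toward smaller lambda2 (less coupling).
    """
    grid = np.asarray(
        DEFAULT_LAMBDA2_GRID if lambda2_grid is None else lambda2_grid, dtype=float
    )
    if grid.ndim != 1 or grid.size == 0 or np.any(grid < 0):
        raise ValueError("lambda2_grid must be a non-empty vector of non-negative values")
    cov = empirical_covariance(X, standardize=standardize)
    scores = np.empty(grid.size)
    state = None
    for g, lam2 in enumerate(grid):
        ps, state = fit_jgl(
            cov, PenaltyPair(lambda1, lam2),
            tol=tol, max_iter=max_iter, step=step, init=state, return_state=True,
        )
        scores[g] = multinetwork_ebic(ps, cov, gamma=gamma, zero_tol=zero_tol)
    idx = int(np.argmin(scores))  # argmin returns the first (smallest lambda2) minimizer
    return SimilarityProfile(
        lambda2_grid=grid,
        scores=scores,
        gamma=gamma,
        selected_lambda2=float(grid[idx]),
        selected_index=idx,
    )


def select_by_aic(
    X,
    lambda1_grid=None,
    lambda2_grid=None,
    standardize: bool = True,
    zero_tol: float = DEFAULT_ZERO_TOL,
    tol: float = 1e-5,
    max_iter: int = 500,
    step: float = 1.0,
):
    """Joint (lambda1, lambda2) selection by AIC over the full 2-d grid.

    This is the baseline tuning strategy for the fused graphical lasso that
    the stability/eBIC two-step procedure is designed to improve upon; it
    tends to over-select edges in high dimensions.

    Returns ``(lambda1, lambda2, PrecisionSet)`` for the AIC-minimizing pair
    (ties toward smaller penalties).
    """
    g1 = np.asarray(DEFAULT_LAMBDA1_GRID if lambda1_grid is None else lambda1_grid, dtype=float)
    g2 = np.asarray(DEFAULT_LAMBDA2_GRID if lambda2_grid is None else lambda2_grid, dtype=float)
    cov = empirical_covariance(X, standardize=standardize)
    best = (np.inf, None, None, None)
    row_state = None
    for lam1 in g1:
        state = row_state
        for j, lam2 in enumerate(g2):
            ps, state = fit_jgl(
                cov, PenaltyPair(lam1, lam2),
                tol=tol, max_iter=max_iter, step=step, init=state, return_state=True,
            )
            if j == 0:
                row_state = state  # warm start for the next lambda1 row
            score = aic_baseline(ps, cov, zero_tol=zero_tol)
            if score < best[0]:
                best = (score, float(lam1), float(lam2), ps)
    _, lam1, lam2, ps = best
    return lam1, lam2, ps
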