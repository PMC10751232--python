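"""Fused joint graphical lasso solved by ADMM.

Estimates K sparse precision matrices Theta(1..K) from per-group sample
covariances by maximizing the penalized log-likelihood

    sum_k w_k [ log det Theta(k) - tr(S(k) Theta(k)) ]
        - lambda1 * sum_k sum_{i!=j} |theta_ij(k)|
        - lambda2 * sum_{k<k'} || Theta(k) - Theta(k') ||_1

where the likelihood weights w_k are 1 by default (so the penalties live on
the familiar per-observation graphical-lasso scale and a single grid such as
lambda1 in [0.01, 1] is meaningful for any sample size); weighting by n_k is
available as an option and simply rescales the penalties.

The lasso (lambda1) term acts on off-diagonal entries only and controls the
sparsity of each conditional-independence graph; the fused (lambda2) term acts
on every entry of each pairwise difference and shrinks corresponding entries
of the K precision matrices toward each other, so related datasets borrow
strength from one another.

ADMM splits the smooth likelihood from the non-smooth penalty.  The
likelihood subproblem has a closed-form solution via an eigendecomposition
per group (``theta_step``); the penalty subproblem separates across matrix
entries into K-dimensional fused-lasso proximal problems (``fused_prox``)
solved exactly: closed form for K=2, exhaustive contiguous-block enumeration
on the sorted coordinates for K>=3 (exact because the proximal map preserves
the coordinate ordering of its argument).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np

__all__ = [
    "PenaltyPair",
    "CovarianceSet",
    "PrecisionSet",
    "ADMMState",
    "GraphSet",
    "empirical_covariance",
    "soft_threshold",
    "fused_prox",
    "theta_step",
    "fit_jgl",
    "graph_from_precision",
]

_SYM_TOL = 1e-10
DEFAULT_ZERO_TOL = 1e-5


@dataclass
class PenaltyPair:
    """Sparsity (``lambda1``) and similarity (``lambda2``) penalty weights."""

    lambda1: float
    lambda2: float

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalty parameters must be non-negative")


@dataclass
class CovarianceSet:
    """Per-group sample covariance matrices with their sample counts.

    Parameters
    ----------
    S : list of (p, p) ndarray
        Symmetric sample covariance (or correlation) matrix per group.
    n : list of int
        Number of observations per group; each must be >= 2.
    feature_names : list of str
        The p variable names, shared across groups.
    """

    S: list
    n: list
    feature_names: list

    def __post_init__(self) -> None:
        self.S = [np.asarray(s, dtype=float) for s in self.S]
        self.n = [int(v) for v in self.n]
        if len(self.S) != len(self.n) or not self.S:
            raise ValueError("S and n must be non-empty and of equal length")
        p = self.S[0].shape[0]
        for k, s in enumerate(self.S):
            if s.shape != (p, p):
                raise ValueError(f"group {k}: expected a {p}x{p} matrix, got {s.shape}")
            if np.max(np.abs(s - s.T)) > _SYM_TOL:
                raise ValueError(f"group {k}: covariance matrix is not symmetric")
        for k, nk in enumerate(self.n):
            if nk < 2:
                raise ValueError(f"group {k}: need at least 2 observations, got {nk}")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must equal matrix dimension")

    @property
    def K(self) -> int:
        return len(self.S)

    @property
    def p(self) -> int:
        return self.S[0].shape[0]


@dataclass
class PrecisionSet:
    """K estimated precision matrices plus solver metadata."""

    theta: list
    penalty: PenaltyPair | None = None
    converged: bool = True
    iterations: int = 0

    @property
    def K(self) -> int:
        return len(self.theta)

    @property
    def p(self) -> int:
        return self.theta[0].shape[0]


@dataclass
class ADMMState:
    """Internal ADMM variables, exposed to allow warm starts across penalties."""

    theta: np.ndarray  # (K, p, p)
    Z: np.ndarray  # (K, p, p) split variable; carries the exact zeros
    U: np.ndarray  # (K, p, p) scaled dual variable
    step: float
    primal_residual: float = np.inf
    dual_residual: float = np.inf


@dataclass
class GraphSet:
    """Per-group undirected graphs as adjacency matrices and edge sets."""

    adjacency: list
    edge_sets: list = field(default=None)
    sparsity: list = field(default=None)

    def __post_init__(self) -> None:
        self.adjacency = [np.asarray(a, dtype=bool) for a in self.adjacency]
        p = self.adjacency[0].shape[0]
        for a in self.adjacency:
            np.fill_diagonal(a, False)
        if self.edge_sets is None:
            self.edge_sets = [
                {(int(i), int(j)) for i, j in zip(*np.nonzero(np.triu(a, 1)))}
                for a in self.adjacency
            ]
        if self.sparsity is None:
            denom = p * (p - 1)
            self.sparsity = [2.0 * len(e) / denom for e in self.edge_sets]

    @property
    def K(self) -> int:
        return len(self.adjacency)

    @property
    def p(self) -> int:
        return self.adjacency[0].shape[0]


def empirical_covariance(X, standardize: bool = True, feature_names=None) -> CovarianceSet:
    """Per-group sample covariance S = (1/(n-1)) Xc' Xc of mean-centered data.

    With ``standardize`` (the default) each column is additionally scaled to
    unit variance, so S(k) is the sample correlation matrix; this makes a
    single penalty grid meaningful across features with different scales.
    """
    mats = [np.asarray(x, dtype=float) for x in X]
    dims = {m.shape[1] for m in mats}
    if len(dims) != 1:
        raise ValueError(f"all groups must share the same number of columns, got {sorted(dims)}")
    p = dims.pop()
    S, n = [], []
    for k, m in enumerate(mats):
        nk = m.shape[0]
        if nk < 2:
            raise ValueError(f"group {k}: need at least 2 rows, got {nk}")
        c = m - m.mean(axis=0)
        s = c.T @ c / (nk - 1)
        if standardize:
            d = np.sqrt(np.diag(s))
            bad = np.nonzero(d <= 0)[0]
            if bad.size:
                raise ValueError(f"group {k}: zero-variance column(s) {bad.tolist()} cannot be standardized")
            s = s / np.outer(d, d)
            np.fill_diagonal(s, 1.0)
        S.append((s + s.T) / 2.0)
        n.append(nk)
    if feature_names is None:
        feature_names = [f"V{i + 1}" for i in range(p)]
    return CovarianceSet(S, n, list(feature_names))


def soft_threshold(x, t):
    """Elementwise soft-thresholding sign(x) * max(|x| - t, 0)."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("threshold must be non-negative")
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


@lru_cache(maxsize=None)
def _fusion_patterns(K: int):
    """Candidate contiguous-block partitions of K sorted coordinates.

    Each candidate is (M, c): the block-averaging matrix and the fusion
    offset per position, giving the stationary point v = M z + a2 * c of the
    fusion objective restricted to that block pattern.
    """
    patterns = []
    for mask in range(2 ** (K - 1)):
        bounds = [i + 1 for i in range(K - 1) if (mask >> i) & 1]
        blocks = np.split(np.arange(K), bounds)
        M = np.zeros((K, K))
        c = np.zeros(K)
        below = 0
        for b in blocks:
            size = len(b)
            above = K - below - size
            M[np.ix_(b, b)] = 1.0 / size
            c[b] = above - below
            below += size
        patterns.append((M, c))
    return patterns


def _fusion_prox(B: np.ndarray, a2: float) -> np.ndarray:
    """Columnwise minimizer of (1/2)||v - b||^2 + a2 * sum_{k<l} |v_k - v_l|.

    ``B`` has shape (K, m): each column is one independent K-dimensional
    problem.  K=2 uses the closed form (fuse to the mean if the gap is within
    2*a2, otherwise move both ends by a2); K>=3 enumerates all 2^(K-1)
    contiguous block partitions of the sorted coordinates and keeps the
    candidate with the smallest objective, which is exact because the
    proximal map is order preserving.
    """
    K = B.shape[0]
    if K == 1 or a2 == 0.0:
        return B.copy()
    if K == 2:
        d = B[0] - B[1]
        shift = np.sign(d) * np.minimum(np.abs(d) / 2.0, a2)
        return np.stack([B[0] - shift, B[1] + shift])
    order = np.argsort(B, axis=0, kind="stable")
    Bs = np.take_along_axis(B, order, axis=0)
    best_obj = None
    best_v = None
    for M, c in _fusion_patterns(K):
        v = M @ Bs + a2 * c[:, None]
        obj = 0.5 * ((v - Bs) ** 2).sum(axis=0)
        for i, j in combinations(range(K), 2):
            obj = obj + a2 * np.abs(v[i] - v[j])
        if best_obj is None:
            best_obj, best_v = obj, v
        else:
            better = obj < best_obj
            best_obj = np.where(better, obj, best_obj)
            best_v = np.where(better[None, :], v, best_v)
    out = np.empty_like(B)
    np.put_along_axis(out, order, best_v, axis=0)
    return out


def fused_prox(z, a1: float, a2: float) -> np.ndarray:
    """Minimizer of (1/2)||v-z||^2 + a1*||v||_1 + a2*sum_{k<l}|v_k - v_l|.

    Solved by fusing first and soft-thresholding the fused solution by
    ``a1``, which is exact because the fusion penalty depends only on
    pairwise differences.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if a1 < 0 or a2 < 0:
        raise ValueError("a1 and a2 must be non-negative")
    v = _fusion_prox(z[:, None], a2)[:, 0]
    return soft_threshold(v, a1)


def theta_step(S_k: np.ndarray, A_k: np.ndarray, n_k: int, step: float) -> np.ndarray:
    """Closed-form minimizer of n_k[tr(S Theta) - log det Theta] + (step/2)||Theta - A||_F^2.

    Eigendecompose (step*A - n_k*S)/step and map each eigenvalue d to
    (d + sqrt(d^2 + 4 n_k/step))/2; the result is symmetric positive
    definite for any symmetric input.
    """
    S_k = np.asarray(S_k, dtype=float)
    A_k = np.asarray(A_k, dtype=float)
    if np.max(np.abs(S_k - S_k.T)) > 1e-8 or np.max(np.abs(A_k - A_k.T)) > 1e-8:
        raise ValueError("theta_step requires symmetric inputs")
    if step <= 0:
        raise ValueError("step must be positive")
    M = A_k - (n_k / step) * S_k
    w, V = np.linalg.eigh((M + M.T) / 2.0)
    phi = (w + np.sqrt(w * w + 4.0 * n_k / step)) / 2.0
    return (V * phi) @ V.T


def fit_jgl(
    cov: CovarianceSet,
    penalty: PenaltyPair,
    tol: float = 1e-5,
    max_iter: int = 500,
    step: float = 1.0,
    init: ADMMState | None = None,
    return_state: bool = False,
    weights="equal",
):
    """Solve the fused joint graphical lasso by ADMM.

    Parameters
    ----------
    cov : CovarianceSet
        Per-group sample covariances and sample counts.
    penalty : PenaltyPair
        Sparsity (lambda1, off-diagonal entries) and similarity (lambda2,
        all entries of pairwise differences) penalties.
    tol : float
        Stop when both the primal residual max_k ||Theta - Z||_max and the
        dual residual step*||Z - Z_prev||_max fall below this value.
    max_iter : int
        Iteration cap; exhaustion emits a warning, not an error.
    step : float
        ADMM step size (rho); fixed, no adaptive balancing, so runs are
        deterministic.
    init : ADMMState, optional
        Warm start, e.g. the state returned for a neighbouring penalty.
    return_state : bool
        Also return the final ADMMState (for warm-starting the next fit).
    weights : "equal" or "sample_size" or sequence of K floats
        Weight of each group's log-likelihood term relative to the
        penalties.  The default "equal" gives every group weight 1, so the
        standard penalty grids (lambda1 in [0.01, 1]) are on the familiar
        per-observation graphical-lasso scale regardless of sample size;
        "sample_size" multiplies each likelihood by n_k instead, which
        rescales the meaning of the penalties by a factor of roughly n.

    Returns
    -------
    PrecisionSet, or (PrecisionSet, ADMMState) if ``return_state``.
    """
    K, p = cov.K, cov.p
    if isinstance(weights, str):
        if weights == "equal":
            w = [1.0] * K
        elif weights == "sample_size":
            w = [float(nk) for nk in cov.n]
        else:
            raise ValueError("weights must be 'equal', 'sample_size', or a sequence")
    else:
        w = [float(v) for v in weights]
        if len(w) != K:
            raise ValueError("need one likelihood weight per group")
    lam1, lam2 = penalty.lambda1, penalty.lambda2
    offdiag = 1.0 - np.eye(p)
    a1 = (lam1 / step) * offdiag
    a2 = lam2 / step
    if init is not None:
        Z = np.array(init.Z, dtype=float, copy=True)
        U = np.array(init.U, dtype=float, copy=True)
        if Z.shape != (K, p, p):
            raise ValueError("warm-start state has incompatible shape")
    else:
        Z = np.stack([np.diag(1.0 / np.clip(np.diag(s), 1e-12, None)) for s in cov.S])
        U = np.zeros((K, p, p))

    theta = Z.copy()
    converged = False
    it = 0
    r_primal = r_dual = np.inf
    for it in range(1, max_iter + 1):
        theta = np.stack(
            [theta_step(cov.S[k], Z[k] - U[k], w[k], step) for k in range(K)]
        )
        B = theta + U
        Z_prev = Z
        Z = _fusion_prox(B.reshape(K, -1), a2).reshape(K, p, p)
        Z = soft_threshold(Z, a1[None, :, :])
        U = U + theta - Z
        r_primal = float(np.max(np.abs(theta - Z)))
        r_dual = float(step * np.max(np.abs(Z - Z_prev)))
        if not (np.isfinite(r_primal) and np.isfinite(r_dual)):
            raise FloatingPointError(
                "non-finite ADMM residuals: ill-conditioned input or bad step size"
            )
        if max(r_primal, r_dual) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"fit_jgl stopped at max_iter={max_iter} with residual "
            f"{max(r_primal, r_dual):.2e} > tol={tol:.0e}",
            RuntimeWarning,
            stacklevel=2,
        )
    theta_out = [(theta[k] + theta[k].T) / 2.0 for k in range(K)]
    result = PrecisionSet(theta_out, penalty=penalty, converged=converged, iterations=it)
    if return_state:
        return result, ADMMState(theta, Z, U, step, r_primal, r_dual)
    return result


def graph_from_precision(ps: PrecisionSet, zero_tol: float = DEFAULT_ZERO_TOL) -> GraphSet:
    """Call edges: (i, j) is an edge in group k iff |theta_ij(k)| > zero_tol.

    The tolerance is needed because the symmetrized ADMM output carries
    entries up to the convergence tolerance away from the exact zeros of the
    split variable.  The inequality is strict, so an entry equal to
    ``zero_tol`` is not an edge.
    """
    if zero_tol <= 0:
        raise ValueError("zero_tol must be positive")
    adjacency = []
    for th in ps.theta:
        a = np.abs(np.asarray(th)) > zero_tol
        np.fill_diagonal(a, False)
        adjacency.append(a | a.T)
    return GraphSet(adjacency=adjacency)
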