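"""Independent numeric oracles used by the tests.

These deliberately avoid the code paths they check: the fused proximal oracle
solves an epigraph QP reformulation with a generic constrained optimizer, and
the penalized-likelihood objective is evaluated term by term for direct
comparisons against generic solutions.
"""

from itertools import combinations

import numpy as np
from scipy.optimize import lsq_linear


def fused_objective(v, z, a1, a2):
    """(1/2)||v-z||^2 + a1*||v||_1 + a2 * sum_{k<l} |v_k - v_l|."""
    v = np.asarray(v, float)
    z = np.asarray(z, float)
    pair = sum(abs(v[i] - v[j]) for i, j in combinations(range(len(v)), 2))
    return 0.5 * np.sum((v - z) ** 2) + a1 * np.sum(np.abs(v)) + a2 * pair


def fused_prox_oracle(z, a1, a2):
    """Solve the fused prox through its dual, a box-constrained least squares.

    The penalty is a support function: a1*|v_k| + a2*|v_i - v_j| =
    max_{|u| <= c} u' G v with G stacking the identity rows (bound a1) and
    the pairwise difference rows (bound a2).  Dualizing the prox gives

        min_u (1/2) || G' u - z ||^2   s.t.  |u_i| <= c_i,

    solved exactly by the BVLS active-set method, and v* = z - G' u*.
    """
    z = np.asarray(z, float)
    K = len(z)
    pairs = list(combinations(range(K), 2))
    G = np.vstack([np.eye(K)] + [
        np.eye(K)[i] - np.eye(K)[j] for i, j in pairs
    ]) if pairs else np.eye(K)
    bounds = np.concatenate([np.full(K, a1), np.full(len(pairs), a2)])
    res = lsq_linear(G.T, z, bounds=(-bounds, bounds), method="bvls", tol=1e-15)
    return z - G.T @ res.x


def jgl_objective(thetas, S, n, lam1, lam2):
    """Negative penalized log-likelihood of the fused joint graphical lasso."""
    K = len(thetas)
    val = 0.0
    for k in range(K):
        th = np.asarray(thetas[k], float)
        sign, logdet = np.linalg.slogdet(th)
        assert sign > 0
        val -= n[k] * (logdet - np.trace(S[k] @ th))
        off = th - np.diag(np.diag(th))
        val += lam1 * np.sum(np.abs(off))
    for k in range(K):
        for l in range(k + 1, K):
            val += lam2 * np.sum(np.abs(np.asarray(thetas[k]) - np.asarray(thetas[l])))
    return float(val)
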