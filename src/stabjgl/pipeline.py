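"""End-to-end orchestration of the two-step penalty selection, plus file I/O.

The full procedure is: (i) select the sparsity penalty lambda1 by stability
under subsampling with the similarity penalty held at a small fixed value;
(ii) select the similarity penalty lambda2 by the multi-network extended BIC
with lambda1 fixed at the value from step (i); then refit the fused joint
graphical lasso on the full data at the selected pair and call edges.  A
reverse-order flag (exploratory) swaps the two steps: lambda2 is selected
first at a fixed lambda1, then lambda1 by stability with that lambda2 held
fixed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .solver import (
    DEFAULT_ZERO_TOL,
    GraphSet,
    PenaltyPair,
    PrecisionSet,
    empirical_covariance,
    fit_jgl,
    graph_from_precision,
)
from .stability import (
    DEFAULT_LAMBDA1_GRID,
    StabilityConfig,
    StabilityProfile,
    lambda1_profile,
)
from .similarity import (
    DEFAULT_LAMBDA2_GRID,
    SimilarityProfile,
    select_lambda2,
)

__all__ = ["StabJGLConfig", "StabJGLResult", "run_stabjgl", "read_matrix", "write_outputs"]

logger = logging.getLogger("stabjgl")


@dataclass
class StabJGLConfig:
    """All tunables of the two-step procedure, with the standard defaults."""

    lambda1_grid: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDA1_GRID.copy())
    lambda2_grid: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDA2_GRID.copy())
    lambda2_fixed: float = 0.01  # lambda2 held here during the stability step
    n_subsamples: int = 20
    beta1: float = 0.1
    gamma: float = 0.0
    seed: int = 0
    workers: int = 1
    standardize: bool = True
    zero_tol: float = DEFAULT_ZERO_TOL
    tol: float = 1e-5
    max_iter: int = 500
    step: float = 1.0
    subsample_sizes: list | None = None
    reverse_order: bool = False
    lambda1_fixed: float = 0.1  # lambda1 held here during a reverse-order lambda2 step

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lambda1_grid"] = np.asarray(self.lambda1_grid).tolist()
        d["lambda2_grid"] = np.asarray(self.lambda2_grid).tolist()
        return d


@dataclass
class StabJGLResult:
    lambda1: float
    lambda2: float
    precisions: PrecisionSet
    graphs: GraphSet
    stability: StabilityProfile
    similarity: SimilarityProfile
    config: StabJGLConfig
    feature_names: list
    runtime_seconds: float


def _validate_data(X, feature_names):
    X = [np.asarray(x, dtype=float) for x in X]
    if not X:
        raise ValueError("need at least one data matrix")
    p = X[0].shape[1]
    for k, x in enumerate(X):
        if x.ndim != 2 or x.shape[1] != p:
            raise ValueError(f"group {k}: expected a 2-d matrix with {p} columns")
        bad = np.argwhere(~np.isfinite(x))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"group {k} has {len(bad)} missing/non-finite value(s), first at "
                f"row {i}, column {j}; impute missing data before fitting"
            )
    if feature_names is None:
        feature_names = [f"V{i + 1}" for i in range(p)]
    elif len(feature_names) != p:
        raise ValueError("feature_names length must match the number of columns")
    return X, list(feature_names)


def run_stabjgl(X, config: StabJGLConfig | None = None, feature_names=None, **overrides) -> StabJGLResult:
    """Run the full two-step procedure and return the fitted networks.

    ``X`` is a list of K (samples x features) matrices over the same
    features.  K=1 is permitted and reduces to a stability-selected single
    network (the lambda2 grid collapses to {0}).  Fully reproducible from
    ``config.seed`` and independent of ``config.workers``.
    """
    if config is None:
        config = StabJGLConfig(**overrides)
    elif overrides:
        raise TypeError("pass either config or keyword overrides, not both")
    X, feature_names = _validate_data(X, feature_names)
    K = len(X)
    t0 = time.perf_counter()

    lambda2_grid = np.asarray(config.lambda2_grid, dtype=float)
    if K == 1:
        lambda2_grid = np.array([0.0])

    solver_kw = dict(tol=config.tol, max_iter=config.max_iter, step=config.step)

    def stability_step(lambda2_fixed: float) -> StabilityProfile:
        cfg = StabilityConfig(
            lambda1_grid=config.lambda1_grid,
            lambda2_fixed=lambda2_fixed if K > 1 else 0.0,
            n_subsamples=config.n_subsamples,
            beta1=config.beta1,
            subsample_sizes=config.subsample_sizes,
            seed=config.seed,
            workers=config.workers,
            standardize=config.standardize,
            zero_tol=config.zero_tol,
            **solver_kw,
        )
        return lambda1_profile(X, cfg)

    def similarity_step(lambda1: float) -> SimilarityProfile:
        return select_lambda2(
            X, lambda1, lambda2_grid=lambda2_grid, gamma=config.gamma,
            standardize=config.standardize, zero_tol=config.zero_tol, **solver_kw,
        )

    if config.reverse_order and K > 1:
        logger.info("step 1 (reverse order): selecting lambda2 by eBIC at lambda1=%.4g",
                    config.lambda1_fixed)
        similarity = similarity_step(config.lambda1_fixed)
        logger.info("selected lambda2=%.4g; step 2: stability search for lambda1",
                    similarity.selected_lambda2)
        stability = stability_step(similarity.selected_lambda2)
    else:
        logger.info("step 1: stability search for lambda1 over %d grid points, "
                    "%d subsamples", len(config.lambda1_grid), config.n_subsamples)
        stability = stability_step(config.lambda2_fixed)
        logger.info("selected lambda1=%.4g; step 2: eBIC search for lambda2 over "
                    "%d grid points", stability.selected_lambda1, len(lambda2_grid))
        similarity = similarity_step(stability.selected_lambda1)

    lam1 = stability.selected_lambda1
    lam2 = similarity.selected_lambda2
    logger.info("final fit at lambda1=%.4g, lambda2=%.4g", lam1, lam2)
    cov = empirical_covariance(X, standardize=config.standardize, feature_names=feature_names)
    precisions = fit_jgl(cov, PenaltyPair(lam1, lam2), **solver_kw)
    graphs = graph_from_precision(precisions, zero_tol=config.zero_tol)
    return StabJGLResult(
        lambda1=lam1,
        lambda2=lam2,
        precisions=precisions,
        graphs=graphs,
        stability=stability,
        similarity=similarity,
        config=config,
        feature_names=feature_names,
        runtime_seconds=time.perf_counter() - t0,
    )


def read_matrix(path):
    """Read a samples-x-features TSV/CSV with a header row of feature names.

    Returns ``(matrix, feature_names)``.  Missing or non-numeric cells are
    rejected with their row/column coordinates.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    names = [str(c) for c in df.columns]
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = int(bad[0]) if len(bad) else int(df.index[df[col].isna()][0])
            raise ValueError(
                f"{path}: non-numeric value in column '{col}', data row {row + 1}"
            )
    na = np.argwhere(df.isna().to_numpy())
    if na.size:
        i, j = na[0]
        raise ValueError(
            f"{path}: missing value at data row {i + 1}, column '{names[j]}'; "
            "impute missing data before fitting"
        )
    return df.to_numpy(dtype=float), names


def write_outputs(result: StabJGLResult, out_dir) -> None:
    """Write edge lists, adjacency matrices, profiles and a parameter JSON.

    Per group: ``edges_group{k}.tsv`` (node_i, node_j, theta_ij,
    partial_correlation) and ``adjacency_group{k}.tsv``.  Across groups:
    ``common_edges.tsv`` (edges present in every group).  Diagnostics:
    ``stability_profile.tsv``, ``similarity_profile.tsv`` and
    ``parameters.json`` (selected penalties, sparsities, resolved config).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = result.feature_names
    K = result.graphs.K
    for k in range(K):
        th = result.precisions.theta[k]
        rows = []
        for i, j in sorted(result.graphs.edge_sets[k]):
            rho = -th[i, j] / np.sqrt(th[i, i] * th[j, j])
            rows.append((names[i], names[j], th[i, j], rho))
        pd.DataFrame(
            rows, columns=["node_i", "node_j", "theta_ij", "partial_correlation"]
        ).to_csv(out / f"edges_group{k + 1}.tsv", sep="\t", index=False)
        pd.DataFrame(
            result.graphs.adjacency[k].astype(int), index=names, columns=names
        ).to_csv(out / f"adjacency_group{k + 1}.tsv", sep="\t")
    common = set.intersection(*[set(e) for e in result.graphs.edge_sets])
    pd.DataFrame(
        [(names[i], names[j]) for i, j in sorted(common)], columns=["node_i", "node_j"]
    ).to_csv(out / "common_edges.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "lambda1": result.stability.lambda1_grid,
            "d_hat": result.stability.d_total,
            "d_mono": result.stability.d_mono,
            **{
                f"d_group{k + 1}": result.stability.d_per_group[:, k]
                for k in range(K)
            },
        }
    ).to_csv(out / "stability_profile.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"lambda2": result.similarity.lambda2_grid, "ebic": result.similarity.scores}
    ).to_csv(out / "similarity_profile.tsv", sep="\t", index=False)
    params = {
        "lambda1": result.lambda1,
        "lambda2": result.lambda2,
        "sparsity": [float(s) for s in result.graphs.sparsity],
        "n_edges": [len(e) for e in result.graphs.edge_sets],
        "converged": result.precisions.converged,
        "runtime_seconds": result.runtime_seconds,
        "config": result.config.to_dict(),
    }
    with open(out / "parameters.json", "w") as fh:
        json.dump(params, fh, indent=2)
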