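# Methods

## Model and estimator

Each group k = 1..K contributes nₖ i.i.d. observations of the same p
variables, assumed zero-mean multivariate Gaussian with precision matrix
Θ(k). Edges of group k's conditional-independence graph are the non-zero
off-diagonal entries of Θ(k). The joint estimator maximizes the penalized
log-likelihood with the fused penalty: an L1 term with weight λ₁ on every
off-diagonal entry of every Θ(k), and an L1 term with weight λ₂ on every
entry (diagonal included) of every pairwise difference Θ(k) − Θ(k′). The λ₂
term encourages not only similar edge patterns but similar entry values
across groups.

**Likelihood weighting.** Each group's log-likelihood enters with weight
wₖ = 1 by default rather than nₖ. The two conventions differ only by a
rescaling of (λ₁, λ₂), but the unweighted form keeps the penalties on the
familiar per-observation graphical-lasso scale, so the standard grids
(λ₁ ∈ [0.01, 1], λ₂ ∈ [0, 0.1]) are meaningful regardless of sample size and
a correlation-matrix input admits a single grid across problems. Weighting by
nₖ is available via `fit_jgl(..., weights="sample_size")`. Sample covariances
use the unbiased 1/(n−1) divisor; by default columns are standardized so
S(k) is a correlation matrix (penalties are scale-sensitive; disable with
`standardize=False` if the variables share units).

## ADMM solver

The problem is split as likelihood + penalty with consensus constraint
Θ = Z and scaled duals U, fixed step ρ (default 1; no adaptive residual
balancing, keeping runs deterministic):

* **Likelihood step** (per group): minimize wₖ[tr(SΘ) − log det Θ] +
  (ρ/2)‖Θ − (Z−U)‖²; closed form via eigendecomposition of
  (ρ(Z−U) − wₖS)/ρ with the strictly positive eigenvalue map
  d ↦ (d + √(d² + 4wₖ/ρ))/2, so every iterate is symmetric positive
  definite.
* **Penalty step** (per matrix entry): a K-dimensional proximal problem
  ½‖v−z‖² + a₁‖v‖₁ + a₂Σ_{k<k′}|vₖ−vₖ′| with a₁ = λ₁/ρ (0 on the diagonal)
  and a₂ = λ₂/ρ. It is solved exactly: the fusion-only problem first (for
  K = 2 the closed form — fuse to the mean when the gap is ≤ 2a₂, otherwise
  move both ends by a₂; for K ≥ 3 exhaustive enumeration of the 2^(K−1)
  contiguous block partitions of the sorted coordinates, exact because the
  proximal map preserves coordinate order), then entrywise soft-thresholding
  by a₁, which is exact because the fusion term depends only on differences.
  Enumeration favors correctness over asymptotic speed; K is small (≤ ~10)
  in the intended applications. The tests verify the operator against an
  independent oracle (the dual of the prox is a box-constrained least-squares
  problem solved by an active-set method).
* **Convergence**: stop when max over groups of ‖Θ−Z‖_max (primal) and
  ρ‖Z−Z_prev‖_max (dual) both fall below 1e-5, capped at 500 iterations
  (warning, not error, on exhaustion). Non-finite residuals raise
  immediately. Fits along a penalty grid are warm-started from the
  neighbouring grid point; this affects only iteration counts, not solutions
  beyond the tolerance.

**Edge calling.** Exact zeros live in the split variable Z; the reported,
symmetrized Θ̂ carries entries up to the tolerance away from zero, so edges
are |θ̂ᵢⱼ| > zero_tol with zero_tol = 1e-5 (strict inequality; entries at the
threshold are not edges). The eBIC/AIC edge counts use the same rule so all
reported scores are reproducible from the outputs.

## Penalty selection

**Step 1, λ₁ (stability).** Subsamples are drawn without replacement, once,
and reused across the whole λ₁ grid (drawing per grid point would add
Monte-Carlo noise between neighbouring grid values); λ₂ is held at 0.01. Edge
selection frequencies ψ across the default 20 subsamples give instabilities
ξ = 2ψ(1−ψ), per-graph variability D̂(k) (mean over the C(p,2) node pairs),
and total variability D̂ (mean over groups). D̂ is monotonized from the sparse
end and the smallest grid value with D̄ ≤ β₁ = 0.1 is selected. If no grid
point qualifies, the largest grid value (sparsest model) is returned with a
warning. Subsample sizes follow the stability-selection rule bₖ = ⌊10√nₖ⌋
when nₖ > 144 and bₖ = ⌊0.8nₖ⌋ otherwise (capped at nₖ−1): near n ≈ 100 the
10√n rule returns almost the full sample, subsamples become near-copies and
the variability signal collapses, so the 80% fallback standard in stability
selection is used there. Replicates can run in parallel (joblib); replicate
seeds and aggregation order are fixed, so results are bit-identical across
worker counts.

**Step 2, λ₂ (extended BIC).** With λ₁ = λ̂₁, the model is refit on the full
data over the λ₂ grid and BIC_γ = Σₖ[nₖtr(S(k)Θ̂(k)) − nₖ log det Θ̂(k) +
|Eₖ| log nₖ + 4|Eₖ|γ log p] is minimized, ties toward smaller λ₂ (less
coupling). γ defaults to 0: the criterion judges coupling between models of
essentially fixed sparsity, so the extra high-dimensionality penalty matters
little. The grid includes λ₂ = 0 so the uncoupled model competes. A
`reverse_order` flag (exploratory) selects λ₂ first, at a user-fixed λ₁,
then runs the stability step with that λ₂.

K = 1 degenerates gracefully: the λ₂ grid collapses to {0} and the procedure
reduces to stability-selected single-network graphical lasso.

## Synthetic scenarios

The generator emulates the benchmark conditions the selection procedure is
designed for:

* **Graphs**: preferential-attachment trees (one edge per incoming node), so
  exactly p−1 edges, sparsity 2/p, heavy-tailed degrees (hubs). For partial
  overlap, round(f·|E|) base edges form a protected core kept in every
  group; the rest are rewired independently per group, uniformly over vacant
  non-core pairs, preserving |E|. Realized pairwise overlap is validated
  against f with tolerance 0.05 + 2/p + 4 binomial standard deviations (the
  2/p term is the expected chance overlap of independently rewired edges —
  a strict ±0.05 band is stochastically violated at f = 0 even at p = 100)
  and stored in the scenario for auditability.
* **Precision matrices**: built directly on the partial-correlation scale
  with unit diagonal and θᵢⱼ = −ρᵢⱼ, magnitudes uniform in [0.1, 0.2] with
  random signs, so edge partial correlations land in the target range
  *exactly* and non-edges are exactly zero (an earlier design — diagonal
  dominance followed by rescaling — achieves the range only approximately).
  Positive definiteness is checked by eigendecomposition; on the rare
  violation, magnitudes shrink by 10% steps floored at the lower bound
  (bounded rounds, deterministic). Shared edges carry the same signed value
  in every group, so a shared edge is the same association, not merely the
  same support.
* **Data**: i.i.d. Gaussian rows via the Cholesky factor of Θ⁻¹, seeded.

What the generator does **not** emulate: non-Gaussian margins, missing
values, batch effects, measurement noise, or graphs denser/more clustered
than trees. Benchmarks passing here show correct mechanics and sensible
selection behavior under the model's own assumptions, not performance on
real omics data (where transformation to approximate normality and
imputation are the user's responsibility — the pipeline rejects missing
values rather than guessing).

## Benchmark sizes and observed behavior

The packaged benchmarks are scaled-down: K = 2, p = 40, n = (100, 150),
20 replicates for sparsity recovery against the AIC-tuned fused baseline and
10 replicates for similarity adaptation, with replicate seeds spawned from a
fixed master seed. At this scale the two-step selection recovers the true
sparsity 0.05 within a factor ~1.4 in the median and beats joint AIC tuning
on both precision and recall; the adaptation of λ₂ to the true sharing level
is directionally correct but noisy, because the eBIC partially rewards the
sparsification that fusing unrelated networks induces (fused group-specific
edges vanish, cutting the |Eₖ| log nₖ term) — an inherent property of the
criterion that is much weaker when the networks truly share structure.

## Numerical conventions

* Precision/recall use the convention 0/0 = 1 (an empty estimate of an empty
  graph is perfect; against a non-empty truth it has precision 1, recall 0).
* Pairwise shared-edge fraction uses |E₁∩E₂|/max(|E₁|,|E₂|) — symmetric and
  conservative.
* eBIC requires positive-definite estimates (log det via `slogdet`); the
  solver guarantees this by construction.
* All randomness flows through integer seeds and `numpy.random.default_rng`;
  derived seeds come from `SeedSequence.spawn`, keeping results independent
  of parallel scheduling.

## Known limitations

* The exact fused proximal enumeration costs 2^(K−1) candidate evaluations
  per entry; beyond K ≈ 15 a path-algorithm implementation would be needed.
* λ̂₁ and λ̂₂ are grid values; reported penalties are only as fine as the
  grids (20 points by default).
* Group-specific λ₁,ₖ or pair-specific λ₂,ₖₗ penalties are not implemented.
* The AIC baseline exists for comparison studies, not as a recommended
  tuning method.
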