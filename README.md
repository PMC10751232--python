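# stabjgl

Joint estimation of multiple sparse Gaussian graphical models with
stability-selected sparsity and likelihood-selected similarity penalties.

## The problem

Given K related datasets measured over the same p variables — say proteomic
profiles from K tumor types — each group's conditional-independence network is
encoded by the zeros of its precision matrix Θ(k) = Σ(k)⁻¹: variables i and j
are conditionally independent given the rest exactly when θᵢⱼ(k) = 0, and the
strength of an edge is the partial correlation ρᵢⱼ = −θᵢⱼ/√(θᵢᵢθⱼⱼ). When the
groups are biologically related, estimating the K networks jointly borrows
strength across them. The fused joint graphical lasso does this by maximizing

    Σₖ wₖ [ log det Θ(k) − tr(S(k) Θ(k)) ]
      − λ₁ Σₖ Σ_{i≠j} |θᵢⱼ(k)|  −  λ₂ Σ_{k<k'} ‖Θ(k) − Θ(k')‖₁

where S(k) is the sample correlation (or covariance) matrix of group k. λ₁
controls how sparse each network is; λ₂ shrinks corresponding entries of the
K precision matrices toward each other.

The difficulty in practice is choosing (λ₁, λ₂). Likelihood criteria such as
the AIC tend to drastically over- or under-select edges in high dimensions.
This package selects the two penalties in two steps:

1. **λ₁ by multi-network stability.** Draw repeated subsamples from every
   group, refit the joint model over a λ₁ grid (λ₂ held small), and record for
   each edge the selection frequency ψ. The edge's instability is
   ξ = 2ψ(1−ψ) ∈ [0, 0.5]; averaging ξ over node pairs and groups gives the
   total variability D̂(λ₁), which is monotonized from the sparse end,
   D̄(λ₁) = sup_{t≥λ₁} D̂(t). The selected λ̂₁ is the smallest grid value with
   D̄ ≤ β₁ (default β₁ = 0.1): the least penalization whose graphs are
   reproducible to within 10% edge-assignment variability.
2. **λ₂ by a multi-network extended BIC.** With λ₁ = λ̂₁ fixed, refit on the
   full data over a λ₂ grid and minimize

       BIC_γ = Σₖ [ nₖ tr(S(k)Θ̂(k)) − nₖ log det Θ̂(k) + |Eₖ| log nₖ
                    + 4 |Eₖ| γ log p ]

   (γ = 0 by default, the ordinary BIC). Since λ₁ already fixed the sparsity
   level, this compares models of similar size and only has to judge how much
   coupling the data support.

The final networks are the fused joint graphical lasso fit at (λ̂₁, λ̂₂),
solved by ADMM with an exact closed-form proximal step for the fused penalty.

The package also ships a synthetic benchmark generator (scale-free true
graphs with sparsity 2/p, edge partial correlations in [0.1, 0.2], a
controllable fraction of edges shared between groups, Gaussian samples) and
recovery metrics (precision, recall, sparsity, pairwise edge overlap).

## Worked example

```python
import stabjgl as sj

# two groups, 40 nodes, identical scale-free true graphs (sparsity 2/40 = 0.05)
scn = sj.make_scenario(K=2, p=40, n=(100, 150), fraction_shared=1.0, seed=7)

res = sj.run_stabjgl(scn.data, seed=7)
print(f"selected lambda1 = {res.lambda1:.3f}, lambda2 = {res.lambda2:.4f}")

report = sj.evaluate_result(res.graphs, scn.true_graphs, res.lambda1, res.lambda2)
print(f"estimated sparsity: {[round(s, 4) for s in report.sparsity]} (truth 0.05)")
print(f"precision: {[round(v, 3) for v in report.precision]}")
print(f"recall:    {[round(v, 3) for v in report.recall]}")
print(f"edges shared between the two estimates: {report.shared_fraction[0]:.3f}")
```

prints

```
selected lambda1 = 0.166, lambda2 = 0.1000
estimated sparsity: [0.0385, 0.0321] (truth 0.05)
precision: [0.567, 0.64]
recall:    [0.436, 0.41]
edges shared between the two estimates: 0.833
```

The stability step lands close to the true sparsity (0.032–0.038 vs 0.05), a
majority of called edges are real, and — because the true graphs are
identical and the eBIC step selected a large λ₂ — the two estimated networks
agree on 83% of their edges.

The same pipeline is available from the shell:

```sh
stabjgl simulate --k 2 --p 40 --n 100,150 --shared 1.0 --seed 7 --out sim/
stabjgl fit sim/data_group1.tsv sim/data_group2.tsv --out fit/ --seed 7
stabjgl evaluate --truth sim/true_edges.tsv --est fit/
```

`fit` accepts TSV/CSV matrices (samples × features, header row of feature
names; missing values are rejected — impute first) and writes per-group edge
lists with partial correlations, adjacency matrices, the list of edges common
to all groups, the variability and eBIC profiles, and a parameter JSON.

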