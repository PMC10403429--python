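# netsgcca

Sparse Generalized Canonical Correlation Analysis with a graph-Laplacian
(GraphNet) penalty, for multiblock / multiomics integration with prior
interaction networks.

## The problem

Given J paired data blocks X₁,…,X_J (n samples × p_j features — e.g. CNV,
mRNA and miRNA measured on the same patients), SGCCA finds per-block weight
vectors w_j whose latent components t_j = X_j w_j maximally covary:

    minimise   Σ_{j≠k} −c_{jk} · cov(X_j w_j, X_k w_k)
    subject to ‖w_j‖₂ ≤ 1  and  ‖w_j‖₁ ≤ s_j   for every block,

where c is a user-chosen 0/1 block design and the ℓ1 radii s_j control
sparsity.  The ℓ1 penalty alone tends to pick a few representatives of each
correlated group, which is unstable and hard to interpret biologically.
netSGCCA adds a GraphNet penalty on one designated block X_g, built from
the Laplacian L_g of a prior feature-interaction graph (e.g. gene–gene
interactions):

    … + (γ_G / λ_max) · w_gᵀ L_g w_g,

with λ_max the largest Laplacian eigenvalue.  Since w_gᵀ L_g w_g ≤ λ_max
whenever ‖w_g‖₂ ≤ 1, this scaling makes γ_G comparable across graphs of
different density.  The penalty smooths weights over graph neighbours, so
whole interacting modules are selected instead of isolated features.

The optimizer updates blocks cyclically; each block solve is FISTA with
backtracking, projecting onto the intersection of the ℓ1 and ℓ2 balls with
Dykstra's algorithm (which converges to the *nearest* feasible point,
unlike plain alternating projections).

Around the model, the package provides the full interrogation protocol:

- graph handling: edge-list/SIF loading, alignment to a block's feature
  list, raw/normalized Laplacians, λ_max via sparse eigensolver;
- graph probes: label permutation, random/inner/outer/isolating edge
  removal, degree/weight/distance analyses;
- stability: subsample ("bootstrap without replacement") refits, pairwise
  Dice and chance-corrected nPOG, selection frequencies;
- survival: a null-deviance-residual pseudo-block for training, Cox-model
  evaluation of the components with Harrell's c-index;
- a synthetic-data generator with graph-derived covariance and known
  ground-truth support, so every stage is testable without downloads.

## Worked example

```python
import numpy as np
from netsgcca import (NetSGCCA, GraphPenaltyConfig, SyntheticSpec,
                      simulate_two_block, recovery_metrics)

ds = simulate_two_block(SyntheticSpec(seed=1))   # n=100, p1=200, p2=100
penalty = GraphPenaltyConfig(target_block="block1", gamma=10.0,
                             laplacian_variant="normalized")
model = NetSGCCA(ds.blocks, sparsity=[2.0, 2.0],
                 penalty=penalty, graph=ds.graph)
res = model.fit()
print(res.summary())
print(recovery_metrics(res.selected("block1"), ds.truth))
```

prints

```
netSGCCA fit
============================================================
blocks: 2   samples: 100   components: 1
component 1: objective -2.88454 (4 outer iterations, converged: yes)
------------------------------------------------------------
block                p       s   gamma  selected
block1             200       2      10        13
block2             100       2       0         6

{'precision': 0.7692307692307693, 'recall': 1.0,
 'f1': 0.8695652173913044, 'n_selected': 13, 'n_truth': 10}
```

The dataset hides a 10-feature support on one community of the prior
graph; with the penalty the model selects 13 features covering all 10 true
ones (recall 1.0).  The same data fitted with `gamma=0` (plain SGCCA)
selects 8 features and misses two of the support.  The objective is the
summed negative covariance plus the scaled penalty; the trace is
guaranteed non-increasing.

A command-line interface mirrors the library
(`netsgcca fit | sweep-gamma | graph-probe | degree-analysis |
survival-eval | simulate | stability`); see `netsgcca --help` and the
config schema in `netsgcca/cli.py`.

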