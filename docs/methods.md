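# Methods

## Model

netSGCCA estimates per-block weight vectors w_j for J paired, column-centred
data blocks X_j (n × p_j) by minimising

    f(w) = Σ_{j≠k} −c_{jk} cov(X_j w_j, X_k w_k) + (γ_G/λ_max) w_gᵀ L_g w_g

subject to ‖w_j‖₂ ≤ 1 and ‖w_j‖₁ ≤ s_j for every block.  The double sum
runs over ordered pairs, so each linked pair of blocks contributes twice;
cov uses the 1/n denominator (a pure rescaling of the objective, fixed for
reproducibility).  L_g is the Laplacian of a prior interaction graph over
the features of one designated block; γ_G ≥ 0 sets the penalty strength.
Dividing by the largest Laplacian eigenvalue λ_max bounds the penalty by
γ_G on the feasible set (w ᵀLw ≤ λ_max‖w‖₂²), making γ_G comparable across
graphs of different density.  The API accepts a list of penalty
configurations (one per block) and sums the terms, though one penalized
block is the standard use.

The ℓ2 constraint is the inequality (ball) form: interior points are left
untouched by the projection.  For the covariance part of the objective the
constraint is active at any optimum whenever s_j permits ‖w‖₂ = 1, so this
coincides with the sphere form in practice while keeping every constraint
set convex.

Feasibility of the ℓ1/ℓ2 pair requires 1 ≤ s_j ≤ √p_j; values outside this
interval are rejected rather than clipped, since they are almost always a
configuration error (an s_j > √p_j is inert).

## Optimisation

Blocks are updated cyclically.  With all other blocks fixed, the smooth
objective restricted to w_j is linear (cross-covariance) plus, on the
penalized block, a convex quadratic.  Each block solve is FISTA:

- initial step size 1/(2γ_G) on a penalized block (the quadratic's
  Hessian 2(γ_G/λ_max)L has spectral norm at most 2γ_G after the λ_max
  scaling) and 1.0 otherwise, halved under backtracking until the standard
  majorization inequality holds; a step below 1e−16 raises;
- each iterate is projected onto the intersection of the ℓ1 ball (radius
  s_j) and the unit ℓ2 ball with Dykstra's alternating projection with
  correction terms.  The single-set ℓ1 projection uses the exact
  sort-based threshold (deterministic under ties); the stopping rule is
  the change in the correction terms (the iterate alone can stall for a
  few cycles early on), default tolerance 1e−8, cap 1000 cycles, with a
  warning and an ℓ1-feasibility enforcement on cap overrun;
- FISTA iterates are not monotone, so the block update returns the best
  iterate seen (including the start).  This makes the outer objective
  trace non-increasing by construction; an increase beyond 1e−9 relative
  slack raises an error.

Outer convergence is declared when the relative objective change over one
full cyclic pass falls below `outer_tol` (default 1e−6, cap 200 passes);
the inner FISTA stops on iterate change below 1e−8 or 100 iterations.
Desk-scale experiment harnesses in the tests and the acceptance script use
reduced caps (outer 60 passes at tol 1e−5, inner 40 iterations at 1e−7)
— problem sizes and caps chosen so a fit takes a fraction of a second at
n = 100, p = 200+100 while all feasibility guarantees (which depend on the
Dykstra tolerance, kept at its default) are preserved.

Initialisation is the first right singular direction of each block
(deterministic, with a fixed sign convention), projected to feasibility;
a seeded random-unit-vector fallback exists.  Because the objective is
invariant under a global sign flip of all w_j, each component is
canonicalised so the largest-magnitude entry of the first block's weights
is positive.

Additional components are extracted by block-wise deflation
X_j ← X_j − t_j (t_jᵀ t_j)⁻¹ t_jᵀ X_j with t_j the block's own score.  The
deflation loadings are stored so `transform` can replay centring, scaling
and deflation on new data; a block whose component is numerically zero is
left undeflated.  How many components are meaningful is data-dependent;
the default is 1.

A feature is *selected* when |w| > 1e−8 (configurable).  The ℓ1 projection
produces exact zeros, so this threshold only guards against the tiny
nonzeros Dykstra can leave at convergence boundaries.

## Graphs and Laplacians

Prior graphs are undirected and simple; self-loops and duplicate/reversed
edge lines are dropped at load time (edge list or SIF).  Alignment to a
block makes the node set exactly the block's feature list, in order:
features missing from the graph become isolated nodes, features sharing a
graph label receive copies of that node's edges, and unmatched graph nodes
are dropped.

Raw Laplacian L = D − A; normalized L = I − D^(−1/2) A D^(−1/2) on
non-isolated nodes.  Isolated nodes get all-zero rows and columns in
*both* variants, so the penalty is inert on features absent from the
prior knowledge (a unit diagonal would instead impose a spurious ridge on
exactly the features we know nothing about).  Edge weights are accepted
(weighted degrees); default weight 1.  λ_max is computed densely below 500
nodes and by a Lanczos sparse eigensolver (relative tolerance 1e−6) above,
and cached.  An edgeless aligned graph has λ_max = 0, which makes the
scaled penalty undefined: combined with γ_G > 0 this is an error telling
the user to set γ_G = 0.

Graph distances are unweighted shortest paths (BFS) — the supported prior
graphs are unweighted; if weighted graphs are supplied, weighted shortest
paths are used instead.

## Stability and metrics

Resampling draws ⌊0.85·n⌋ samples *without replacement* per run
("bootstrap" is kept as the field's customary term), optionally stratified
(floor per stratum, largest-remainder top-up to the global count), with
child seed = base seed + run index so any single run is reproducible in
isolation.

Dice = 2|A∩B|/(|A|+|B|), with two empty selections defined as perfectly
agreeing (1, logged).  nPOG is the chance-corrected overlap
(O − E)/(O_max − E) with O = |A∩B|, E = |A||B|/p and O_max = min(|A|,|B|);
its expectation under independent uniform selections is 0 and its maximum
is 1; the degenerate O_max = E case returns 1.  The exact normalization in
the literature varies; this form is isolated in one function and pinned by
a permutation-oracle test.

## Survival

The survival outcome enters training as a one-column pseudo-block of null
deviance residuals: with the Nelson–Aalen cumulative hazard Λ̂ (tied event
times share their at-risk set, i.e. Breslow-style — the main alternative,
Efron weighting, differs only at ties and is not implemented), the
martingale residual is M_i = δ_i − Λ̂(t_i) and

    d_i = sign(M_i) √(−2[M_i + δ_i log(δ_i − M_i)]),

with δ log(·) = 0 for censored subjects.  The residual block is connected
to every data block and used only during training; at transform time the
omics blocks alone are scored.  All-censored data are rejected (the
residual block would be constant).  Evaluation fits a proportional-hazards
model (delegated to lifelines) on the training components and reports
Harrell's c-index — comparable pairs are (i, j) with t_i < t_j and
δ_i = 1, tied risks count 1/2 — on training ("validation") and held-out
sets.  Exactly collinear component matrices make the Cox fit fail; the
error carries the condition number and a `penalizer` option is the
documented escape hatch.

## Synthetic data generator

The generator emulates graph-structured two-block data with a known
ground truth.  Defaults (the study conditions for all shipped analyses):
n = 100 samples; block 1 with p₁ = 200 features over a 20-community graph
(10 nodes per community, within-community edge probability 0.8, between
0.01); block 2 with p₂ = 100 features; a 10-feature support placed on one
connected community (a scattered mode exists); latent strength 1.0; noise
SD 1.0.

A latent factor u ~ N(0,1) drives the support features of block 1
(strength × u plus noise correlated according to the graph covariance
restricted to the support) and 10 features of block 2 (plus independent
noise).  The graph covariance is the regularized Laplacian inverse
(L + εI)⁻¹ rescaled to unit diagonal (ε = 0.1): graph proximity then
implies correlation, which is precisely the structure the penalty is meant
to exploit.  Survival times are exponential with hazard exp(risk), with
uniform censoring whose upper bound is tuned by root finding to hit the
requested censoring fraction in expectation.

Two consequences of this design are worth knowing.  First, a connected
support shares a common noise factor whose strength grows as ε shrinks;
with ε = 0.1 the within-support correlation is high, which caps the
achievable correlation between any block-1 component and the latent factor
well below 1 (block-2 components, whose noise is independent, do reach
≈0.95).  Second, even with no latent signal, a community-placed support
remains *mechanically* favoured by the model, because the model selects
correlated groups — that is its design, not an artefact; the null-signal
check therefore uses the scattered-support mode, where the support carries
no correlation marking.  What passing tests on these data show is that the
solver, penalty, probes and survival stages behave as specified on
Gaussian, module-structured data; they do not certify behaviour on real
omics marginals (counts, segment-level CNV, heavy tails), on graphs with
the size/degree profile of full interactome databases, or when multiple
uncorrelated supports exist.

## Known limitations

- Binary blocks (mutations) are out of scope; inputs must be numeric and
  complete-case (no imputation).
- Deflation-based multi-component extraction is one convention among
  several; component orthogonality holds within blocks but cross-block
  properties are not guaranteed.
- The γ_G grid search and the s_j grid search harnesses are provided, but
  no automatic hyperparameter selection is performed by default.
- Very slowly converging Dykstra instances (near-degenerate geometry) fall
  back to the last iterate with an ℓ1 re-projection and a warning.
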