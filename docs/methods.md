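# Methods

## Setting

One server and *n* institutional clients hold drug-response data with a
shared feature space (horizontal, cross-silo federation).  A dataset of
(cell line, drug) pairs with a scalar response is partitioned into
training DT, validation DV and hold-out DH.  The server keeps a small
initial fraction DT(I) of the training pool (default 5%) plus DV; the
remainder DT(−I) is divided among the clients.  All clients participate
in every round; only parameter arrays, sample counts and counter
integers cross the client boundary.

## REFINED feature-to-image mapping

Convolution needs neighbourhood structure, which tabular biomedical
features lack.  The mapping is fitted once, on the server's DT(I) only,
and broadcast with the initial model:

1. **Feature distances.** Columns are standardised (constant columns
   map to zero) and the distance between features i and j is the
   Euclidean distance of their standardised columns scaled by 1/√n, so
   perfectly anti-correlated features sit at distance 2.  A
   `1 − |Pearson r|` alternative is exposed for users who want
   anti-correlated features mapped close together.
2. **Planar embedding.** Metric MDS (SMACOF, classical-scaling
   initialisation, scipy/sklearn) embeds the features in 2D.  The
   embedding is PCA-aligned with fixed sign conventions and uniformly
   rescaled so its larger extent spans the grid — deterministic given a
   seed.
3. **Constrained grid assignment.** Features must occupy distinct cells
   of a g×g grid, g defaulting to ⌈√p⌉ (the smallest square admitting an
   injection).  The assignment minimises the discretisation stress
   Σ<sub>i<j</sub> (d<sub>ij</sub> − grid\_dist<sub>ij</sub>)², where
   d<sub>ij</sub> are the embedding distances.  Search: several
   deterministic snap starts (greedy nearest-free-cell in three feature
   orders, ties broken by lowest (row, col); plus a jointly optimal snap
   via the linear assignment problem; plus, for p ≤ 24, a few seeded
   random starts) each refined by strictly descending hill climbing over
   pairwise swaps and relocations to free cells, with two escape moves
   tried only when a sweep stalls — a chained relocation through a free
   cell, and (p ≤ 24) a 3-cycle rotation.  Within every climb the stress
   is non-increasing; the best final assignment is kept.  On tiny
   instances (p ≤ 6 on a 3×3 grid) the result lands within 10% of the
   exhaustive-search optimum, which the test suite checks against a
   brute-force enumeration oracle.  The original formulation of this
   mapping uses Bayesian MDS for the constrained refinement; the
   deterministic search above deliberately replaces it to keep the
   module seedable and unit-testable while preserving the defining
   constraint that no two features share a cell.

## Deep Regression Forest

A forest of T full binary trees of depth d (defaults T=2, d=4).  Each
tree has 2^(d−1)−1 internal nodes; the extractor's final linear layer
emits one logit per internal node (T·(2^(d−1)−1) outputs, sliced
contiguously per tree, breadth-first within a tree), and a sigmoid turns
each logit into the LEFT-branch probability.  Leaves carry Gaussians
over the (standardised) response, initialised at N(1, 1).

* **Prediction**: P(ℓ|x) is the product of branch probabilities along
  the path; tree prediction Σ P(ℓ|x)μ<sub>ℓ</sub>; forest prediction is
  the mean over trees.
* **Loss**: per-tree mixture NLL −log Σ<sub>ℓ</sub> P(ℓ|x)·N(y; μ<sub>ℓ</sub>, σ<sub>ℓ</sub>²),
  averaged over trees and batch, computed in log-sum-exp form.  The
  gradient w.r.t. the sigmoid outputs uses the subtree recursion
  T<sub>v</sub> = s<sub>v</sub>T<sub>left</sub> + (1−s<sub>v</sub>)T<sub>right</sub>,
  giving ∂m/∂s<sub>v</sub> = π<sub>v</sub>(T<sub>left</sub> − T<sub>right</sub>)
  with π<sub>v</sub> the node arrival probability — division-free and
  stable under saturated routing (sigmoids are clipped to (10⁻⁷, 1−10⁻⁷)
  on the likelihood path).  The unit tests verify it against central
  finite differences.
* **Leaf updates**: with the network frozen, responsibilities
  ξ<sub>iℓ</sub> ∝ P(ℓ|x<sub>i</sub>)·N(y<sub>i</sub>; μ<sub>ℓ</sub>, σ<sub>ℓ</sub>²)
  (row-normalised in log space) feed weighted mean/variance updates.
  This is an EM step on the per-tree mixture, so the training NLL is
  non-increasing across iterations — the property the tests enforce.
  The exact update schedule is not uniquely determined by the
  alternating-optimisation description this design follows; the
  responsibility-weighted form was chosen for its monotonicity
  guarantee.  Defaults: 3 iterations per local epoch; variance floor
  ε = 10⁻⁴ (prevents degenerate Gaussians under hard routing); leaves
  with total responsibility below 10⁻¹² keep their previous parameters.

## Models and the numpy core

No deep-learning framework is used: `feddrf.nn` implements dense
layers, valid 2D convolution (im2col), relu/tanh/sigmoid, and SGD with
momentum, all with hand-written backward passes and parameters exposed
as flat `{name: array}` dicts.  Three model families share this
surface: `ann` (dense on the concatenated flat features), `refined_cnn`
(two-arm CNN on the cell/drug images, squared-error head), and
`refined_drf` (same extractor, forest head).  Defaults: one 3×3
convolution with 4 filters per arm, tanh trunk of widths (32, 16),
batch 32, lr 0.05, momentum 0.9.  The client-baseline preset removes
the last convolution per arm, keeps one hidden layer and uses batch 12,
reflecting how individually trained client models are slimmed down for
their smaller samples.  Optimiser state is reset at each epoch
boundary, which makes a federated round with a single client literally
identical to one centralized epoch (the suite checks bit-for-bit
equality over three rounds).

## Federated loop

Per round: broadcast → each client runs exactly one epoch of local
backprop plus one leaf-update pass → the server scores every client's
updated model on DV *before* aggregation (these trajectories feed the
diagnostic) → data-weighted federated average over every network tensor
and every leaf mean/variance (aggregated variances re-floored; leaf
variances are averaged directly rather than via precisions, consistent
with plain averaging of all parameters) → learning-rate schedule and
early stopping on the aggregated model's DV NRMSE (defaults: lr halved
after 5 non-improving rounds, stop after 10; both configurable).
Aggregation weights default to client sample counts, normalised; empty
clients are skipped with weight 0.  The server pretrains the round-0
model on DT(I) with the same early-stopping machinery and restores the
best-DV parameters.

**Personalized variant.** The head (final linear layer — for the DRF,
the layer emitting the routing logits) is excluded from aggregation;
each client keeps its own copy across rounds.  Because clients hold no
validation data, the per-client "non-improving epoch" counters are
maintained server-side from the per-client DV trajectories it already
records, and their mean drives the learning-rate reduction and early
stopping, matching the averaged-counter stopping rule of the protocol.

## Heterogeneity diagnostic

Given per-client DV-loss trajectories x<sub>t</sub><sup>(j)</sup>,
t = 1..m−1 up to a convergence point m (taken by default as the round
at which the federation stopped; manual override available):

    B   = (m−1)/(n−1) Σ_j (x̄_j − x̄)²
    W_j = 1/(m−2) Σ_t (x_t^(j) − x̄_j)²,  W = mean_j W_j
    R   = (αB + (1−α)W) / W,  α = 1/(m−1)

The ratio orientation was chosen as the only one satisfying both
required limits: R → 1−α ≈ 1 as B → 0 for large m, and R ≫ 1 when
client means separate.  R is scale-invariant in the loss units and
monotone in B for fixed W.  The detection threshold (default 1.5) is a
tool default, not a derived constant.  W = 0 with B > 0 is reported as
+∞ with a warning; the fully degenerate case returns 1−α.

## Synthetic panels

`generate_study` simulates a screening panel over all (cell, drug)
pairs.  Features are block-correlated (shared latent per block with
loadings and feature-level noise), giving the REFINED step genuine
neighbourhoods.  The response is a smooth surface computed directly
from the observable features — a bilinear interaction of tanh
projections of the two arms plus per-arm tanh terms — shifted by a
per-drug offset scaled by `cluster_effect` and observed with Gaussian
noise `noise_sd`.  With zero noise and zero cluster effect the response
is an exact deterministic function of the inputs, and a flexible
reference regressor reaches hold-out NRMSE well under 0.2 (checked in
the tests with an independent sklearn model).  Defaults: 504 cells × 24
drugs (the shape of a familiar public screen), noise\_sd 0.3 relative to
a roughly unit-scale signal, cluster\_effect 1.0 so the drug-cluster
offsets are a leading-order component of the response — strong enough
that disjoint drug allocations create clearly distinct client
populations.  What the generator does *not* emulate: real dose-response
curve structure, assay noise heteroscedasticity, batch effects, or
chemically meaningful drug descriptors — so passing tests demonstrate
the machinery works as specified, not that it attains any particular
accuracy on real screens.

Partitions: `split_random` (IID; DT(I) 5%, DV 10%, DH 10% by default)
and `split_quasi_random` (n clients, k drugs each; k·n = n\_drugs gives
a disjoint cover, larger k samples drug sets randomly and splits shared
drugs' samples evenly).  `permute_targets` implements the corruption
protocol: exactly round(fraction·n) response values permuted among
themselves, preserving the multiset.

## Desk-scale study presets and problem sizes

Two packaged studies power the headline checks and the acceptance
script; their sizes are chosen to exercise the methods end to end on a
single CPU in minutes:

* **Federation benefit** — 10 replicates of a 100-cell × 20-drug panel
  (2 000 samples; 64 cell features → 8×8 images, 25 drug features →
  5×5), 5 IID clients, 20 rounds, against per-client reduced baselines
  trained with a 10% local validation split.
* **Heterogeneity sweep** — 20 replicates × {k=2, k=24} of an 80-cell ×
  24-drug panel with 12 clients and 8 rounds.  The panel is sized so
  each client shard at full overlap is large enough (~120 samples) that
  homogeneous clients produce well-mixed trajectories: with very small
  shards each client's local epoch pulls persistently toward its own
  sample, which inflates B even under IID allocation and would blur the
  diagnostic's homogeneous reading.

## Known limitations

* The convolutional extractor presets are representative, not replicas
  of any published architecture; at desk scale the networks are small.
* Leaf-variance averaging across clients is a pragmatic choice; a
  precision-weighted pooling might behave differently under strongly
  heteroscedastic clients.
* The diagnostic assumes a common convergence window m across clients;
  trajectories of unequal length are truncated to the shortest.
* No secure aggregation, differential privacy, client subsampling or
  vertical partitioning — the privacy guarantee is purely architectural
  (only parameters and counts cross the boundary).
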