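# Methods

This note records the models, numerical choices and design decisions behind
`manifoldmri`, and what the synthetic studies do and do not establish.

## Gaussian class models and the composite geodesic metric

Each class of feature vectors is modelled as i.i.d. draws from a
multivariate Gaussian.  Estimation is maximum likelihood with the biased
`1/N` covariance divisor; a diagonal regularization `ε` (default `1e-5`,
recorded in the fitted object) is added *after* estimation to guarantee
invertibility, which matters whenever the batch size is below the feature
dimension (batch-of-10 fits in 128 dimensions are rank-9 plus `εI`).

Class dissimilarity uses a composite metric: a Mahalanobis term under the
averaged covariance plus the affine-invariant SPD distance
`Σᵢ ln²λᵢ` over the eigenvalues of `Σ₀⁻¹Σ₁`.  The eigenvalues are computed
from the congruent symmetric problem `Σ₀^{-1/2} Σ₁ Σ₀^{-1/2}`
(eigendecomposition square roots, eigenvalue floor `1e-12` before
logarithms) rather than from the non-symmetric product, which is
numerically fragile at `d ≈ 128`: the raw product can return complex or
negative eigenvalues whose logarithms are undefined.  Any non-finite
intermediate yields `+inf` instead of an exception, because the graph
stage explicitly prunes infinite edges.  Consequences of the robust form:

* the metric is exactly symmetric and affine-invariant (both are tested
  against independent oracles — `logm`-Frobenius on SPD pairs, and
  `scipy` Mahalanobis under equal covariances);
* it essentially never returns `+inf` for regularized fits, so infinite-
  edge pruning is a safety valve here, not a routine event.

The KL divergence uses the closed Gaussian form via Cholesky solves; the
Fisher Information Matrix is block-diagonal with `mean_block = Σ⁻¹` and
`cov_block = ½ Σ⁻¹ ⊗ Σ⁻¹`.

## Statistical layer

**Permutation tests.**  The observed statistic is the geodesic distance
between the two group fits; each of `B` permutations re-partitions the
pooled rows into the original group sizes and refits.  `p = #{D ≥
D_obs}/B` exactly — no add-one smoothing, so `p = 0` is reportable; a
`smooth` flag switches to `(count+1)/(B+1)`.  The pooled matrix is sorted
lexicographically before the seeded permutation stream is applied, making
the result invariant to the row order of the inputs.  Calibration under the
null (two groups of 50 from one 5-D Gaussian, `B = 200`, 500 replicates) is
asserted to give an α = 0.05 rejection rate in [0.03, 0.07].  No
multiple-testing correction is applied across class pairs; the tables
report raw p-values.

**Intra-class variability** is the mean Mahalanobis distance of samples to
their own class fit — affine-invariant at `ε = 0`, and equal to the mean of
a χ_d variable for a correctly specified Gaussian (tested at d = 10).

**PGA** centers a class, whitens with the inverse principal square root of
the (regularized) class covariance, and runs PCA on the whitened data.
Exact self-whitening necessarily flattens the spectrum to `1/d` — informative
spectra arise only through regularization or through a covariance other
than the class's own, so the whitening covariance is an explicit parameter
(`cov=np.eye(d)` recovers ordinary PCA).  No claim is made that any default
reproduces a particular published spectrum.

## Synthetic studies

The generator emulates a staged grayscale-MRI dataset: class `k` draws
latents from `N(offset_k·e_k, scale_k·((1−ρ_k)I + ρ_k J))` with defaults
`offsets = (0, 25, 50, 75)`, `scales = (1.0, 1.3, 1.8, 2.5)`,
`ρ = (0, 0.1, 0.2, 0.3)` on 8 latent dimensions — variability and feature
correlation grow with stage.  Offsets sit on distinct latent axes: ReLU
networks can then give every class its own feature direction (collinear
means make hidden features pairwise-collinear and classes collapse by
sign).  The offset scale was calibrated so that the configured ground-truth
class distances (23.5–71.1) match the few-tens scale reported for real
staged MRI data; in within-class standard deviations the separation is
≥ 15 sd, far above the ≥ 5 sd regime the tests target.

Rendering is a fixed affine map: QR-orthonormalized smooth random fields
(Gaussian-filtered white noise, σ = size/8) plus a background template,
with a gain that keeps clipping to [0, 1] a > 4σ event.  Because the map is
affine and injective and the metric is affine-invariant, the latent
geometry survives to pixels, and parameter recovery is testable: fits at
n = 1000/class reproduce configured distances within 10%.

What the synthetic studies do **not** emulate: scanner noise, partial
volume, registration error, nonlinear anatomy-to-intensity effects, or
class overlap.  Pixel covariance has rank = latent_dim, so PCA to 128
components retains trailing components of ~zero variance (harmless — the
`ε` floor dominates them).  Passing tests therefore demonstrate
correctness of the pipeline's mathematics and its behavior in a separable
regime, not performance on real scans.

## Manifold graph

Nodes are batch-level Gaussians (default 300 sampled images per class,
consecutive batches of 10, seeded sampling without replacement).  Pruning
retains edges at or below the 80th linear-interpolation percentile of the
finite weights; infinite weights are always pruned; a Kruskal MST of the
complete graph (infinities replaced by a sentinel above every finite
weight) is merged back, so the output is connected unconditionally.
networkx is used for the MST because scipy's sparse MST treats zero-weight
entries as absent edges, which is wrong for identical manifold points.

Two pruning scopes are exposed, and the choice is consequential:

* `per_class` (default when labels are available): the percentile is
  computed and applied within each class block — each class is its own
  statistical manifold — and only the MST introduces between-class bridges.
  On the default study this yields a 99.8% class-pure graph.
* `global`: one threshold over all pairs.  With K balanced classes only
  1/K of pairs are same-class, so retaining 80% of edges necessarily keeps
  large numbers of cross-class edges no matter how separated the classes
  are (the metric's affine invariance makes this scale-free).  Symmetric
  normalized propagation then collapses class centroids, and measured GCN
  accuracy caps around 0.7–0.9 on the default study.

The per-class default is the package's resolution of an ambiguity in how
such graphs are described in the literature; the global form is retained,
tested, and selectable in config (`graph.prune_scope`).

Node features are the batch mean vectors.  The default GNN adjacency is
binary post-pruning: the GCN normalization treats entries as affinities,
and raw distances would invert semantics (larger weight = farther).  A
Gaussian-kernel mode `exp(−w²/σ̂²)` (σ̂ = median finite edge weight)
preserves weighting for users who want it.

## GNN training

Architectures: GCN 2×64 (dropout 0.5), GAT 64 units with 8 heads then 64
with 1 head (dropout 0.6, LeakyReLU slope 0.2, heads concatenated at the
hidden layer and averaged at the output layer), GraphSAGE 2×128 (dropout
0.6, self ‖ neighbor-mean concatenation, isolated nodes aggregate
themselves), each followed by a linear softmax head.  All layers are
implemented in NumPy over a small reverse-mode autodiff module; every
layer's forward pass is verified against per-node brute-force oracles and
every architecture's gradients against central finite differences.

Optimization: Adam at `1e-4`, global gradient-norm clipping at 1.0,
weighted cross-entropy with class weights `N/(K·N_c)`, stratified 80–20
train/test split with 20% of the training nodes as validation, early
stopping on validation accuracy (patience 10) with best-parameter
restoration, at most 100 epochs, fully seed-deterministic.

Two training choices deserve explanation because the cited hyperparameters
do not uniquely determine them:

* **Mini-batched loss (batch 16).**  Each epoch takes one Adam step per
  shuffled mini-batch of 16 training nodes (the forward pass always spans
  the whole graph).  At learning rate `1e-4`, a single full-batch step per
  epoch gives ≤ 100 steps total, which measurably cannot leave the random
  initialization regime — validation accuracy never improves and early
  stopping fires at chance level.  The mini-batched reading yields ~5 steps
  per epoch and convergence within ~12 epochs on separable graphs.
* **Zero-initialized output head** (hidden layers Glorot-uniform).  With a
  random head, initial logit gaps scale with the node-feature magnitude and
  exceed what ≤ 500 steps at `1e-4` can reorder; a zero head makes initial
  logits uniform so the first coherent gradient steps classify
  well-separated class prototypes almost immediately.

On the default well-separated study this configuration gives GCN and
GraphSAGE test accuracy 1.0 and GAT ≥ 0.958 across every seed tried, with
GAT the occasionally-weakest model.

## Degenerate inputs and tie-breaking

Constant feature columns standardize to 0 (not NaN).  PCA signs are fixed
(largest-magnitude loading positive) for cross-platform reproducibility.
A class never predicted gets precision 0 with a logged warning.  SMOTE
reduces `k` to `count−1` with a warning when a class has ≤ k samples, and
draws source points round-robin over a shuffled ordering so the synthetic
count per original point differs by at most one.  Percentile ties at the
pruning threshold are retained ("exceeding" prunes strictly-greater
weights).  MST tie-breaks follow Kruskal's stable edge ordering (insertion
order `i < j`), making graph construction a pure function of its inputs.

## Known limitations

* The Gaussian class model cannot represent multimodal or skewed feature
  distributions; no kernel-density alternative is provided.
* The composite metric is not the exact Fisher–Rao geodesic distance of
  the full Gaussian manifold (no closed form exists in general); it is
  implemented as specified, including its known tendency to report small
  distances between distant stages when covariance structure aligns.
* The pipeline fits standardization/PCA on all data before the node split,
  which leaks distributional information into the test nodes; this mirrors
  the described procedure.  The fitted scaler and `PcaModel` expose
  `transform`, so train-only fitting is available at the library level and
  should be preferred for real evaluations.
* Training is CPU-only and full-graph; it is sized for ~10²-node manifold
  graphs, not for thousands of nodes.
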