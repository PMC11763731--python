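# manifoldmri

Information-geometry and manifold-graph staging of grayscale brain-MRI-like
images.

## The problem

Staging a progressive condition such as Alzheimer's disease from structural
MRI means separating image classes whose differences are subtle and
distributional: later stages show not only shifted mean anatomy but
*increased variability and stronger feature correlations*.  This package
implements a pipeline that treats each impairment class as a multivariate
Gaussian — a point on a statistical manifold — and measures class
differences with the Fisher Information metric, then turns batch-level
Gaussian estimates into a geodesic-weighted graph and classifies its nodes
with graph neural networks.  It is aimed at methods researchers who want a
tested, fully seeded reference implementation of this analysis, exercisable
end to end on synthetic data with known ground truth.

## The model

Images are flattened, standardized and PCA-reduced to features
`x ∈ R^n`.  Each class `k` is modelled as `N(μ_k, Σ_k)` with maximum-
likelihood estimates (biased `1/N` covariance) and a diagonal
regularization `ε = 1e-5`.  Class dissimilarity uses the composite geodesic
distance

```
D_G² = (μ₁−μ₀)ᵀ [ (Σ₀+Σ₁)/2 ]⁻¹ (μ₁−μ₀)  +  Σᵢ ln² λᵢ ,
```

where `λᵢ` are the eigenvalues of `Σ₀⁻¹Σ₁` (computed from the symmetric
form `Σ₀^{-1/2} Σ₁ Σ₀^{-1/2}`).  The first term is a Mahalanobis distance
under the averaged covariance; the second is the affine-invariant metric on
SPD matrices.  Closed-form Gaussian KL divergence, the block-diagonal
Fisher Information Matrix `diag(Σ⁻¹, ½ Σ⁻¹⊗Σ⁻¹)`, permutation tests
(label shuffling, `p = #{D_perm ≥ D_obs}/B`), average intra-class
Mahalanobis variability, and Principal Geodesic Analysis (tangent-space
whitening by `Σ^{-1/2}` followed by PCA) complete the statistical layer.

For classification, 300 images per class are sampled and split into batches
of 10; each batch's regularized Gaussian fit is a *manifold point* (graph
node, featurized by its mean vector).  Per class, edges above the 80th
percentile of the geodesic weights are pruned (infinite weights always
are), and a global minimum spanning tree is merged back so the graph is
connected.  GCN (`σ(D̃^{-1/2}(A+I)D̃^{-1/2} H W)`), GAT (multi-head
attention with LeakyReLU logits and softmax over neighborhoods) and
GraphSAGE (self ‖ neighbor-mean concatenation) node classifiers are
implemented in NumPy with a small reverse-mode autodiff core and trained
with Adam (lr `1e-4`), gradient clipping (norm 1.0), dropout, class
weights, a stratified 80–20 split, and early stopping on validation
accuracy.

## Worked example

```python
import numpy as np
import manifoldmri as m
from manifoldmri import synthetic as syn

# 4-class synthetic study: 64x64 grayscale images rendered from latent
# Gaussians with growing mean offsets, covariance inflation and correlation
study = syn.default_study(n_images=400, sample_seed=11, basis_seed=7)
fm = syn.study_feature_matrix(study)            # 1600 x 4096 pixel features
std, _ = m.standardize(fm)
geo, pca = m.pca_fit_transform(std, variance_target=0.95)
print(m.class_distance_matrix(geo, epsilon=1e-5).round(2))
```

```
                      stage0_no_impairment  stage1_very_mild  stage2_mild  stage3_moderate
stage0_no_impairment                  0.00             20.85        41.88            56.80
stage1_very_mild                     20.85              0.00        47.19            60.36
stage2_mild                          41.88             47.19         0.00            68.63
stage3_moderate                      56.80             60.36        68.63             0.00
```

The estimated between-class geodesic distances grow with stage separation
(21 to 69 units), reflecting the configured latent geometry.  A permutation
test confirms the separation is far beyond label-shuffling noise:

```python
labels = np.asarray(geo.labels)
res = m.permutation_test(geo.X[labels == "stage0_no_impairment"],
                         geo.X[labels == "stage2_mild"],
                         n_permutations=200, seed=0)
print(f"observed={res.observed:.2f}, p={res.p_value:.4f}")
# observed=41.88, p=0.0000
```

Graph construction and GCN classification:

```python
g128, _ = m.pca_fit_transform(std, n_components=128, random_state=0)
points = m.sample_manifold_points(g128, per_class=300, batch=10, seed=3)
graph = m.prune_and_connect(m.build_complete_graph(points),
                            percentile=80, points=points)
tensors = m.graph_tensors(graph, adjacency_mode="binary")
_, history, report = m.train_node_classifier(
    tensors, m.ModelConfig.for_arch("gcn", 4), m.TrainConfig(seed=0))
print(f"GCN: {len(history)} epochs, test accuracy {report.accuracy:.3f}")
# GCN: 11 epochs, test accuracy 1.000
```

The graph has 120 nodes (30 batch Gaussians per class) and 1399 edges, 7 of
them added by the spanning tree; on this well-separated study the GCN
classifies every held-out node correctly, with per-class precision, recall
and F1 all 1.0 over the 24 test nodes.

## Command line

```bash
manifoldmri synth   --out data/ --seed 11            # write a synthetic study
manifoldmri run-all --config pipeline.yaml           # full pipeline from YAML
manifoldmri preprocess / geometry / permtest / graph / train  # single stages
```

`run-all` writes the feature matrix, class distance matrix, permutation
table, variability and PGA tables, the graph JSON, per-model classification
reports, and a manifest with the config hash and all seeds; re-running
reuses existing artifacts and regenerates only missing stages.

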