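"""Statistical inference on the Gaussian manifold.

Permutation tests for between-class geodesic distances, average intra-class
Mahalanobis variability, and Principal Geodesic Analysis via tangent-space
whitening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .geometry import EIG_FLOOR, fit_gaussian, geodesic_distance
from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a two-group geodesic-distance permutation test.

    ``p_value`` is the exact proportion of permuted distances that are
    greater than or equal to the observed one (no smoothing by default, so
    p = 0.0 is possible).
    """

    observed: float
    p_value: float
    null_distances: np.ndarray
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class PgaResult:
    """Principal geodesic components of one class.

    ``explained_variance_ratio`` covers the full whitened spectrum (sums to
    1); ``components`` holds the leading ``n_components`` orthonormal
    directions in whitened coordinates.
    """

    explained_variance_ratio: np.ndarray
    components: np.ndarray
    n_components: int


def _canonical_rows(X: np.ndarray) -> np.ndarray:
    """Sort rows lexicographically so results do not depend on input order."""
    return X[np.lexsort(X.T[::-1])]


def permutation_test(
    x_a: np.ndarray,
    x_b: np.ndarray,
    n_permutations: int = 1000,
    epsilon: float = 1e-5,
    seed: int = 0,
    smooth: bool = False,
) -> PermutationResult:
    """Label-shuffling significance test for the geodesic distance.

    The observed statistic is the geodesic distance between Gaussians fitted
    (with diagonal regularization ``epsilon``) to the two groups.  Each
    permutation re-partitions the pooled rows into groups of the original
    sizes and refits; the p-value is the proportion of permuted distances
    >= observed.  With ``smooth`` the (count+1)/(B+1) estimator is used so
    p-values are strictly positive.
    """
    x_a = np.asarray(x_a, float)
    x_b = np.asarray(x_b, float)
    if x_a.ndim != 2 or x_b.ndim != 2 or x_a.shape[1] != x_b.shape[1]:
        raise ValueError("groups must be 2-D with equal dimension")
    if x_a.shape[0] < 2 or x_b.shape[0] < 2:
        raise ValueError("each group needs at least 2 rows")
    observed = geodesic_distance(fit_gaussian(x_a, epsilon),
                                 fit_gaussian(x_b, epsilon))
    pooled = _canonical_rows(np.vstack([x_a, x_b]))
    n_a, n = x_a.shape[0], pooled.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        ga = pooled[perm[:n_a]]
        gb = pooled[perm[n_a:]]
        null[b] = geodesic_distance(fit_gaussian(ga, epsilon),
                                    fit_gaussian(gb, epsilon))
    count = int(np.sum(null >= observed))
    if smooth:
        p = (count + 1) / (n_permutations + 1)
    else:
        p = count / n_permutations
    return PermutationResult(observed=float(observed), p_value=float(p),
                             null_distances=null,
                             n_permutations=n_permutations, seed=seed)


def intra_class_variability(features: FeatureMatrix, epsilon: float = 1e-5) -> dict:
    """Average Mahalanobis distance of samples to their own class fit.

    Measures within-class dispersion relative to the class mean under the
    class's own regularized covariance; affine-invariant at epsilon = 0.
    """
    labels = np.asarray(features.labels)
    out = {}
    for label in features.class_order():
        rows = features.X[labels == label]
        if rows.shape[0] < 2:
            raise ValueError(f"class {label!r} has fewer than 2 samples")
        p = fit_gaussian(rows, epsilon=epsilon)
        c, low = linalg.cho_factor(p.sigma)
        centered = rows - p.mu
        sq = np.einsum("ij,ji->i", centered,
                       linalg.cho_solve((c, low), centered.T))
        out[label] = float(np.mean(np.sqrt(np.maximum(sq, 0.0))))
    return out


def pga(
    features_class: np.ndarray,
    epsilon: float = 1e-5,
    n_components: int = 2,
    cov: np.ndarray | None = None,
) -> PgaResult:
    """Principal Geodesic Analysis by tangent-space whitening.

    Centers the class at its mean, multiplies by the inverse principal
    square root of the (regularized) class covariance, and runs PCA on the
    whitened data.  ``cov`` overrides the estimated covariance — passing the
    identity recovers ordinary PCA, and exact self-whitening (epsilon = 0 on
    well-conditioned data) flattens the spectrum to 1/d by construction.
    """
    X = np.asarray(features_class, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    n, d = X.shape
    if not (1 <= n_components <= d):
        raise ValueError("n_components must be in [1, dimension]")
    p = fit_gaussian(X, epsilon=epsilon)
    whiten_cov = p.sigma if cov is None else np.asarray(cov, float)
    w, V = linalg.eigh((whiten_cov + whiten_cov.T) / 2.0)
    w = np.maximum(w, EIG_FLOOR)
    inv_sqrt = (V * (w ** -0.5)) @ V.T
    white = (X - p.mu) @ inv_sqrt
    # PCA spectrum of the whitened data (population covariance)
    cw = (white.T @ white) / n
    ew, Vw = linalg.eigh(cw)
    order = np.argsort(ew)[::-1]
    ew = np.maximum(ew[order], 0.0)
    Vw = Vw[:, order]
    total = ew.sum()
    rank = int(np.sum(ew > 1e-12 * max(ew[0], 1.0))) if total > 0 else 0
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds the numerical rank {rank} "
            "of the whitened class data"
        )
    ratios = ew / total
    comps = Vw[:, :n_components].T.copy()
    for i in range(comps.shape[0]):  # deterministic sign
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PgaResult(explained_variance_ratio=ratios, components=comps,
                     n_components=n_components)
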