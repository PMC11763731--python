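"""Information-geometry core: Gaussian class models on the statistical manifold.

Each impairment class is modelled as a multivariate Gaussian N(mu, Sigma)
fitted by maximum likelihood (biased 1/N covariance).  The Fisher Information
metric turns the family into a Riemannian manifold; class dissimilarity is
measured with the closed-form Gaussian KL divergence and with a composite
geodesic distance

    D_G^2 = (mu1 - mu0)^T ((Sigma0 + Sigma1)/2)^-1 (mu1 - mu0)
            + sum_i ln^2 lambda_i,

where lambda_i are the eigenvalues of Sigma0^-1 Sigma1.  The first term is a
Mahalanobis distance under the averaged covariance; the second is the
affine-invariant metric on symmetric positive-definite matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)

#: symmetry tolerance for covariance inputs
SYM_TOL = 1e-10
#: eigenvalue floor applied before matrix logarithms
EIG_FLOOR = 1e-12


@dataclass(frozen=True)
class GaussianParams:
    """A point on the Gaussian statistical manifold.

    Parameters
    ----------
    mu : (d,) mean vector.
    sigma : (d, d) symmetric positive-definite covariance.
    epsilon : diagonal regularization that was actually added to ``sigma``.
    n_fit : number of samples used for estimation (0 for analytic parameters).
    """

    mu: np.ndarray
    sigma: np.ndarray
    epsilon: float = 0.0
    n_fit: int = 0

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if mu.ndim != 1:
            raise ValueError("mu must be a vector")
        if sigma.shape != (mu.size, mu.size):
            raise ValueError("sigma must be square and match mu")
        if not np.all(np.isfinite(mu)) or not np.all(np.isfinite(sigma)):
            raise ValueError("GaussianParams requires finite mu and sigma")
        if np.max(np.abs(sigma - sigma.T)) > SYM_TOL * max(1.0, np.max(np.abs(sigma))):
            raise ValueError("sigma must be symmetric")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", (sigma + sigma.T) / 2.0)

    @property
    def dim(self) -> int:
        return self.mu.size


@dataclass(frozen=True)
class FisherMatrix:
    """Block-diagonal Fisher Information of a Gaussian: no mean/covariance
    cross terms.  ``mean_block`` is Sigma^-1 (d x d); ``cov_block`` is
    (1/2) Sigma^-1 (x) Sigma^-1 (d^2 x d^2, Kronecker product)."""

    mean_block: np.ndarray
    cov_block: np.ndarray


def fit_gaussian(features: np.ndarray, epsilon: float = 1e-5) -> GaussianParams:
    """Maximum-likelihood Gaussian fit with diagonal regularization.

    The covariance uses the biased 1/N divisor; ``epsilon`` is added to the
    diagonal *after* estimation to guarantee invertibility.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError("features must be a non-empty 2-D array")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    n, d = X.shape
    mu = X.mean(axis=0)
    centered = X - mu
    sigma = (centered.T @ centered) / n + epsilon * np.eye(d)
    return GaussianParams(mu=mu, sigma=sigma, epsilon=epsilon, n_fit=n)


def fisher_information(p: GaussianParams) -> FisherMatrix:
    """Fisher Information Matrix of a Gaussian at ``p``."""
    try:
        c, low = linalg.cho_factor(p.sigma)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "sigma is singular; refit with a positive diagonal "
            "regularization (epsilon > 0)"
        ) from exc
    sigma_inv = linalg.cho_solve((c, low), np.eye(p.dim))
    sigma_inv = (sigma_inv + sigma_inv.T) / 2.0
    return FisherMatrix(mean_block=sigma_inv, cov_block=0.5 * np.kron(sigma_inv, sigma_inv))


def kl_divergence(p: GaussianParams, q: GaussianParams) -> float:
    """Closed-form KL divergence KL(p || q) between Gaussians.

    (1/2)[ln(|Sq|/|Sp|) - d + tr(Sq^-1 Sp) + (mq-mp)^T Sq^-1 (mq-mp)].
    """
    if p.dim != q.dim:
        raise ValueError("dimension mismatch between p and q")
    d = p.dim
    c, low = linalg.cho_factor(q.sigma)
    # log|Sq| from the Cholesky factor; log|Sp| via slogdet (may be tiny).
    logdet_q = 2.0 * np.sum(np.log(np.diag(c)))
    sign, logdet_p = np.linalg.slogdet(p.sigma)
    if sign <= 0:
        raise ValueError("p.sigma is not positive-definite")
    trace_term = np.trace(linalg.cho_solve((c, low), p.sigma))
    diff = q.mu - p.mu
    maha = float(diff @ linalg.cho_solve((c, low), diff))
    return float(0.5 * (logdet_q - logdet_p - d + trace_term + maha))


def _inv_sqrt_psd(sigma: np.ndarray) -> np.ndarray:
    """Inverse principal square root via eigendecomposition, eigenvalues
    floored at EIG_FLOOR for numerical robustness."""
    w, V = linalg.eigh(sigma)
    w = np.maximum(w, EIG_FLOOR)
    return (V * (w ** -0.5)) @ V.T


def geodesic_distance(p: GaussianParams, q: GaussianParams) -> float:
    """Fisher-metric composite geodesic distance between two Gaussians.

    Combines the Mahalanobis term under the averaged covariance with the
    log-eigenvalue term over Sigma0^-1 Sigma1.  The eigenvalues are obtained
    from the congruent symmetric problem Sigma0^-1/2 Sigma1 Sigma0^-1/2,
    which is real and positive for SPD inputs.  Numerical failure or overflow
    yields ``+inf`` (downstream graph construction prunes infinite edges
    instead of failing).
    """
    if p.dim != q.dim:
        raise ValueError("dimension mismatch between p and q")
    try:
        avg = (p.sigma + q.sigma) / 2.0
        c, low = linalg.cho_factor(avg)
        diff = q.mu - p.mu
        mean_term = float(diff @ linalg.cho_solve((c, low), diff))
        inv_sqrt = _inv_sqrt_psd(p.sigma)
        congruent = inv_sqrt @ q.sigma @ inv_sqrt
        lam = linalg.eigvalsh((congruent + congruent.T) / 2.0)
        lam = np.maximum(lam, EIG_FLOOR)
        log_term = float(np.sum(np.log(lam) ** 2))
        value = np.sqrt(mean_term + log_term)
    except (linalg.LinAlgError, FloatingPointError, ValueError):
        return float("inf")
    if not np.isfinite(value):
        return float("inf")
    return float(value)


def class_distance_matrix(features, epsilon: float = 1e-5) -> pd.DataFrame:
    """Pairwise geodesic distance matrix between per-class Gaussian fits.

    ``features`` is a :class:`~manifoldmri.preprocess.FeatureMatrix`.  The
    diagonal is exactly zero and the matrix is symmetric by construction.
    """
    labels = np.asarray(features.labels)
    order = features.class_order()
    if len(order) < 2:
        raise ValueError("need at least 2 classes")
    fits = {}
    for label in order:
        rows = features.X[labels == label]
        if rows.shape[0] < 2:
            raise ValueError(f"class {label!r} has fewer than 2 samples")
        fits[label] = fit_gaussian(rows, epsilon=epsilon)
    K = len(order)
    D = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            d = geodesic_distance(fits[order[i]], fits[order[j]])
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=order, columns=order)


def save_gaussian(path, p: GaussianParams) -> None:
    np.savez_compressed(path, mu=p.mu, sigma=p.sigma,
                        epsilon=p.epsilon, n_fit=p.n_fit)


def load_gaussian(path) -> GaussianParams:
    with np.load(path) as data:
        return GaussianParams(mu=data["mu"], sigma=data["sigma"],
                              epsilon=float(data["epsilon"]),
                              n_fit=int(data["n_fit"]))
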