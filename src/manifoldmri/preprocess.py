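"""Image ingestion and feature-matrix preprocessing.

Turns directories of grayscale scans into the flat feature matrix the
geometry and graph stages consume: grayscale decode, bilinear resize to a
square grid, flatten, standardize (population variance), PCA (either to a
variance target or to a fixed component count), and SMOTE minority
oversampling for class balancing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from sklearn.decomposition import PCA as _SkPCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

_FEATURE_SPACES = ("pixel", "standardized", "pca")


@dataclass
class FeatureMatrix:
    """Rows of flattened/reduced image features with aligned class labels."""

    X: np.ndarray
    labels: np.ndarray
    feature_space: str = "pixel"

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or self.X.shape[1] < 1:
            raise ValueError("X must be 2-D with at least one feature")
        if self.labels.shape[0] != self.X.shape[0]:
            raise ValueError("labels must align with rows of X")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite entries")
        if self.feature_space not in _FEATURE_SPACES:
            raise ValueError(f"feature_space must be one of {_FEATURE_SPACES}")

    def class_order(self) -> list:
        """Unique labels in order of first appearance."""
        seen = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def class_counts(self) -> dict:
        order = self.class_order()
        return {lab: int(np.sum(self.labels == lab)) for lab in order}

    def save(self, path) -> None:
        np.savez_compressed(path, X=self.X, labels=self.labels.astype(str),
                            feature_space=self.feature_space)

    @classmethod
    def load(cls, path) -> "FeatureMatrix":
        with np.load(path, allow_pickle=False) as data:
            return cls(X=data["X"], labels=data["labels"],
                       feature_space=str(data["feature_space"]))


@dataclass
class StandardScalerParams:
    """Per-feature location/scale of a standardization fit."""

    mean: np.ndarray
    scale: np.ndarray  # population standard deviation; 1.0 for constant columns
    constant_mask: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.scale

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, float) * self.scale + self.mean


@dataclass
class PcaModel:
    """Orthonormal linear reduction fitted by PCA.

    ``components`` rows are orthonormal; the deterministic sign convention
    makes the largest-magnitude loading of every component positive.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray

    def __post_init__(self):
        C = np.asarray(self.components, float)
        G = C @ C.T
        if np.max(np.abs(G - np.eye(C.shape[0]))) > 1e-8:
            raise ValueError("components must be row-orthonormal")
        r = np.asarray(self.explained_variance_ratio, float)
        if np.any(np.diff(r) > 1e-12):
            raise ValueError("explained_variance_ratio must be nonincreasing")
        if r.sum() > 1 + 1e-8:
            raise ValueError("explained_variance_ratio sums above 1")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(X, float)) - self.mean) @ self.components.T

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(Z, float)) @ self.components + self.mean

    def save(self, path) -> None:
        np.savez_compressed(path, mean=self.mean, components=self.components,
                            explained_variance_ratio=self.explained_variance_ratio)

    @classmethod
    def load(cls, path) -> "PcaModel":
        with np.load(path) as data:
            return cls(mean=data["mean"], components=data["components"],
                       explained_variance_ratio=data["explained_variance_ratio"])


def load_image_directory(path) -> tuple[np.ndarray, np.ndarray]:
    """Load one-subfolder-per-class grayscale images scaled to [0, 1].

    Subfolders and files are visited in sorted order so repeated ingests give
    identical row ordering.  Unreadable files are skipped with a warning.
    """
    root = Path(path)
    if not root.is_dir():
        raise ValueError(f"{root} is not a directory")
    images, labels = [], []
    shape = None
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        for f in sorted(p for p in sub.iterdir() if p.is_file()):
            try:
                with Image.open(f) as im:
                    arr = np.asarray(im.convert("L"), dtype=float) / 255.0
            except Exception:  # unreadable/non-image file
                logger.warning("skipping unreadable file %s", f)
                continue
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(
                    f"image {f} has shape {arr.shape}, expected {shape}; "
                    "resize inputs to a common grid first"
                )
            images.append(arr)
            labels.append(sub.name)
    if not images:
        raise ValueError(f"no readable images found under {root}")
    return np.stack(images), np.asarray(labels)


def resize_flatten(images: np.ndarray, labels, size: int = 64) -> FeatureMatrix:
    """Bilinear-resize a stack of images to ``size`` x ``size`` and flatten.

    Sampling uses the align-corners grid (source coordinate i*(H-1)/(h-1)),
    so a same-size input is returned unchanged.
    """
    imgs = np.asarray(images, dtype=float)
    if imgs.ndim != 3 or imgs.shape[0] == 0:
        raise ValueError("images must be a non-empty (n, h, w) stack")
    n, h, w = imgs.shape
    if h == 0 or w == 0 or size < 1:
        raise ValueError("zero-sized image or target")
    if (h, w) == (size, size):
        out = imgs
    else:
        rows = np.linspace(0.0, h - 1.0, size) if size > 1 else np.array([(h - 1) / 2.0])
        cols = np.linspace(0.0, w - 1.0, size) if size > 1 else np.array([(w - 1) / 2.0])
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        coords = np.stack([rr.ravel(), cc.ravel()])
        out = np.empty((n, size, size))
        for i in range(n):
            out[i] = ndimage.map_coordinates(
                imgs[i], coords, order=1, mode="nearest"
            ).reshape(size, size)
    return FeatureMatrix(X=out.reshape(n, size * size), labels=np.asarray(labels),
                         feature_space="pixel")


def standardize(features: FeatureMatrix) -> tuple[FeatureMatrix, StandardScalerParams]:
    """Zero-mean unit-variance scaling with the population (1/N) variance.

    Constant columns map to exactly 0 rather than NaN.
    """
    X = features.X
    if X.shape[0] < 2:
        raise ValueError("standardization needs at least 2 samples")
    mean = X.mean(axis=0)
    var = X.var(axis=0)  # population variance, matching the MLE convention
    constant = var <= 0
    scale = np.where(constant, 1.0, np.sqrt(var))
    Z = (X - mean) / scale
    Z[:, constant] = 0.0
    scaler = StandardScalerParams(mean=mean, scale=scale, constant_mask=constant)
    return FeatureMatrix(X=Z, labels=features.labels, feature_space="standardized"), scaler


def pca_fit_transform(
    features: FeatureMatrix,
    variance_target: float | None = None,
    n_components: int | None = None,
    random_state: int = 0,
) -> tuple[FeatureMatrix, PcaModel]:
    """Fit PCA and project, keeping either a variance fraction or a fixed k.

    With ``variance_target`` the retained count is the minimum k whose
    cumulative explained-variance ratio reaches the target.  The sign of each
    component is fixed so its largest-magnitude loading is positive,
    making the projection reproducible across runs and platforms.
    """
    if (variance_target is None) == (n_components is None):
        raise ValueError("give exactly one of variance_target or n_components")
    X = features.X
    n, f = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_rank = min(n - 1, f)
    if n_components is not None:
        if not (1 <= n_components <= max_rank):
            raise ValueError(
                f"n_components must be in [1, {max_rank}] for this matrix"
            )
        sk = _SkPCA(n_components=n_components, random_state=random_state)
    elif not (0 < variance_target <= 1):
        raise ValueError("variance_target must lie in (0, 1]")
    elif variance_target == 1.0:
        sk = _SkPCA(n_components=max_rank, svd_solver="full")
    else:
        sk = _SkPCA(n_components=float(variance_target), svd_solver="full")
    Z = sk.fit_transform(X)
    components = sk.components_.copy()
    # deterministic sign convention
    for i in range(components.shape[0]):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] = -components[i]
            Z[:, i] = -Z[:, i]
    model = PcaModel(mean=sk.mean_, components=components,
                     explained_variance_ratio=sk.explained_variance_ratio_.copy())
    return FeatureMatrix(X=Z, labels=features.labels, feature_space="pca"), model


def smote_oversample(
    features: FeatureMatrix,
    targets: dict,
    k: int = 5,
    seed: int = 0,
) -> FeatureMatrix:
    """SMOTE minority oversampling to the per-class ``targets`` counts.

    Every synthetic row is ``x + u*(x' - x)`` with u ~ U[0, 1], x an original
    class member (chosen round-robin over a shuffled ordering) and x' one of
    its k nearest same-class neighbors in Euclidean distance.  Original rows
    are retained unchanged; classes absent from ``targets`` are left alone.
    """
    rng = np.random.default_rng(seed)
    labels = features.labels
    X = features.X
    out_X = [X]
    out_labels = [labels]
    for label in features.class_order():
        rows = X[labels == label]
        cur = rows.shape[0]
        target = int(targets.get(label, cur))
        if target < cur:
            raise ValueError(
                f"target {target} for class {label!r} is below current count {cur}"
            )
        n_new = target - cur
        if n_new == 0:
            continue
        k_eff = k
        if cur <= k:
            k_eff = cur - 1
            logger.warning(
                "class %r has %d samples <= k=%d; reducing k to %d",
                label, cur, k, k_eff,
            )
        if k_eff < 1:
            raise ValueError(f"class {label!r} needs >= 2 samples for SMOTE")
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(rows)
        # neighbor index 0 is the point itself
        neighbor_idx = nn.kneighbors(rows, return_distance=False)[:, 1:]
        order = rng.permutation(cur)
        src = order[np.arange(n_new) % cur]
        pick = rng.integers(0, k_eff, size=n_new)
        u = rng.uniform(0.0, 1.0, size=n_new)
        base = rows[src]
        neigh = rows[neighbor_idx[src, pick]]
        synth = base + u[:, None] * (neigh - base)
        out_X.append(synth)
        out_labels.append(np.full(n_new, label, dtype=labels.dtype))
    return FeatureMatrix(X=np.vstack(out_X), labels=np.concatenate(out_labels),
                         feature_space=features.feature_space)
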