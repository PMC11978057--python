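"""Eigenface model: PCA of mean-centered, vectorized face images.

Each grayscale face image (H x W) is flattened to a length H*W column
vector; PCA finds the orthonormal directions of maximum variance in that
space ("eigenfaces").  Components are retained until the cumulative
explained-variance ratio reaches a target (0.90 by default), keeping the
minimum count that achieves the bound.  Projections onto the retained basis
are the feature vectors fed to the classifiers.

At face-image dimensionality (300 x 200 = 60,000 pixels) with a few hundred
samples the covariance matrix is rank-deficient, so the decomposition uses
the snapshot method: eigendecompose the n x n Gram matrix of the centered
data and map its eigenvectors back to pixel space.  This is exact and far
cheaper than a 60,000-dimensional eigenproblem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

DEFAULT_VARIANCE_TARGET = 0.90


class DegenerateDataError(ValueError):
    """All training images identical: no variance to decompose."""


@dataclass
class EigenfaceModel:
    """Fitted eigenface basis.

    Attributes
    ----------
    mean_face : ndarray, shape (H*W,)
    basis : ndarray, shape (n_components, H*W)
        Rows are orthonormal eigenfaces, by decreasing explained variance.
    explained_ratio : ndarray, shape (n_components,)
        Fraction of total variance per retained component.
    image_shape : (H, W)
    variance_target : float
    """

    mean_face: np.ndarray
    basis: np.ndarray
    explained_ratio: np.ndarray
    image_shape: tuple[int, int]
    variance_target: float = DEFAULT_VARIANCE_TARGET

    @property
    def n_components(self) -> int:
        return self.basis.shape[0]

    def save(self, path: str | Path) -> None:
        """Serialize to <path>.npz plus a JSON metadata sidecar <path>.json."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 mean_face=self.mean_face, basis=self.basis,
                 explained_ratio=self.explained_ratio)
        meta = {
            "scheme": "EF",
            "image_shape": list(self.image_shape),
            "variance_target": self.variance_target,
            "n_components": int(self.n_components),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "EigenfaceModel":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            mean_face=arrays["mean_face"],
            basis=arrays["basis"],
            explained_ratio=arrays["explained_ratio"],
            image_shape=tuple(meta["image_shape"]),
            variance_target=float(meta["variance_target"]),
        )


def _as_matrix(images: list[np.ndarray]) -> tuple[np.ndarray, tuple[int, int]]:
    shape = images[0].shape
    for im in images:
        if im.shape != shape:
            raise ValueError(f"image shape mismatch: {im.shape} vs {shape}")
    X = np.stack([np.asarray(im, dtype=np.float64).ravel() for im in images])
    return X, shape


def fit_eigenfaces(
    images: list[np.ndarray],
    variance_target: float = DEFAULT_VARIANCE_TARGET,
) -> EigenfaceModel:
    """Fit an eigenface basis retaining the minimal component count whose
    cumulative explained-variance ratio reaches ``variance_target``.

    Raises
    ------
    DegenerateDataError
        If all images are identical (zero total variance).
    ValueError
        For fewer than two images, shape mismatch, or a target outside (0, 1].
    """
    if len(images) < 2:
        raise ValueError("need at least 2 images to fit eigenfaces")
    if not (0.0 < variance_target <= 1.0):
        raise ValueError("variance_target must be in (0, 1]")
    X, shape = _as_matrix(images)
    mean = X.mean(axis=0)
    Xc = X - mean
    n = Xc.shape[0]

    # Snapshot method: eigenvalues of Xc Xc^T are the squared singular values.
    gram = Xc @ Xc.T
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    total = evals.sum()
    if total <= 0 or total < 1e-10 * n:
        raise DegenerateDataError("all images identical: zero total variance")
    # drop numerically-null directions before the retention rule
    keep = evals > max(1e-12 * evals[0], 0.0)
    evals, evecs = evals[keep], evecs[:, keep]

    ratios = evals / total
    cum = np.cumsum(ratios)
    # minimal count with cumulative ratio >= target (include the component
    # that exactly hits the bound)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, len(ratios))

    basis = (Xc.T @ evecs[:, :k]) / np.sqrt(evals[:k])
    return EigenfaceModel(
        mean_face=mean,
        basis=basis.T,
        explained_ratio=ratios[:k],
        image_shape=shape,
        variance_target=variance_target,
    )


def project_eigenface(image: np.ndarray, model: EigenfaceModel) -> np.ndarray:
    """Project one image onto the retained eigenface basis.

    Returns ``basis @ (vec(image) - mean_face)``, the model's feature vector.
    """
    image = np.asarray(image)
    if image.shape != model.image_shape:
        raise ValueError(
            f"image shape {image.shape} does not match model {model.image_shape}"
        )
    centered = image.astype(np.float64).ravel() - model.mean_face
    return model.basis @ centered


def reconstruct(projection: np.ndarray, model: EigenfaceModel) -> np.ndarray:
    """Map a projection back to pixel space (mean + basis^T coefficients)."""
    flat = model.mean_face + model.basis.T @ np.asarray(projection, dtype=np.float64)
    return flat.reshape(model.image_shape)
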