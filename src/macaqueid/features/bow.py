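"""Bag-of-visual-words: k-means codebook fitting and histogram encoding.

Pooled keypoint descriptors from the training images are clustered into a
fixed vocabulary (200 visual words by default).  Each image is then encoded
as the histogram of nearest-centroid assignments of its descriptors,
L1-normalized so images with different keypoint counts are comparable; an
image with no descriptors encodes to the zero vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .keypoints import Descriptor

DEFAULT_VOCABULARY = 200


class InsufficientDataError(ValueError):
    """Fewer pooled descriptors than requested vocabulary size."""


@dataclass
class Codebook:
    """k centroid descriptors for visual-word quantization."""

    centroids: np.ndarray  # (k, d)
    fit_seed: int

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), centroids=self.centroids)
        meta = {"scheme": "BoW", "k": int(self.k), "fit_seed": int(self.fit_seed)}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Codebook":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(centroids=arrays["centroids"], fit_seed=int(meta["fit_seed"]))


def _stack(descriptors: list[Descriptor]) -> np.ndarray:
    return np.stack([d.values for d in descriptors])


def fit_codebook(
    descriptors: list[Descriptor],
    k: int = DEFAULT_VOCABULARY,
    seed: int = 0,
) -> Codebook:
    """Cluster pooled descriptors into a k-word vocabulary.

    Deterministic for fixed inputs and seed.  Raises
    :class:`InsufficientDataError` when fewer than ``k`` descriptors are
    pooled.
    """
    if len(descriptors) < k:
        raise InsufficientDataError(
            f"{len(descriptors)} descriptors < vocabulary size {k}"
        )
    X = _stack(descriptors)
    km = KMeans(n_clusters=k, random_state=seed, n_init=4)
    km.fit(X)
    return Codebook(centroids=km.cluster_centers_.astype(np.float64), fit_seed=seed)


def encode_bow(descriptors: list[Descriptor], codebook: Codebook) -> np.ndarray:
    """Encode descriptors as an L1-normalized visual-word histogram.

    Nearest centroid by Euclidean distance; empty descriptor lists encode
    to the zero vector of length k.
    """
    k = codebook.k
    if not descriptors:
        return np.zeros(k)
    X = _stack(descriptors)
    if X.shape[1] != codebook.centroids.shape[1]:
        raise ValueError(
            f"descriptor dim {X.shape[1]} != codebook dim {codebook.centroids.shape[1]}"
        )
    assign = cdist(X, codebook.centroids).argmin(axis=1)
    hist = np.bincount(assign, minlength=k).astype(np.float64)
    return hist / hist.sum()
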