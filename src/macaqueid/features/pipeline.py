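"""Uniform extractor interface over the four feature schemes.

Cross-validation needs to (a) precompute whatever is fold-independent once
per dataset (LBP histograms, keypoint descriptors), (b) fit fold-dependent
state (eigenbasis, codebook) on the training indices only, and (c) record
which indices that state was fitted on so leakage can be audited.  Each
extractor therefore exposes::

    prepare(images)        # once per dataset
    fit(train_indices)     # once per fold; appends to .fit_history
    transform(indices)     # feature matrix for any subset
    transform_images(imgs) # features for fresh images (realtime path)

Schemes: ``EF`` (eigenface projections), ``LBP-H`` (gridded LBP
histograms), ``SIFT-BoW`` / ``SURF-BoW`` (visual-word histograms).
"""

from __future__ import annotations

import numpy as np

from . import bow as _bow
from . import eigenfaces as _ef
from . import keypoints as _kp
from .lbp import LBPSpec, lbp_histogram

SCHEMES = ("EF", "LBP-H", "SIFT-BoW", "SURF-BoW")


class _BaseExtractor:
    scheme: str = ""

    def __init__(self) -> None:
        self._images: list[np.ndarray] | None = None
        #: per-fold record of the index sets fold state was fitted on
        self.fit_history: list[np.ndarray] = []

    def prepare(self, images: list[np.ndarray]) -> None:
        self._images = list(images)

    def fit(self, train_indices: np.ndarray) -> None:
        self.fit_history.append(np.asarray(train_indices, dtype=int).copy())

    def transform(self, indices: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def transform_images(self, images: list[np.ndarray]) -> np.ndarray:
        raise NotImplementedError


class EigenfaceExtractor(_BaseExtractor):
    """Eigenface projections; the basis is refitted per fold."""

    scheme = "EF"

    def __init__(self, variance_target: float = _ef.DEFAULT_VARIANCE_TARGET):
        super().__init__()
        self.variance_target = variance_target
        self.model: _ef.EigenfaceModel | None = None

    def fit(self, train_indices: np.ndarray) -> None:
        super().fit(train_indices)
        imgs = [self._images[i] for i in np.asarray(train_indices, dtype=int)]
        self.model = _ef.fit_eigenfaces(imgs, self.variance_target)

    def transform_images(self, images: list[np.ndarray]) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("extractor not fitted")
        return np.stack([_ef.project_eigenface(im, self.model) for im in images])

    def transform(self, indices: np.ndarray) -> np.ndarray:
        return self.transform_images([self._images[i] for i in np.asarray(indices, dtype=int)])


class LBPExtractor(_BaseExtractor):
    """Gridded LBP histograms; fold-independent, computed once in prepare."""

    scheme = "LBP-H"

    def __init__(self, spec: LBPSpec = LBPSpec()):
        super().__init__()
        self.spec = spec
        self._feats: np.ndarray | None = None

    def prepare(self, images: list[np.ndarray]) -> None:
        super().prepare(images)
        self._feats = np.stack([lbp_histogram(im, self.spec) for im in images])

    def transform(self, indices: np.ndarray) -> np.ndarray:
        return self._feats[np.asarray(indices, dtype=int)]

    def transform_images(self, images: list[np.ndarray]) -> np.ndarray:
        return np.stack([lbp_histogram(im, self.spec) for im in images])


class BowExtractor(_BaseExtractor):
    """Keypoint descriptors + bag-of-visual-words encoding.

    Descriptors are extracted once per image in ``prepare``; the codebook
    is refitted per fold on the pooled descriptors of the training indices
    only (never the test fold).
    """

    def __init__(self, method: str = "SIFT", top_k: int | None = None,
                 vocabulary: int = _bow.DEFAULT_VOCABULARY, seed: int = 0):
        super().__init__()
        self.method = method.upper()
        self.scheme = f"{self.method}-BoW"
        self.top_k = top_k if top_k is not None else _kp.DEFAULT_TOP_K[self.method]
        self.vocabulary = vocabulary
        self.seed = seed
        self._descs: list[list[_kp.Descriptor]] | None = None
        self.codebook: _bow.Codebook | None = None

    def prepare(self, images: list[np.ndarray]) -> None:
        super().prepare(images)
        self._descs = [_kp.extract_keypoints(im, self.method, self.top_k) for im in images]

    def fit(self, train_indices: np.ndarray) -> None:
        super().fit(train_indices)
        pooled = [d for i in np.asarray(train_indices, dtype=int) for d in self._descs[i]]
        k = min(self.vocabulary, len(pooled))
        if k == 0:
            raise _bow.InsufficientDataError("no descriptors in training fold")
        self.codebook = _bow.fit_codebook(pooled, k=k, seed=self.seed)

    def transform(self, indices: np.ndarray) -> np.ndarray:
        if self.codebook is None:
            raise RuntimeError("extractor not fitted")
        return np.stack([_bow.encode_bow(self._descs[i], self.codebook)
                         for i in np.asarray(indices, dtype=int)])

    def transform_images(self, images: list[np.ndarray]) -> np.ndarray:
        if self.codebook is None:
            raise RuntimeError("extractor not fitted")
        return np.stack([
            _bow.encode_bow(_kp.extract_keypoints(im, self.method, self.top_k), self.codebook)
            for im in images
        ])


def make_extractor(scheme: str, seed: int = 0, **kwargs) -> _BaseExtractor:
    """Factory mapping a scheme name to a fresh extractor instance."""
    scheme = scheme.upper().replace("_", "-")
    if scheme == "EF":
        return EigenfaceExtractor(**kwargs)
    if scheme in ("LBP-H", "LBPH", "LBP"):
        return LBPExtractor(**kwargs)
    if scheme == "SIFT-BOW":
        return BowExtractor("SIFT", seed=seed, **kwargs)
    if scheme == "SURF-BOW":
        return BowExtractor("SURF", seed=seed, **kwargs)
    raise ValueError(f"unknown feature scheme {scheme!r}; choose from {SCHEMES}")
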