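"""Local keypoint descriptors with strongest-k retention.

Two descriptor families are supported:

* ``SIFT`` — scikit-image's SIFT detector/descriptor (128-dim gradient
  orientation histograms).  The detector does not expose a per-keypoint
  strength, so strength is measured here as the scale-normalized absolute
  Laplacian-of-Gaussian response ``sigma^2 |LoG(image, sigma)|`` at the
  keypoint's position and scale — the standard blob-saliency measure.
* ``SURF`` — an upright SURF-style extractor authored here: keypoints are
  local maxima of the scale-normalized determinant of the Hessian over a
  small scale stack, and the 64-dim descriptor sums Haar-like first-order
  responses (dx, |dx|, dy, |dy|) over a 4 x 4 grid of subregions scaled by
  the detection scale, L2-normalized.

Only the strongest ``top_k`` keypoints are kept (defaults: 5 for SIFT, 3
for SURF), ranked by descending strength with (y, x) scan order breaking
ties so extraction is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import SIFT as _SkSIFT
from skimage.feature import peak_local_max

DEFAULT_TOP_K = {"SIFT": 5, "SURF": 3}
DESCRIPTOR_DIM = {"SIFT": 128, "SURF": 64}


@dataclass
class Descriptor:
    """A local descriptor with its keypoint strength and pixel location."""

    values: np.ndarray
    response: float
    location: tuple[float, float]  # (x, y)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("descriptor contains non-finite values")
        if self.response < 0:
            raise ValueError("response must be >= 0")


def _top_k(descs: list[Descriptor], top_k: int) -> list[Descriptor]:
    # strongest first; ties by (y, x) scan order for determinism
    descs = sorted(descs, key=lambda d: (-d.response, d.location[1], d.location[0]))
    return descs[:top_k]


# -- SIFT ------------------------------------------------------------------


def _sift_descriptors(image: np.ndarray) -> list[Descriptor]:
    img = np.asarray(image, dtype=np.float32)
    if img.max() == img.min():
        return []
    # upsampling=1 skips the initial 2x upscale: faces are already large
    det = _SkSIFT(upsampling=1)
    try:
        det.detect_and_extract(img)
    except RuntimeError:  # no keypoints survive filtering
        return []
    if len(det.keypoints) == 0:
        return []
    # scale-normalized |LoG| strength per keypoint.  Keypoint sigmas are
    # continuous; they are binned onto a geometric grid (ratio 1.25) so only
    # a handful of LoG filters are needed — the response is a ranking key,
    # not a measurement, and a <12% scale error does not reorder blobs.
    responses = np.zeros(len(det.keypoints))
    step = np.log(1.25)
    sigmas = np.exp(np.round(np.log(np.maximum(det.sigmas, 1e-3)) / step) * step)
    sigmas = np.round(sigmas, 6)
    smooth = img.astype(np.float64)
    for s in np.unique(sigmas):
        log_img = ndimage.gaussian_laplace(smooth, sigma=s)
        mask = sigmas == s
        rr = det.keypoints[mask, 0].astype(int).clip(0, img.shape[0] - 1)
        cc = det.keypoints[mask, 1].astype(int).clip(0, img.shape[1] - 1)
        responses[mask] = (s ** 2) * np.abs(log_img[rr, cc])
    return [
        Descriptor(det.descriptors[i].astype(np.float64), float(responses[i]),
                   (float(det.keypoints[i, 1]), float(det.keypoints[i, 0])))
        for i in range(len(det.keypoints))
    ]


# -- SURF-style ------------------------------------------------------------

_SURF_SIGMAS = (1.6, 3.2, 4.8, 6.4)


def _surf_descriptors(image: np.ndarray, max_keep: int | None = None) -> list[Descriptor]:
    img = np.asarray(image, dtype=np.float64)
    if img.max() == img.min():
        return []
    candidates: list[tuple[float, int, int, float]] = []  # (resp, r, c, sigma)
    grads: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for sigma in _SURF_SIGMAS:
        Hrr = ndimage.gaussian_filter(img, sigma, order=(2, 0))
        Hcc = ndimage.gaussian_filter(img, sigma, order=(0, 2))
        Hrc = ndimage.gaussian_filter(img, sigma, order=(1, 1))
        doh = (sigma ** 4) * (Hrr * Hcc - Hrc ** 2)
        thresh = 0.01 * doh.max() if doh.max() > 0 else np.inf
        peaks = peak_local_max(doh, min_distance=3, threshold_abs=max(thresh, 1e-6))
        for r, c in peaks:
            candidates.append((float(doh[r, c]), int(r), int(c), sigma))
    # strongest first (ties by scan order); descriptors are only built for
    # the candidates that can survive the top-k cut
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    if max_keep is not None:
        candidates = candidates[: 2 * max_keep]  # margin for dropped windows
    descs: list[Descriptor] = []
    for resp, r, c, sigma in candidates:
        if sigma not in grads:
            grads[sigma] = (ndimage.gaussian_filter(img, sigma, order=(1, 0)),
                            ndimage.gaussian_filter(img, sigma, order=(0, 1)))
        vec = _surf_descriptor_at(img, r, c, sigma, grads[sigma])
        if vec is not None:
            descs.append(Descriptor(vec, resp, (float(c), float(r))))
    return descs


def _surf_descriptor_at(img: np.ndarray, r: int, c: int, sigma: float,
                        grads: tuple[np.ndarray, np.ndarray]) -> np.ndarray | None:
    """Upright 64-dim descriptor: 4x4 subregions of Haar response sums."""
    dy, dx = grads
    half = int(round(5 * sigma))  # 10*sigma window, 4x4 subregions
    if half < 4:
        half = 4
    y0, y1 = r - half, r + half
    x0, x1 = c - half, c + half
    if y0 < 0 or x0 < 0 or y1 > img.shape[0] or x1 > img.shape[1]:
        # clamp the window into the image rather than dropping the keypoint
        y0, x0 = max(0, y0), max(0, x0)
        y1, x1 = min(img.shape[0], y1), min(img.shape[1], x1)
        if y1 - y0 < 8 or x1 - x0 < 8:
            return None
    wy = np.array_split(np.arange(y0, y1), 4)
    wx = np.array_split(np.arange(x0, x1), 4)
    feats = []
    for ys in wy:
        for xs in wx:
            sub_dx = dx[np.ix_(ys, xs)]
            sub_dy = dy[np.ix_(ys, xs)]
            feats.extend([sub_dx.sum(), np.abs(sub_dx).sum(),
                          sub_dy.sum(), np.abs(sub_dy).sum()])
    vec = np.asarray(feats)
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 0 else vec


def extract_keypoints(
    image: np.ndarray,
    method: str = "SIFT",
    top_k: int | None = None,
) -> list[Descriptor]:
    """Extract the strongest ``top_k`` keypoint descriptors from one image.

    A featureless (constant) image yields an empty list; fewer descriptors
    than ``top_k`` are returned when fewer keypoints exist.
    """
    method = method.upper()
    if method not in DESCRIPTOR_DIM:
        raise ValueError(f"unknown keypoint method {method!r}")
    if top_k is None:
        top_k = DEFAULT_TOP_K[method]
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if method == "SIFT":
        descs = _sift_descriptors(image)
    else:
        descs = _surf_descriptors(image, max_keep=top_k)
    return _top_k(descs, top_k)
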