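"""Image and frame-stream I/O plus the fixed preprocessing front end.

Every downstream feature extractor consumes a grayscale face crop at the
canonical resolution (default 300 x 200, height x width, portrait).  The
preprocessing is deliberately simple and fully deterministic: grayscale by
arithmetic channel mean (round half-up) and bilinear resize.

Video arrives either through a real container (via imageio) or through the
frame-directory convention: zero-padded numeric filenames plus an optional
``timestamps.csv`` sidecar (columns ``frame_index``, ``time_s``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

#: Canonical (height, width) every face crop is normalized to before
#: feature extraction.  Height-first; portrait by default.
CANONICAL_SHAPE: tuple[int, int] = (300, 200)

#: Nominal frame rate datasets are resampled to, frames per second.
DEFAULT_FPS: float = 10.0


class ChannelCountError(ValueError):
    """Raised when a color operation receives a non-3-channel image."""


class DimensionError(ValueError):
    """Raised for empty images or non-positive target dimensions."""


def _require_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ChannelCountError(
            f"expected a H x W x 3 image, got shape {image.shape}"
        )
    return image


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an RGB image to grayscale by averaging the three channels.

    The mean is rounded half-up to an integer, computed in exact integer
    arithmetic so the result is identical on every platform.

    Parameters
    ----------
    image : ndarray, shape (H, W, 3)
        Integer intensities in [0, 255].

    Returns
    -------
    ndarray of uint8, shape (H, W)
    """
    image = _require_rgb(image)
    total = image.astype(np.int64).sum(axis=2)
    # floor((total/3) + 1/2) == floor((2*total + 3) / 6) exactly
    gray = (2 * total + 3) // 6
    return gray.astype(np.uint8)


def resize_canonical(
    image: np.ndarray,
    target_h: int = CANONICAL_SHAPE[0],
    target_w: int = CANONICAL_SHAPE[1],
) -> np.ndarray:
    """Bilinearly resize a grayscale image to the canonical resolution.

    No anti-aliasing prefilter is applied, so output intensities stay
    within the [min, max] envelope of the input.  An image already at the
    target size is returned unchanged.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise DimensionError(f"expected a 2-D grayscale image, got shape {image.shape}")
    if image.size == 0:
        raise DimensionError("cannot resize an empty image")
    if target_h < 1 or target_w < 1:
        raise DimensionError("target dimensions must be >= 1")
    if image.shape == (target_h, target_w):
        return image.astype(np.uint8, copy=False)
    out = _sk_resize(
        image.astype(np.float64),
        (target_h, target_w),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.floor(out + 0.5).clip(0, 255).astype(np.uint8)


def preprocess(image: np.ndarray, shape: tuple[int, int] = CANONICAL_SHAPE) -> np.ndarray:
    """Full canonical preprocessing: grayscale (if RGB) then resize."""
    image = np.asarray(image)
    if image.ndim == 3:
        image = to_grayscale(image)
    return resize_canonical(image, shape[0], shape[1])


@dataclass
class FrameStream:
    """An ordered sequence of timestamped RGB frames.

    Attributes
    ----------
    timestamps : ndarray of float, seconds, strictly increasing
    frames : list of ndarray, each (H, W, 3) uint8
    nominal_rate : float or None
        Frames per second after resampling; None for raw captures.
    """

    timestamps: np.ndarray
    frames: list[np.ndarray]
    nominal_rate: float | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != len(self.frames):
            raise ValueError("timestamps and frames length mismatch")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(zip(self.timestamps, self.frames))


def resample_stream(stream: FrameStream, rate: float = DEFAULT_FPS) -> FrameStream:
    """Resample a stream to a fixed rate by nearest-previous frame selection.

    Output ticks are ``t0 + k / rate`` for ``k = 0 .. floor(duration * rate)``;
    each tick carries the input frame with the latest timestamp <= tick.  No
    frame interpolation is performed: identification must run on real frames.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if len(stream) == 0:
        return FrameStream(np.empty(0), [], nominal_rate=rate)
    t0 = float(stream.timestamps[0])
    duration = float(stream.timestamps[-1]) - t0
    n_ticks = int(np.floor(duration * rate + 1e-9)) + 1
    ticks = t0 + np.arange(n_ticks) / rate
    # nearest-previous: index of last timestamp <= tick
    idx = np.searchsorted(stream.timestamps, ticks + 1e-12, side="right") - 1
    idx = np.clip(idx, 0, len(stream) - 1)
    return FrameStream(ticks, [stream.frames[i] for i in idx], nominal_rate=rate)


# ---------------------------------------------------------------------------
# File I/O


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG image as an RGB uint8 array (grayscale is stacked)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=2)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return arr.astype(np.uint8)


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a label manifest CSV (columns image_path, identity_id[, split]).

    Paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"identity_id": str})
    required = {"image_path", "identity_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    df["image_path"] = [str((path.parent / p).resolve()) for p in df["image_path"]]
    return df


def load_labeled_images(manifest: str | Path | pd.DataFrame) -> tuple[list[np.ndarray], list[str]]:
    """Load all images referenced by a manifest, preprocessed to canonical grays."""
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    images = [preprocess(read_image(p)) for p in manifest["image_path"]]
    labels = [str(l) for l in manifest["identity_id"]]
    return images, labels


_FRAME_RE = re.compile(r"(\d+)\.(png|jpg|jpeg)$", re.IGNORECASE)


def read_frame_dir(path: str | Path, fps: float = DEFAULT_FPS) -> FrameStream:
    """Read a frame directory as a stream.

    Filenames must end in a zero-padded frame number; an optional
    ``timestamps.csv`` (frame_index, time_s) overrides the uniform grid
    ``index / fps``.
    """
    path = Path(path)
    entries: list[tuple[int, Path]] = []
    for p in sorted(path.iterdir()):
        m = _FRAME_RE.search(p.name)
        if m:
            entries.append((int(m.group(1)), p))
    entries.sort(key=lambda e: e[0])
    times: dict[int, float] = {}
    ts_csv = path / "timestamps.csv"
    if ts_csv.exists():
        tdf = pd.read_csv(ts_csv)
        times = dict(zip(tdf["frame_index"].astype(int), tdf["time_s"].astype(float)))
    timestamps = [times.get(i, i / fps) for i, _ in entries]
    frames = [read_image(p) for _, p in entries]
    return FrameStream(np.asarray(timestamps), frames, nominal_rate=None)
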