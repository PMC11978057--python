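"""Deterministic synthetic face-image generator.

No face recordings ship with this package, so benchmarking and the realtime
layer are exercised on procedurally generated multi-identity face crops.
Each identity is a template: an elliptical face with two eye discs, a
muzzle region with nostrils, and a band-limited fur-noise texture, all
parameterized by a small vector.  The identity signal lives both in global
geometry (which favors holistic eigenface features) and in texture
statistics (which favors LBP histograms), so every extractor path is
exercised non-trivially.  Nuisance variation — lighting gain and gradient,
pose jitter (translation/rotation), Gaussian sensor noise, blur — comes
from a render configuration and is drawn per image.

Everything is deterministic under fixed seeds: same seeds, same bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import FrameStream, write_image

#: rendered face-crop size before canonical preprocessing (H, W)
RENDER_SHAPE = (240, 160)

PARAM_NAMES = (
    "face_width", "face_height", "eye_spacing", "eye_size", "eye_height",
    "muzzle_width", "muzzle_height", "fur_freq", "fur_contrast", "brightness",
)

DEFAULT_SEPARATION = 0.8


class SeparationError(RuntimeError):
    """Could not draw templates with the requested pairwise separation."""


@dataclass(frozen=True)
class IdentityTemplate:
    """One synthetic individual: geometry parameters + a fur-texture seed."""

    id: str
    shape_params: np.ndarray  # len(PARAM_NAMES), each in [0, 1]
    base_texture_seed: int


@dataclass(frozen=True)
class RenderConfig:
    """Per-image nuisance settings.

    lighting_gain : multiplicative intensity factor
    lighting_gradient : (per-row, per-column) intensity slope across the image
    max_shift : max |translation| of the face, pixels
    max_rotation : max |rotation| of the face, degrees
    noise_sd : Gaussian sensor-noise standard deviation, intensity units
    blur_sigma : Gaussian blur, pixels
    """

    lighting_gain: float = 1.0
    lighting_gradient: tuple[float, float] = (0.0, 0.0)
    max_shift: float = 5.0
    max_rotation: float = 5.0
    noise_sd: float = 8.0
    blur_sigma: float = 0.6


@dataclass(frozen=True)
class ConfigRanges:
    """Ranges the per-image render configs are drawn from (dataset defaults)."""

    gain: tuple[float, float] = (0.85, 1.15)
    gradient: tuple[float, float] = (-15.0, 15.0)
    max_shift: float = 5.0
    max_rotation: float = 5.0
    noise_sd: float = 8.0
    blur_sigma: float = 0.6


def make_population(
    n_identities: int,
    seed: int = 0,
    separation: float = DEFAULT_SEPARATION,
    max_attempts: int = 5000,
) -> list[IdentityTemplate]:
    """Draw templates whose parameter vectors are pairwise >= ``separation``
    apart (Euclidean, rejection sampling).  Deterministic per seed.
    """
    if n_identities < 2:
        raise ValueError("need at least 2 identities")
    if separation <= 0:
        raise ValueError("separation must be > 0")
    rng = np.random.default_rng(seed)
    params: list[np.ndarray] = []
    attempts = 0
    while len(params) < n_identities:
        if attempts >= max_attempts:
            raise SeparationError(
                f"could not place {n_identities} identities at separation "
                f"{separation} within {max_attempts} draws"
            )
        cand = rng.random(len(PARAM_NAMES))
        attempts += 1
        if all(np.linalg.norm(cand - p) >= separation for p in params):
            params.append(cand)
    return [
        IdentityTemplate(
            id=f"id{i + 1:02d}",
            shape_params=p,
            base_texture_seed=int(rng.integers(0, 2**31 - 1)),
        )
        for i, p in enumerate(params)
    ]


def _fur_texture(template: IdentityTemplate, shape: tuple[int, int]) -> np.ndarray:
    """Band-limited noise field, fixed per identity (part of the signal)."""
    p = dict(zip(PARAM_NAMES, template.shape_params))
    rng = np.random.default_rng(template.base_texture_seed)
    noise = rng.standard_normal(shape)
    sigma = 1.2 + 2.2 * p["fur_freq"]
    tex = ndimage.gaussian_filter(noise, sigma)
    tex /= max(tex.std(), 1e-9)
    return tex * (8.0 + 16.0 * p["fur_contrast"])


def _rest_face(template: IdentityTemplate, shape: tuple[int, int] = RENDER_SHAPE
               ) -> tuple[np.ndarray, np.ndarray]:
    """Face layer and its mask at rest pose (no jitter, no lighting)."""
    H, W = shape
    p = dict(zip(PARAM_NAMES, template.shape_params))
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    cy, cx = H / 2.0, W / 2.0

    ay = (0.34 + 0.10 * p["face_height"]) * H
    ax = (0.28 + 0.10 * p["face_width"]) * W
    face_mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    base = 110.0 + 60.0 * p["brightness"]
    img = np.full((H, W), 0.0)
    img[face_mask] = base
    img += face_mask * _fur_texture(template, shape)

    # eyes: dark discs
    es = (0.14 + 0.12 * p["eye_spacing"]) * W
    er = (0.035 + 0.035 * p["eye_size"]) * W
    eh = cy - (0.10 + 0.10 * p["eye_height"]) * H
    for sx in (-1, 1):
        ex = cx + sx * es
        eye = (yy - eh) ** 2 + (xx - ex) ** 2 <= er ** 2
        img[eye & face_mask] = 25.0
    # brow band above the eyes, slightly dark
    brow = (np.abs(yy - (eh - 2.2 * er)) < 0.6 * er) & face_mask
    img[brow] *= 0.82

    # muzzle: bright ellipse low on the face, with nostrils
    mw = (0.12 + 0.10 * p["muzzle_width"]) * W
    mh = (0.10 + 0.08 * p["muzzle_height"]) * H
    my = cy + 0.22 * H
    muzzle = ((yy - my) / mh) ** 2 + ((xx - cx) / mw) ** 2 <= 1.0
    img[muzzle & face_mask] = base + 45.0
    for sx in (-1, 1):
        nost = (yy - (my - 0.25 * mh)) ** 2 + (xx - (cx + sx * 0.35 * mw)) ** 2 <= (0.035 * W) ** 2
        img[nost & face_mask] = 30.0

    return img, face_mask.astype(np.float64)


def render(
    template: IdentityTemplate,
    config: RenderConfig = RenderConfig(),
    seed: int = 0,
    float_gray: bool = False,
) -> np.ndarray:
    """Render one face image under a nuisance configuration.

    Returns an RGB uint8 image at :data:`RENDER_SHAPE` (the channel mean
    recovers the underlying gray level exactly).  With ``float_gray`` the
    unquantized grayscale field is returned instead — useful when exact
    (quantization-free) intensity relations matter, e.g. for checking the
    monotone-invariance of LBP under a pure gain change.

    Deterministic for fixed (template, config, seed).
    """
    H, W = RENDER_SHAPE
    rng = np.random.default_rng(seed)
    face, mask = _rest_face(template)

    angle = rng.uniform(-config.max_rotation, config.max_rotation)
    shift = rng.uniform(-config.max_shift, config.max_shift, size=2)
    if config.max_rotation > 0:
        face = ndimage.rotate(face, angle, reshape=False, order=1)
        mask = ndimage.rotate(mask, angle, reshape=False, order=1)
    if config.max_shift > 0:
        face = ndimage.shift(face, shift, order=1)
        mask = ndimage.shift(mask, shift, order=1)
    mask = np.clip(mask, 0.0, 1.0)

    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    background = 55.0 + 18.0 * (xx / W)  # plain backdrop wall
    img = background * (1.0 - mask) + face * mask

    # imaging chain: optical blur, then lighting, then sensor noise — so a
    # pure gain change is an exact elementwise monotone map of the scene
    if config.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, config.blur_sigma)
    gy, gx = config.lighting_gradient
    img = img * config.lighting_gain + gy * (yy / H - 0.5) + gx * (xx / W - 0.5)
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)

    if float_gray:
        return img
    gray = np.clip(np.floor(img + 0.5), 8, 247)
    rgb = np.stack([gray + 8, gray, gray - 8], axis=2)
    return rgb.astype(np.uint8)


@dataclass
class Dataset:
    """An in-memory labeled face set plus its reproducibility manifest."""

    images: list[np.ndarray]  # RGB uint8
    labels: list[str]
    manifest: pd.DataFrame  # image_path, identity_id, render_seed, ...
    configs: list[RenderConfig]

    def write(self, out_dir: str | Path) -> Path:
        """Write PNGs, manifest.csv and a full-face boxes.json sidecar."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "images").mkdir(exist_ok=True)
        boxes = []
        for i, img in enumerate(self.images):
            write_image(out_dir / self.manifest.loc[i, "image_path"], img)
            h, w = img.shape[:2]
            boxes.append({"frame_index": i, "x0": 0, "y0": 0, "x1": w, "y1": h,
                          "score": 1.0, "identity_id": self.labels[i]})
        self.manifest.to_csv(out_dir / "manifest.csv", index=False)
        (out_dir / "boxes.json").write_text(json.dumps(boxes, indent=1))
        return out_dir / "manifest.csv"


def _sample_config(rng: np.random.Generator, ranges: ConfigRanges) -> RenderConfig:
    return RenderConfig(
        lighting_gain=float(rng.uniform(*ranges.gain)),
        lighting_gradient=(float(rng.uniform(*ranges.gradient)),
                           float(rng.uniform(*ranges.gradient))),
        max_shift=ranges.max_shift,
        max_rotation=ranges.max_rotation,
        noise_sd=ranges.noise_sd,
        blur_sigma=ranges.blur_sigma,
    )


def make_dataset(
    population: list[IdentityTemplate],
    images_per_id: int = 60,
    config_ranges: ConfigRanges = ConfigRanges(),
    seed: int = 0,
    class_counts: dict[str, int] | None = None,
) -> Dataset:
    """Render a labeled face set: ``images_per_id`` renders per identity
    (or explicit per-identity ``class_counts`` for unbalanced cohorts),
    with per-image nuisance configs drawn from ``config_ranges``.

    Deterministic per seed; every per-image render seed and config is
    recorded in the manifest.
    """
    if images_per_id < 1:
        raise ValueError("images_per_id must be >= 1")
    rng = np.random.default_rng(seed)
    images, labels, configs, rows = [], [], [], []
    for template in population:
        count = (class_counts or {}).get(template.id, images_per_id)
        for j in range(count):
            cfg = _sample_config(rng, config_ranges)
            render_seed = int(rng.integers(0, 2**31 - 1))
            images.append(render(template, cfg, seed=render_seed))
            labels.append(template.id)
            configs.append(cfg)
            rows.append({
                "image_path": f"images/{template.id}_{j:04d}.png",
                "identity_id": template.id,
                "render_seed": render_seed,
                "lighting_gain": round(cfg.lighting_gain, 6),
                "gradient_y": round(cfg.lighting_gradient[0], 6),
                "gradient_x": round(cfg.lighting_gradient[1], 6),
                "noise_sd": cfg.noise_sd,
            })
    return Dataset(images, labels, pd.DataFrame(rows), configs)


def make_session_stream(
    population: list[IdentityTemplate],
    duration: float = 10.0,
    fps: float = 10.0,
    segment: float = 3.0,
    seed: int = 0,
    frame_shape: tuple[int, int] = (360, 480),
    config_ranges: ConfigRanges = ConfigRanges(),
) -> tuple[FrameStream, list[dict]]:
    """Synthesize a group-cage style video: one identity visible per
    ~``segment``-second span, its face composited at a jittered position.

    The face moves as a bounded random walk (smooth motion, like a real
    animal), so successive boxes overlap and the realtime layer's IoU
    chain-linking holds within a window.

    Returns the frame stream plus a ground-truth sidecar (one record per
    frame: box coordinates and the visible identity) consumable by
    :class:`macaqueid.detect.FixtureDetector`.
    """
    rng = np.random.default_rng(seed)
    H, W = frame_shape
    fh, fw = RENDER_SHAPE
    n_frames = int(round(duration * fps))
    timestamps = np.arange(n_frames) / fps
    frames, sidecar = [], []
    x0 = int(rng.integers(0, W - fw + 1))
    y0 = int(rng.integers(0, H - fh + 1))
    prev_segment = -1
    for i in range(n_frames):
        t = timestamps[i]
        seg = int(t // segment)
        ident = population[seg % len(population)]
        cfg = _sample_config(rng, config_ranges)
        face = render(ident, cfg, seed=int(rng.integers(0, 2**31 - 1)))
        if seg != prev_segment:  # new animal enters at a fresh position
            x0 = int(rng.integers(0, W - fw + 1))
            y0 = int(rng.integers(0, H - fh + 1))
            prev_segment = seg
        else:  # smooth drift, at most 8 px per frame and axis
            x0 = int(np.clip(x0 + rng.integers(-8, 9), 0, W - fw))
            y0 = int(np.clip(y0 + rng.integers(-8, 9), 0, H - fh))
        frame = np.full((H, W, 3), 45, dtype=np.uint8)
        wall = (40 + 25 * np.linspace(0, 1, W))[None, :, None]
        frame = np.clip(frame + wall.astype(np.uint8) // 2, 0, 255)
        frame[y0:y0 + fh, x0:x0 + fw] = face
        frames.append(frame)
        sidecar.append({"frame_index": i, "x0": x0, "y0": y0,
                        "x1": x0 + fw, "y1": y0 + fh, "score": 1.0,
                        "identity_id": ident.id})
    return FrameStream(timestamps, frames, nominal_rate=fps), sidecar
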