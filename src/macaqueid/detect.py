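"""Pluggable face detection: a contract, a sidecar-replay fixture, and cropping.

The production system this mirrors used a fine-tuned object-detection CNN to
localize monkey faces.  Training such a detector is out of scope here; instead
any object satisfying :class:`DetectorContract` can be mounted, and
:class:`FixtureDetector` replays ground-truth boxes from a JSON sidecar so the
rest of the pipeline can be exercised deterministically.

Coordinates are 0-based and half-open: a box (x0, y0, x1, y1) covers columns
[x0, x1) and rows [y0, y1), so width = x1 - x0 exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from . import imaging

logger = logging.getLogger(__name__)


class DetectorError(ValueError):
    """A detector returned a box violating the bounding-box contract."""


class DegenerateCropError(ValueError):
    """A crop collapsed to (near) nothing after clipping to the frame."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned half-open pixel box with a confidence score in [0, 1]."""

    x0: int
    y0: int
    x1: int
    y1: int
    score: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise DetectorError(f"degenerate box {self}")
        if not (0.0 <= self.score <= 1.0):
            raise DetectorError(f"score outside [0, 1]: {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def clip(self, frame_h: int, frame_w: int) -> "BoundingBox":
        return BoundingBox(
            max(0, self.x0), max(0, self.y0),
            min(frame_w, self.x1), min(frame_h, self.y1),
            self.score,
        )

    def iou(self, other: "BoundingBox") -> float:
        ix = max(0, min(self.x1, other.x1) - max(self.x0, other.x0))
        iy = max(0, min(self.y1, other.y1) - max(self.y0, other.y0))
        inter = ix * iy
        union = self.width * self.height + other.width * other.height - inter
        return inter / union if union else 0.0


@runtime_checkable
class DetectorContract(Protocol):
    """Anything that maps a frame to candidate face boxes.

    Implementations must be deterministic for a fixed frame and return boxes
    satisfying the :class:`BoundingBox` invariants.  ``frame_index`` is passed
    through so replay-style detectors can key on it.
    """

    def detect(self, frame: np.ndarray, frame_index: int | None = None) -> list[BoundingBox]:
        ...


class FixtureDetector:
    """Replays ground-truth boxes from a JSON sidecar keyed by frame index.

    Sidecar format: a JSON array of objects with keys ``frame_index, x0, y0,
    x1, y1, score`` and optionally ``identity_id`` (kept for test fixtures).
    Frames absent from the sidecar yield no detections.
    """

    def __init__(self, sidecar: str | Path | list[dict]):
        if isinstance(sidecar, (str, Path)):
            records = json.loads(Path(sidecar).read_text())
        else:
            records = list(sidecar)
        self._by_frame: dict[int, list[dict]] = {}
        for rec in records:
            self._by_frame.setdefault(int(rec["frame_index"]), []).append(rec)

    def detect(self, frame: np.ndarray, frame_index: int | None = None) -> list[BoundingBox]:
        recs = self._by_frame.get(int(frame_index) if frame_index is not None else -1, [])
        return [
            BoundingBox(int(r["x0"]), int(r["y0"]), int(r["x1"]), int(r["y1"]),
                        float(r.get("score", 1.0)))
            for r in recs
        ]

    def identity_at(self, frame_index: int) -> str | None:
        """Ground-truth identity for a frame, when the sidecar records one."""
        recs = self._by_frame.get(int(frame_index), [])
        for r in recs:
            if "identity_id" in r:
                return str(r["identity_id"])
        return None


def detect_faces(
    frame: np.ndarray,
    detector: DetectorContract,
    frame_index: int | None = None,
) -> list[BoundingBox]:
    """Run a detector on one frame; validate, clip and sort its boxes.

    Returns boxes sorted by descending score.  A malformed box raises
    :class:`DetectorError` naming the offender.
    """
    h, w = frame.shape[:2]
    boxes = detector.detect(frame, frame_index)
    out: list[BoundingBox] = []
    for box in boxes:
        if not isinstance(box, BoundingBox):
            raise DetectorError(f"detector returned non-box object {box!r}")
        clipped = box.clip(h, w)
        out.append(clipped)
    return sorted(out, key=lambda b: -b.score)


def crop_and_preprocess(
    frame: np.ndarray,
    box: BoundingBox,
    shape: tuple[int, int] = imaging.CANONICAL_SHAPE,
) -> np.ndarray:
    """Extract a half-open crop and run the canonical preprocessing on it.

    Boxes reaching outside the frame are clipped (with a warning); a crop
    that degenerates to under 2 x 2 pixels after clipping is an error.
    """
    h, w = frame.shape[:2]
    clipped = box.clip(h, w)
    if (clipped.x0, clipped.y0, clipped.x1, clipped.y1) != (box.x0, box.y0, box.x1, box.y1):
        logger.warning("box %s clipped to frame bounds (%d x %d)", box, h, w)
    if clipped.width < 2 or clipped.height < 2:
        raise DegenerateCropError(f"crop degenerate after clipping: {clipped}")
    sub = frame[clipped.y0:clipped.y1, clipped.x0:clipped.x1]
    return imaging.preprocess(sub, shape)
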