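"""Near-real-time identification: frame pooling, confidence tables, voting.

Frames are pooled in fixed windows (0.5 s by default) and classified
together: each detected face crop yields a row of per-class confidences,
forming the window's frames x classes table.  Each row votes for its argmax
class and the window's identification is the modal vote — ties broken by
larger summed confidence across the tied classes, then lexicographic
identity order.  Windows with fewer than ``min_rows`` rows abstain rather
than fabricate an identity.  Updates advance every 0.5 s, so at the
defaults consecutive windows partition the timeline.

When several faces appear in one frame, detections are linked across the
window's frames into chains by box-overlap continuity (IoU >= 0.3); each
chain gets its own table and vote, and the window's primary result comes
from the chain with the most rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import detect as _detect
from .imaging import FrameStream

logger = logging.getLogger(__name__)

ABSTAIN = "ABSTAIN"
ALL = "ALL"


@dataclass
class SessionConfig:
    """Pooling window length, update cadence, and display-mode selection."""

    window: float = 0.5
    update_interval: float = 0.5
    selected_id: str = ALL
    min_rows: int = 1
    iou_link_threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.window <= 0 or self.update_interval <= 0:
            raise ValueError("window and update_interval must be > 0")


@dataclass
class ConfidenceTable:
    """Per-window matrix of frame confidences: frames in rows, classes in columns."""

    window_start: float
    classes: np.ndarray
    rows: np.ndarray  # (n_rows, n_classes), each row sums to 1
    frame_indices: list[int]
    boxes: list[_detect.BoundingBox] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return 0 if self.rows.size == 0 else self.rows.shape[0]


@dataclass
class IdentificationResult:
    """One window's identification: modal vote or abstention."""

    window_start: float
    predicted: str
    vote_counts: dict[str, int]
    aggregate_confidence: float
    boxes: list[_detect.BoundingBox] = field(default_factory=list)

    def to_record(self) -> dict:
        return {
            "window_start": round(float(self.window_start), 6),
            "predicted": self.predicted,
            "vote_counts": {k: int(v) for k, v in sorted(self.vote_counts.items())},
            "aggregate_confidence": round(float(self.aggregate_confidence), 9),
            "boxes": [[b.x0, b.y0, b.x1, b.y1, round(b.score, 6)] for b in self.boxes],
        }


def pool_window(stream: FrameStream, config: SessionConfig, start: float) -> list[tuple[int, float, np.ndarray]]:
    """Frames with timestamp in the half-open window [start, start + window).

    Returns (frame_index, timestamp, frame) triples; empty list for a gap.
    """
    t = stream.timestamps
    mask = (t >= start - 1e-9) & (t < start + config.window - 1e-9)
    return [(int(i), float(t[i]), stream.frames[i]) for i in np.flatnonzero(mask)]


def build_confidence_table(
    frames: list[tuple[int, float, np.ndarray]],
    detector: _detect.DetectorContract,
    pipeline,
    window_start: float = 0.0,
) -> ConfidenceTable:
    """Classify each frame's top detection into one confidence row.

    Per frame: detect -> crop_and_preprocess -> extract features ->
    per-class confidences.  Frames without a detection contribute no row;
    a detector or model failure skips the frame with a log message.
    """
    rows, indices, boxes = [], [], []
    for frame_index, _, frame in frames:
        try:
            dets = _detect.detect_faces(frame, detector, frame_index)
        except _detect.DetectorError as exc:
            logger.warning("detector failed on frame %d: %s", frame_index, exc)
            continue
        if not dets:
            continue
        box = dets[0]
        try:
            crop = _detect.crop_and_preprocess(frame, box)
            conf = pipeline.predict_confidence_images([crop])[0]
        except Exception as exc:
            logger.warning("classification failed on frame %d: %s", frame_index, exc)
            continue
        rows.append(conf)
        indices.append(frame_index)
        boxes.append(box)
    classes = np.asarray(pipeline.classes)
    mat = np.vstack(rows) if rows else np.zeros((0, len(classes)))
    return ConfidenceTable(window_start, classes, mat, indices, boxes)


def majority_vote(table: ConfidenceTable, min_rows: int = 1) -> IdentificationResult:
    """Vote each row's argmax class; the modal class wins.

    Ties are broken by the larger summed confidence over the tied classes,
    then lexicographic identity order.  Fewer than ``min_rows`` rows (or an
    empty table) abstains.
    """
    n = table.n_rows
    if n < min_rows or n == 0:
        return IdentificationResult(table.window_start, ABSTAIN, {}, 0.0,
                                    list(table.boxes))
    argmax = table.rows.argmax(axis=1)
    votes: dict[str, int] = {}
    for a in argmax:
        cls = str(table.classes[a])
        votes[cls] = votes.get(cls, 0) + 1
    top = max(votes.values())
    tied = [c for c, v in votes.items() if v == top]
    if len(tied) > 1:
        summed = {c: float(table.rows[:, list(table.classes).index(c)].sum())
                  for c in tied}
        best_sum = max(summed.values())
        tied = sorted(c for c in tied if summed[c] == best_sum)
    winner = sorted(tied)[0]
    col = list(table.classes).index(winner)
    agg = float(table.rows[argmax == col, col].mean()) if np.any(argmax == col) else 0.0
    return IdentificationResult(table.window_start, winner, votes, agg,
                                list(table.boxes))


def _split_chains(table: ConfidenceTable, all_rows: list[dict], iou_thr: float) -> list[ConfidenceTable]:
    """Link detections across frames into chains by IoU continuity."""
    chains: list[list[dict]] = []
    for rec in all_rows:
        placed = False
        for chain in chains:
            if rec["box"].iou(chain[-1]["box"]) >= iou_thr:
                chain.append(rec)
                placed = True
                break
        if not placed:
            chains.append([rec])
    out = []
    for chain in chains:
        out.append(ConfidenceTable(
            table.window_start, table.classes,
            np.vstack([r["conf"] for r in chain]),
            [r["frame_index"] for r in chain],
            [r["box"] for r in chain],
        ))
    return out


def run_session(
    stream: FrameStream,
    detector: _detect.DetectorContract,
    pipeline,
    config: SessionConfig = SessionConfig(),
    log_path: str | Path | None = None,
) -> tuple[list[IdentificationResult], list[dict]]:
    """Run the pooling/voting loop over a whole stream.

    One :class:`IdentificationResult` is produced per update tick.  When
    multiple detections occur per frame, detections are chained by IoU
    continuity and the chain with the most rows decides the window.  The
    result for window [t, t + window) depends only on frames with
    timestamp < t + window.

    Overlay events mirror the single-selected-identity display mode: with
    ``selected_id`` set, an event (bounding box of the last contributing
    frame) is emitted only for windows predicting that identity; with
    ``ALL``, for every non-abstaining window.

    Returns (results, overlay_events); writes a JSON-lines session log when
    ``log_path`` is given.
    """
    results: list[IdentificationResult] = []
    overlays: list[dict] = []
    if len(stream) == 0:
        return results, overlays
    t0 = float(stream.timestamps[0])
    t_end = float(stream.timestamps[-1])
    start = t0
    while start <= t_end + 1e-9:
        frames = pool_window(stream, config, start)
        # gather every detection per frame for chain splitting
        recs: list[dict] = []
        for frame_index, _, frame in frames:
            try:
                dets = _detect.detect_faces(frame, detector, frame_index)
            except _detect.DetectorError as exc:
                logger.warning("detector failed on frame %d: %s", frame_index, exc)
                continue
            for box in dets:
                try:
                    crop = _detect.crop_and_preprocess(frame, box)
                    conf = pipeline.predict_confidence_images([crop])[0]
                except Exception as exc:
                    logger.warning("frame %d skipped: %s", frame_index, exc)
                    continue
                recs.append({"frame_index": frame_index, "box": box, "conf": conf})
        classes = np.asarray(pipeline.classes)
        base = ConfidenceTable(start, classes, np.zeros((0, len(classes))), [])
        if recs:
            chains = _split_chains(base, recs, config.iou_link_threshold)
            # longest chain decides the window; earlier chain wins a tie
            primary = max(enumerate(chains), key=lambda t: (t[1].n_rows, -t[0]))[1]
            result = majority_vote(primary, config.min_rows)
        else:
            result = majority_vote(base, config.min_rows)
        results.append(result)
        if result.predicted != ABSTAIN and (
            config.selected_id == ALL or result.predicted == config.selected_id
        ):
            overlays.append({
                "window_start": round(start, 6),
                "predicted": result.predicted,
                "box": ([result.boxes[-1].x0, result.boxes[-1].y0,
                         result.boxes[-1].x1, result.boxes[-1].y1]
                        if result.boxes else None),
            })
        start = round(start + config.update_interval, 9)

    if log_path is not None:
        write_session_log(results, log_path)
    return results, overlays


def write_session_log(results: list[IdentificationResult], path: str | Path) -> None:
    """Persist a session as JSON-lines, one record per window (sorted keys,
    fixed float rounding, so identical sessions produce identical bytes)."""
    with open(path, "w") as fh:
        for r in results:
            fh.write(json.dumps(r.to_record(), sort_keys=True) + "\n")


class IdentificationPipeline:
    """A fitted extractor + trained classifier, the realtime inference unit."""

    def __init__(self, extractor, model):
        self.extractor = extractor
        self.model = model

    @property
    def classes(self) -> np.ndarray:
        return self.model.classes

    def predict_confidence_images(self, images: list[np.ndarray]) -> np.ndarray:
        feats = self.extractor.transform_images(images)
        return self.model.predict_confidence(feats)
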