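import itertools
import json

import numpy as np
import pytest

from macaqueid import detect, imaging, realtime
from macaqueid.realtime import ABSTAIN, ConfidenceTable, SessionConfig


class StubPipeline:
    """Deterministic pipeline: confidence follows the crop's mean intensity."""

    classes = np.array(["a", "b", "c"])

    def predict_confidence_images(self, images):
        out = []
        for im in images:
            m = float(np.mean(im))
            # brighter crops favor later classes
            logits = np.array([255 - m, m, m / 2])
            out.append(logits / logits.sum())
        return np.vstack(out)


def _stream(n_frames, fps=10.0, value=100):
    frames = [np.full((40, 30, 3), value, dtype=np.uint8) for _ in range(n_frames)]
    return imaging.FrameStream(np.arange(n_frames) / fps, frames, nominal_rate=fps)


def _full_box_sidecar(n_frames, w=30, h=40):
    return [{"frame_index": i, "x0": 0, "y0": 0, "x1": w, "y1": h, "score": 1.0}
            for i in range(n_frames)]


def _table(rows, classes=("a", "b", "c"), start=0.0):
    rows = np.asarray(rows, dtype=float)
    return ConfidenceTable(start, np.asarray(classes), rows,
                           list(range(len(rows))))


class TestPoolWindow:
    def test_ten_fps_half_second_window_pools_five(self):
        stream = _stream(30)
        cfg = SessionConfig()
        frames = realtime.pool_window(stream, cfg, 0.0)
        assert len(frames) == 5
        assert [f[0] for f in frames] == [0, 1, 2, 3, 4]

    def test_gap_yields_empty_window(self):
        stream = _stream(10)
        assert realtime.pool_window(stream, SessionConfig(), 5.0) == []

    def test_consecutive_windows_partition_timeline(self):
        stream = _stream(30)
        cfg = SessionConfig()
        seen = []
        for k in range(6):
            seen.extend(f[0] for f in realtime.pool_window(stream, cfg, 0.5 * k))
        assert seen == list(range(30))


class TestBuildConfidenceTable:
    def test_all_frames_detected_gives_full_table(self):
        stream = _stream(5)
        det = detect.FixtureDetector(_full_box_sidecar(5))
        frames = [(i, float(i) / 10, stream.frames[i]) for i in range(5)]
        table = realtime.build_confidence_table(frames, det, StubPipeline())
        assert table.n_rows == 5
        assert np.allclose(table.rows.sum(axis=1), 1.0, atol=1e-9)

    def test_undetected_frames_contribute_no_row(self):
        stream = _stream(5)
        det = detect.FixtureDetector(_full_box_sidecar(3))  # frames 3, 4 missing
        frames = [(i, float(i) / 10, stream.frames[i]) for i in range(5)]
        table = realtime.build_confidence_table(frames, det, StubPipeline())
        assert table.n_rows == 3
        assert table.frame_indices == [0, 1, 2]

    def test_single_frame_table_equals_direct_prediction(self):
        stream = _stream(1, value=130)
        det = detect.FixtureDetector(_full_box_sidecar(1))
        table = realtime.build_confidence_table([(0, 0.0, stream.frames[0])],
                                                det, StubPipeline())
        crop = detect.crop_and_preprocess(stream.frames[0],
                                          detect.BoundingBox(0, 0, 30, 40))
        direct = StubPipeline().predict_confidence_images([crop])[0]
        assert np.allclose(table.rows[0], direct)


def brute_force_vote(rows, classes):
    """Independent reimplementation of the voting + tie rules."""
    argmax = [int(np.argmax(r)) for r in rows]
    counts = {}
    for a in argmax:
        counts[a] = counts.get(a, 0) + 1
    top = max(counts.values())
    tied = [c for c, v in counts.items() if v == top]
    if len(tied) > 1:
        sums = {c: sum(r[c] for r in rows) for c in tied}
        m = max(sums.values())
        tied = [c for c in tied if sums[c] == m]
    return classes[min(tied, key=lambda c: classes[c])]


class TestMajorityVote:
    def test_clear_majority(self):
        rows = [[.8, .1, .1]] * 3 + [[.1, .8, .1]] + [[.7, .2, .1]]
        result = realtime.majority_vote(_table(rows))
        assert result.predicted == "a"
        assert result.vote_counts == {"a": 4, "b": 1}

    def test_empty_table_abstains(self):
        result = realtime.majority_vote(_table(np.zeros((0, 3))))
        assert result.predicted == ABSTAIN

    def test_min_rows_abstention(self):
        result = realtime.majority_vote(_table([[.5, .3, .2]]), min_rows=3)
        assert result.predicted == ABSTAIN

    def test_two_way_tie_broken_by_summed_confidence(self):
        rows = [[.9, .05, .05], [.8, .15, .05], [.15, .8, .05], [.15, .7, .15]]
        # votes a: 2, b: 2; summed conf a = 1.7+... vs b
        result = realtime.majority_vote(_table(rows))
        sums = np.asarray(rows).sum(axis=0)
        expected = "a" if sums[0] > sums[1] else "b"
        assert result.predicted == expected

    def test_exact_tie_falls_back_to_lexicographic(self):
        rows = [[.6, .4, 0], [.4, .6, 0]]
        result = realtime.majority_vote(_table(rows))
        assert result.predicted == "a"

    def test_vote_count_conservation(self, rng):
        for _ in range(20):
            rows = rng.dirichlet(np.ones(3), size=int(rng.integers(1, 8)))
            result = realtime.majority_vote(_table(rows))
            assert sum(result.vote_counts.values()) == len(rows)

    def test_agrees_with_bruteforce_over_all_patterns(self):
        """Every argmax pattern of a 5-frame, 3-class table."""
        classes = np.array(["a", "b", "c"])
        conf = {0: [.6, .25, .15], 1: [.2, .65, .15], 2: [.1, .2, .7]}
        for pattern in itertools.product(range(3), repeat=5):
            rows = np.array([conf[p] for p in pattern])
            expected = brute_force_vote(rows, classes)
            got = realtime.majority_vote(_table(rows)).predicted
            assert got == expected, pattern


class TestRunSession:
    def _session_inputs(self, n_frames=30):
        stream = _stream(n_frames)
        det = detect.FixtureDetector(_full_box_sidecar(n_frames))
        return stream, det, StubPipeline()

    def test_one_result_per_update_tick(self):
        stream, det, pipe = self._session_inputs(30)
        results, _ = realtime.run_session(stream, det, pipe)
        assert len(results) == 6  # ticks 0.0, 0.5, ..., 2.5
        assert [r.window_start for r in results] == [0.0, 0.5, 1.0, 1.5, 2.0, 2.5]

    def test_replay_is_byte_identical(self, tmp_path):
        stream, det, pipe = self._session_inputs(30)
        realtime.run_session(stream, det, pipe, log_path=tmp_path / "a.jsonl")
        realtime.run_session(stream, det, pipe, log_path=tmp_path / "b.jsonl")
        assert (tmp_path / "a.jsonl").read_bytes() == (tmp_path / "b.jsonl").read_bytes()

    def test_selected_id_never_predicted_gives_no_overlays(self):
        stream, det, pipe = self._session_inputs(20)
        cfg = SessionConfig(selected_id="zzz")
        results, overlays = realtime.run_session(stream, det, pipe, cfg)
        assert overlays == []
        assert len(results) == 4

    def test_selected_all_gives_overlay_per_identified_window(self):
        stream, det, pipe = self._session_inputs(20)
        results, overlays = realtime.run_session(stream, det, pipe)
        named = [r for r in results if r.predicted != ABSTAIN]
        assert len(overlays) == len(named)

    def test_empty_stream_ends_normally(self):
        stream = imaging.FrameStream(np.empty(0), [], nominal_rate=10.0)
        results, overlays = realtime.run_session(
            stream, detect.FixtureDetector([]), StubPipeline())
        assert results == [] and overlays == []

    def test_log_records_parse_back(self, tmp_path):
        stream, det, pipe = self._session_inputs(10)
        results, _ = realtime.run_session(stream, det, pipe,
                                          log_path=tmp_path / "s.jsonl")
        lines = (tmp_path / "s.jsonl").read_text().splitlines()
        assert len(lines) == len(results)
        rec = json.loads(lines[0])
        assert set(rec) == {"window_start", "predicted", "vote_counts",
                            "aggregate_confidence", "boxes"}
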