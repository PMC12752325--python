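import numpy as np
import pandas as pd
import pytest

from reachkin import (
    LANDMARK_NAMES,
    ParticipantInfo,
    SimConfig,
    adapt_pose33,
    preprocess,
    read_landmark_csv,
    reference_cohort,
    simulate_cohort,
    write_landmark_csv,
)
from reachkin.errors import EmptySeriesError, FormatError, ValidationError
from reachkin.landmark_io import pose33_indices, read_participants_csv, write_participants_csv

from conftest import make_series


def _minimal_rows(n_frames=2, fps=30.0):
    rows = []
    for f in range(n_frames):
        for j, name in enumerate(LANDMARK_NAMES):
            rows.append(
                {"participant_id": "P1", "day": 1, "block": 1, "frame": f, "fps": fps,
                 "landmark": name, "x": 10.0 * j + f, "y": 5.0 * j, "visibility": 1.0}
            )
    return pd.DataFrame(rows)


class TestReadWrite:
    def test_minimal_well_formed_file(self, tmp_path):
        path = tmp_path / "lm.csv"
        _minimal_rows(2).to_csv(path, index=False)
        series = read_landmark_csv(path)
        assert len(series) == 1
        assert series[0].n_frames == 2
        assert series[0].fps == 30.0

    def test_missing_column_names_column(self, tmp_path):
        path = tmp_path / "lm.csv"
        _minimal_rows().drop(columns=["visibility"]).to_csv(path, index=False)
        with pytest.raises(FormatError, match="visibility"):
            read_landmark_csv(path)

    def test_unknown_landmark_rejected(self, tmp_path):
        df = _minimal_rows()
        df.loc[0, "landmark"] = "nose"
        path = tmp_path / "lm.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="nose"):
            read_landmark_csv(path)

    def test_non_constant_fps_rejected(self, tmp_path):
        df = _minimal_rows()
        df.loc[df["frame"] == 1, "fps"] = 60.0
        path = tmp_path / "lm.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="fps"):
            read_landmark_csv(path)

    def test_empty_collection_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_landmark_csv([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].split(",")[0] == "participant_id"

    def test_row_count_is_frames_times_landmarks(self, tmp_path):
        series = make_series({"pinky": np.zeros((5, 2))})
        path = tmp_path / "lm.csv"
        write_landmark_csv([series], path)
        assert len(pd.read_csv(path)) == 5 * 8

    def test_round_trip_on_simulated_session(self, tmp_path):
        cfg = SimConfig(n_participants=2, days=2, blocks_per_day=2,
                        movements_per_block=3, seed=5)
        series, _, _ = simulate_cohort(cfg)
        path = tmp_path / "lm.csv"
        write_landmark_csv(series, path)
        back = read_landmark_csv(path)
        assert len(back) == len(series)
        by_key = {(s.participant_id, s.day, s.block): s for s in back}
        for s in series:
            r = by_key[(s.participant_id, s.day, s.block)]
            assert r.fps == s.fps
            np.testing.assert_array_equal(r.frame_index, s.frame_index)
            np.testing.assert_array_equal(r.x, s.x)
            np.testing.assert_array_equal(r.y, s.y)
            np.testing.assert_array_equal(r.visibility, s.visibility)

    def test_frame_range_filter(self, tmp_path):
        path = tmp_path / "lm.csv"
        _minimal_rows(6).to_csv(path, index=False)
        (series,) = read_landmark_csv(path, frame_range=(2, 5))
        np.testing.assert_array_equal(series.frame_index, [2, 3, 4])

    def test_participants_round_trip(self, tmp_path):
        cohort = reference_cohort()
        path = tmp_path / "meta.csv"
        write_participants_csv(cohort, path)
        back = read_participants_csv(path)
        assert back == cohort


class TestAdaptPose33:
    @staticmethod
    def _records(n, signal=None):
        records = []
        for f in range(n):
            lms = [{"x": 0.5, "y": 0.5, "visibility": 1.0} for _ in range(33)]
            if signal is not None:
                lms[11] = {"x": signal[f, 0], "y": signal[f, 1], "visibility": 1.0}
                lms[12] = {"x": signal[f, 0], "y": signal[f, 1], "visibility": 1.0}
            records.append({"frame": f, "landmarks": lms})
        return records

    def test_left_paretic_uses_left_source_indices(self):
        idx = pose33_indices("L")
        assert (idx["pinky"], idx["index"], idx["wrist"], idx["elbow"]) == (17, 19, 15, 13)
        assert pose33_indices("R")["wrist"] == 16

    def test_normalized_to_pixel_scaling(self, participant):
        series = adapt_pose33(self._records(1), participant, 30.0, (1920, 1080))
        assert series.x[0, 0] == pytest.approx(960.0)
        assert series.y[0, 0] == pytest.approx(540.0)

    def test_shoulder_signal_recovered(self, participant):
        rng = np.random.default_rng(0)
        signal = rng.uniform(0.2, 0.8, size=(20, 2))
        series = adapt_pose33(self._records(20, signal), participant, 30.0, (1000, 500))
        j = LANDMARK_NAMES.index("shoulder_left")
        np.testing.assert_allclose(series.x[:, j], signal[:, 0] * 1000, rtol=1e-12)
        np.testing.assert_allclose(series.y[:, j], signal[:, 1] * 500, rtol=1e-12)

    def test_bad_frame_size_rejected(self, participant):
        with pytest.raises(ValidationError):
            adapt_pose33(self._records(1), participant, 30.0, (0, 1080))

    def test_missing_landmark_flagged_not_fatal(self, participant):
        records = self._records(2)
        records[1]["landmarks"] = records[1]["landmarks"][:11]  # truncated frame
        series = adapt_pose33(records, participant, 30.0, (100, 100))
        assert series.visibility[1].min() == 0.0
        assert series.visibility[0].min() == 1.0


class TestPreprocess:
    def test_full_visibility_is_identity(self):
        series = make_series({"pinky": np.arange(10.0).reshape(5, 2)})
        out = preprocess(series, visibility_threshold=0.5, max_gap=2)
        np.testing.assert_array_equal(out.x, series.x)
        np.testing.assert_array_equal(out.frame_index, series.frame_index)
        assert out.n_interpolated == 0 and out.n_dropped == 0

    def test_threshold_zero_is_identity_even_with_zero_visibility(self):
        vis = np.zeros((4, 8))
        series = make_series({"pinky": np.zeros((4, 2))}, visibility=vis)
        out = preprocess(series, visibility_threshold=0.0, max_gap=2)
        np.testing.assert_array_equal(out.x, series.x)
        assert out.n_frames == 4

    def test_single_gap_midpoint_interpolation(self):
        xy = np.array([[0.0, 0.0], [999.0, 999.0], [10.0, 20.0]])
        vis = np.ones((3, 8))
        vis[1, 0] = 0.1  # pinky occluded in the middle frame
        series = make_series({"pinky": xy}, visibility=vis)
        out = preprocess(series, visibility_threshold=0.5, max_gap=1)
        assert out.n_frames == 3
        assert out.x[1, 0] == pytest.approx(5.0)
        assert out.y[1, 0] == pytest.approx(10.0)
        assert out.n_interpolated == 1

    def test_long_gap_dropped(self):
        vis = np.ones((6, 8))
        vis[1:4, 0] = 0.0  # 3-frame run > max_gap
        series = make_series({"pinky": np.zeros((6, 2))}, visibility=vis)
        out = preprocess(series, visibility_threshold=0.5, max_gap=2)
        np.testing.assert_array_equal(out.frame_index, [0, 4, 5])
        assert out.n_dropped == 3

    def test_all_frames_dropped_raises(self):
        vis = np.zeros((3, 8))
        series = make_series({"pinky": np.zeros((3, 2))}, visibility=vis)
        with pytest.raises(EmptySeriesError):
            preprocess(series, visibility_threshold=0.5, max_gap=1)

    def test_random_masking_conservation(self):
        rng = np.random.default_rng(3)
        n = 400
        xy = rng.uniform(0, 100, size=(n, 2))
        vis = np.ones((n, 8))
        vis[rng.random((n, 8)) < 0.05] = 0.0
        series = make_series({"pinky": xy}, visibility=vis)
        out = preprocess(series, visibility_threshold=0.5, max_gap=5)
        assert np.isfinite(out.x).all() and np.isfinite(out.y).all()
        assert out.n_frames + out.n_dropped == n
        # never invents frames
        assert set(out.frame_index) <= set(series.frame_index)
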