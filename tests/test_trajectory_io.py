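import io

import numpy as np
import pandas as pd
import pytest

from axokin.trajectory_io import (
    LANDMARKS,
    CalibrationSpec,
    IndividualMeta,
    LandmarkTrajectory,
    PoseTableError,
    fill_low_confidence,
    read_pose_table,
    write_kinematics_table,
    read_kinematics_table,
)
from conftest import write_pose_csv


def _simple_landmarks(n=100, names=LANDMARKS):
    rng = np.random.default_rng(0)
    return {
        name: {"x": rng.uniform(0, 500, n), "y": rng.uniform(0, 500, n),
               "likelihood": np.ones(n)}
        for name in names
    }


class TestReadPoseTable:
    def test_time_base_and_shape(self, tmp_path):
        path = write_pose_csv(tmp_path / "b.csv", _simple_landmarks(100))
        traj = read_pose_table(path, fps=1000,
                               calibration=CalibrationSpec(50.0))
        assert traj.n_frames == 100
        assert traj.t[0] == 0.0
        assert traj.t[-1] == pytest.approx(0.099)
        assert set(traj.landmarks) == set(LANDMARKS)

    def test_linear_calibration(self, tmp_path):
        lm = _simple_landmarks(5)
        lm["e"]["x"][:] = 100.0
        lm["e"]["y"][:] = 200.0
        path = write_pose_csv(tmp_path / "b.csv", lm)
        traj = read_pose_table(path, fps=1000,
                               calibration=CalibrationSpec(50.0, 0.5))
        assert traj.scale == pytest.approx(0.01)
        assert traj.landmarks["e"][0, 0] == pytest.approx(1.0)
        assert traj.landmarks["e"][0, 1] == pytest.approx(2.0)

    def test_missing_bodypart_named_in_error(self, tmp_path):
        lm = _simple_landmarks(10, names=[n for n in LANDMARKS if n != "hd2"])
        path = write_pose_csv(tmp_path / "b.csv", lm)
        with pytest.raises(PoseTableError, match="hd2"):
            read_pose_table(path, fps=1000, calibration=CalibrationSpec(50.0))

    def test_alias_map_renames_bodyparts(self, tmp_path):
        lm = _simple_landmarks(10)
        lm["eye_left"] = lm.pop("e")
        path = write_pose_csv(tmp_path / "b.csv", lm)
        traj = read_pose_table(path, fps=1000,
                               calibration=CalibrationSpec(50.0),
                               aliases={"eye_left": "e"})
        assert "e" in traj.landmarks

    def test_bad_header_is_dialect_error(self):
        with pytest.raises(PoseTableError):
            read_pose_table(io.StringIO("a,b\n1,2\n"), fps=1000,
                            calibration=CalibrationSpec(50.0))

    def test_calibration_scale_invariance(self, tmp_path):
        """Scaling pixels and pixels_per_square together leaves cm fixed."""
        lm = _simple_landmarks(20)
        p1 = write_pose_csv(tmp_path / "a.csv", lm)
        lm2 = {k: {"x": v["x"] * 3.0, "y": v["y"] * 3.0,
                   "likelihood": v["likelihood"]} for k, v in lm.items()}
        p2 = write_pose_csv(tmp_path / "b.csv", lm2)
        t1 = read_pose_table(p1, fps=1000, calibration=CalibrationSpec(50.0))
        t2 = read_pose_table(p2, fps=1000, calibration=CalibrationSpec(150.0))
        for name in LANDMARKS:
            assert np.allclose(t1.landmarks[name][:, :2],
                               t2.landmarks[name][:, :2], atol=1e-9)


class TestFillLowConfidence:
    def _traj(self, conf, xy=None, n=None):
        n = n or len(conf)
        landmarks = {}
        for name in LANDMARKS:
            arr = np.column_stack([
                np.arange(n, dtype=float) if xy is None else xy.copy(),
                np.zeros(n),
                np.asarray(conf, dtype=float),
            ])
            landmarks[name] = arr
        return LandmarkTrajectory(
            bout_id="b", individual_id="i", stage="larva", fps=1000.0,
            scale=0.01, t=np.arange(n) / 1000.0, landmarks=landmarks)

    def test_full_confidence_is_identity(self):
        traj = self._traj(np.ones(50))
        out = fill_low_confidence(traj)
        for name in LANDMARKS:
            assert np.array_equal(out.landmarks[name], traj.landmarks[name])

    def test_single_gap_linear_interpolation(self):
        conf = np.ones(5)
        conf[2] = 0.1
        xy = np.array([0.0, 0.0, 99.0, 2.0, 2.0])
        traj = self._traj(conf, xy=xy)
        out = fill_low_confidence(traj, min_confidence=0.9, max_gap=3)
        assert out.usable
        assert out.landmarks["e"][2, 0] == pytest.approx(1.0)

    def test_long_gap_flags_bout(self):
        conf = np.ones(100)
        conf[20:75] = 0.0
        traj = self._traj(conf)
        out = fill_low_confidence(traj, max_gap=10)
        assert not out.usable
        assert any("max_gap" in f for f in out.flags)

    def test_boundary_gap_longer_than_max_flags(self):
        conf = np.ones(60)
        conf[:30] = 0.0
        out = fill_low_confidence(self._traj(conf), max_gap=10)
        assert not out.usable

    def test_invalid_threshold_raises(self):
        with pytest.raises(ValueError):
            fill_low_confidence(self._traj(np.ones(10)), min_confidence=1.5)


class TestKinematicsTable:
    def test_round_trip(self, tmp_path, noiseless_bout):
        _, _, record = noiseless_bout
        path = tmp_path / "k.csv"
        written = write_kinematics_table([record, record], path)
        assert len(written) == 2
        back = read_kinematics_table(path)
        for col in written.columns:
            if written[col].dtype.kind == "f":
                assert np.allclose(back[col], written[col], rtol=1e-12)
            else:
                assert (back[col] == written[col]).all()

    def test_empty_records_gives_header_only(self, tmp_path):
        path = tmp_path / "k.csv"
        write_kinematics_table([], path)
        back = pd.read_csv(path)
        assert len(back) == 0
        assert "MG" in back.columns and "PCD" in back.columns


class TestIndividualMeta:
    def test_svl_is_mean_of_measurements(self):
        meta = IndividualMeta("i1", "adult", [8.0, 8.4, 8.6])
        assert meta.svl == pytest.approx(25.0 / 3.0)

    @pytest.mark.parametrize("stage, svls", [
        ("hatchling", [2.0]), ("larva", []), ("larva", [2.0, -1.0]),
    ])
    def test_validation(self, stage, svls):
        with pytest.raises(ValueError):
            IndividualMeta("i1", stage, svls)
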