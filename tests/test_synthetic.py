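"""The synthetic gait generator: trajectory construction guarantees,
internal consistency of emitted derivatives, sensor-corruption algebra and
CSV round-tripping."""

import numpy as np
import pytest

from footclear import (
    GaitProfile,
    IMURecording,
    SensorErrorModel,
    apply_calibration,
    CalibrationModel,
    estimate_initial_tilt,
    make_trajectory,
    read_recording,
    synthesize_imu,
    write_recording,
)
from footclear.exceptions import RecordingFormatError
from footclear.orientation import GRAVITY, initial_tilt_matrix

FS = 200.0


def grid_profile(**kw):
    """Profile whose swing midpoint lands exactly on the sample grid."""
    base = dict(
        n_strides=5, stride_duration=1.0, foot_flat_fraction=0.30,
        peak_clearance=0.20, stationary_lead=2.0,
    )
    base.update(kw)
    return GaitProfile(**base)


class TestTrajectory:
    def test_zero_peak_clearance_is_identically_zero(self):
        truth = make_trajectory(grid_profile(peak_clearance=0.0), FS)
        assert np.all(truth.clearance_true == 0.0)

    def test_peak_value_and_swing_count(self):
        truth = make_trajectory(grid_profile(), FS)
        assert abs(truth.clearance_true.max() - 0.20) < 1e-9
        h = truth.clearance_true
        maxima = np.sum((h[1:-1] > h[:-2]) & (h[1:-1] > h[2:]))
        assert maxima == 5

    def test_second_difference_matches_analytic_acceleration(self):
        # independent finite-difference oracle (4th-order central stencil)
        truth = make_trajectory(grid_profile(), FS)
        h = truth.clearance_true
        dt = 1.0 / FS
        stencil = (
            -h[:-4] + 16 * h[1:-3] - 30 * h[2:-2] + 16 * h[3:-1] - h[4:]
        ) / (12 * dt**2)
        assert np.max(np.abs(stencil - truth.accel_vertical_true[2:-2])) < 1e-3

    def test_foot_flat_consistency(self):
        truth = make_trajectory(grid_profile(), FS)
        assert np.all(truth.clearance_true[truth.foot_flat_mask] == 0.0)
        assert np.all(truth.velocity_true[truth.foot_flat_mask] == 0.0)
        assert np.all(truth.clearance_true >= 0.0)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            make_trajectory(grid_profile(), 20.0)  # fs too low
        with pytest.raises(ValueError):
            GaitProfile(stride_duration=-1.0)
        with pytest.raises(ValueError):
            GaitProfile(foot_flat_fraction=1.5)
        with pytest.raises(ValueError):
            GaitProfile(stationary_lead=0.2)

    def test_per_stride_peaks_for_obstacles(self):
        peaks = (0.1, 0.4, 0.1, 0.3, 0.1)
        truth = make_trajectory(grid_profile(peak_clearance=peaks), FS)
        assert abs(truth.clearance_true.max() - 0.4) < 1e-9


class TestSynthesizeIMU:
    def test_gravity_only_with_perfect_sensor(self):
        profile = grid_profile(
            n_strides=1, peak_clearance=0.0, peak_pitch_rate=0.0,
            walking_speed=0.0,
        )
        truth = make_trajectory(profile, FS)
        rec = synthesize_imu(truth, SensorErrorModel.ideal())
        assert np.allclose(rec.accel[0], GRAVITY, atol=1e-12)
        assert np.allclose(rec.accel[1:], 0.0, atol=1e-12)
        assert np.allclose(rec.gyro, 0.0, atol=1e-12)

    @pytest.mark.parametrize("pitch,roll", [(0.15, 0.0), (0.1, -0.08)])
    def test_mount_rotation_recovered_by_tilt_formulas(self, pitch, roll):
        profile = grid_profile(
            n_strides=1, peak_clearance=0.0, peak_pitch_rate=0.0,
            walking_speed=0.0,
        )
        truth = make_trajectory(profile, FS)
        err = SensorErrorModel.ideal()
        err.mount_pitch, err.mount_roll = pitch, roll
        rec = synthesize_imu(truth, err)
        sg = rec.accel[:, 0]
        expected = initial_tilt_matrix(pitch, roll).T @ np.array([GRAVITY, 0, 0])
        assert np.allclose(sg, expected, atol=1e-12)
        tilt = estimate_initial_tilt(sg)
        assert abs(tilt.theta_z0 - pitch) < 1e-10
        assert abs(tilt.theta_y0 - roll) < 1e-10
        assert np.allclose(tilt.matrix @ sg, [GRAVITY, 0, 0], atol=1e-9)

    def test_scale_bias_corruption_is_algebraic_inverse(self, truth_normal):
        S0 = np.diag([1.02, 0.98, 1.01])
        B0 = np.array([0.1, -0.05, 0.02])
        err = SensorErrorModel.ideal()
        err.scale_true, err.bias_true = S0, B0
        rec = synthesize_imu(truth_normal, err)
        restored = apply_calibration(
            CalibrationModel(S=S0, B=B0, residual=0.0), rec.accel
        )
        clean = synthesize_imu(truth_normal, SensorErrorModel.ideal())
        assert np.allclose(restored, clean.accel, atol=1e-12)

    def test_reproducibility_same_seed(self, truth_normal):
        a = synthesize_imu(truth_normal, SensorErrorModel(seed=7))
        b = synthesize_imu(truth_normal, SensorErrorModel(seed=7))
        assert np.array_equal(a.accel, b.accel)
        assert np.array_equal(a.gyro, b.gyro)
        c = synthesize_imu(truth_normal, SensorErrorModel(seed=8))
        assert not np.array_equal(a.accel, c.accel)


class TestRecordingIO:
    def test_roundtrip_bitwise(self, tmp_path, default_recording):
        path = tmp_path / "rec.csv"
        write_recording(default_recording, path)
        back = read_recording(path)
        assert np.array_equal(back.accel, default_recording.accel)
        assert np.array_equal(back.gyro, default_recording.gyro)
        assert np.array_equal(back.time, default_recording.time)

    def test_missing_gyro_column_named(self, tmp_path, default_recording):
        path = tmp_path / "rec.csv"
        write_recording(default_recording, path)
        text = path.read_text().replace("gz", "qq")
        path.write_text(text)
        with pytest.raises(RecordingFormatError, match="gz"):
            read_recording(path)

    def test_repeated_timestamp_reports_index(self, tmp_path):
        path = tmp_path / "rec.csv"
        path.write_text(
            "t,ax,ay,az,gx,gy,gz\n"
            "0.000,9.81,0,0,0,0,0\n"
            "0.005,9.81,0,0,0,0,0\n"
            "0.005,9.81,0,0,0,0,0\n"
            "0.010,9.81,0,0,0,0,0\n"
        )
        with pytest.raises(RecordingFormatError, match="2"):
            read_recording(path)

    def test_nonuniform_sampling_rejected(self):
        t = np.array([0.0, 0.005, 0.02, 0.025])
        with pytest.raises(RecordingFormatError, match="non-uniform"):
            IMURecording(t, np.zeros((3, 4)), np.zeros((3, 4)), 200.0)
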