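"""Synthetic gait trajectories and the corrupted IMU signals they imply.

The generator builds an analytically differentiable vertical trajectory of
the ankle-mounted sensor — a stationary lead, then alternating swing bumps
and foot-flat phases — together with the matching sagittal-plane pitch
rotation and forward progression. From that ground truth it synthesizes
the raw sensor channels by running the measurement chain backwards:
project gravity plus linear acceleration into the (possibly misaligned)
sensor frame, then corrupt with the inverse of the accelerometer
scale/bias model, gyroscope bias, and additive Gaussian noise.

Shapes
------
The swing bump is raised-cosine-squared, ``h(s) = P sin^4(pi s)`` with
``s`` the normalized swing time: it is C2 at the flat boundaries, which
matches the smooth-within-stride assumption behind the linear de-drift.
The pitch rate uses the zero-net-rotation shape ``2 A sin^3 cos``, so the
foot returns to flat at every heel strike; the forward displacement uses a
cycloidal profile. All derivatives are available in closed form, so the
emitted accelerations are exact, not finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import RecordingFormatError
from .orientation import GRAVITY, initial_tilt_matrix
from .preprocessing import IMURecording

__all__ = [
    "GaitProfile",
    "SensorErrorModel",
    "GroundTruth",
    "PROFILES",
    "make_trajectory",
    "synthesize_imu",
    "synthesize_static_set",
    "write_recording",
    "read_recording",
    "write_ground_truth",
    "read_ground_truth",
]

# peak of the zero-net pitch-rate shape 2 sin^3(u) cos(u), attained at u = pi/3
_RATE_SHAPE_PEAK = 3.0 * np.sqrt(3.0) / 8.0


@dataclass(frozen=True)
class GaitProfile:
    """Kinematic description of a synthetic walking trial.

    Attributes
    ----------
    n_strides : int
        Number of swing/foot-flat cycles after the stationary lead.
    stride_duration : float
        Stride period in seconds (swing + foot-flat).
    foot_flat_fraction : float
        Fraction of the stride spent in full ground contact, in (0, 1).
    peak_clearance : float or sequence of float
        Peak heel height per stride in metres; a sequence (one value per
        stride) emulates obstacle crossing.
    peak_pitch_rate : float
        Peak sagittal angular rate during swing, rad/s.
    walking_speed : float
        Mean forward speed in m/s (advance per stride = speed * duration).
    stationary_lead : float
        Initial still period in seconds (>= 1 s; the pipeline requires it).
    heel_pivot_duration : float
        Optional rotation-without-translation phase before the first swing,
        emulating the stance ankle rocking about the heel before heel-off.
    """

    n_strides: int = 5
    stride_duration: float = 1.1
    foot_flat_fraction: float = 0.35
    peak_clearance: float | tuple = 0.20
    peak_pitch_rate: float = 4.5
    walking_speed: float = 1.0
    stationary_lead: float = 2.0
    heel_pivot_duration: float = 0.0

    def __post_init__(self):
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if self.stride_duration <= 0:
            raise ValueError("stride_duration must be positive")
        if not 0.0 < self.foot_flat_fraction < 1.0:
            raise ValueError("foot_flat_fraction must be in (0, 1)")
        if self.stationary_lead < 1.0:
            raise ValueError(
                "stationary_lead must be >= 1 s (the pipeline needs an "
                "initial still period)"
            )
        if self.heel_pivot_duration < 0:
            raise ValueError("heel_pivot_duration must be >= 0")
        if np.any(np.asarray(self.stride_peaks()) < 0):
            raise ValueError("peak_clearance must be >= 0")

    def stride_peaks(self) -> np.ndarray:
        """Per-stride peak clearance, broadcast to ``n_strides`` values."""
        peaks = np.atleast_1d(np.asarray(self.peak_clearance, dtype=float))
        if peaks.size == 1:
            return np.full(self.n_strides, peaks[0])
        if peaks.size != self.n_strides:
            raise ValueError(
                f"peak_clearance has {peaks.size} values for "
                f"{self.n_strides} strides"
            )
        return peaks


#: Preset walking conditions: normal / fast / obstacle-crossing.
PROFILES: dict[str, GaitProfile] = {
    "normal": GaitProfile(),
    "fast": GaitProfile(
        stride_duration=0.85,
        foot_flat_fraction=0.30,
        peak_clearance=0.22,
        peak_pitch_rate=6.5,
        walking_speed=1.7,
    ),
    "obstacle": GaitProfile(
        stride_duration=1.3,
        foot_flat_fraction=0.35,
        peak_clearance=(0.20, 0.45, 0.20, 0.40, 0.20),
        peak_pitch_rate=5.0,
        walking_speed=1.0,
    ),
}


@dataclass
class SensorErrorModel:
    """Ground-truth sensor imperfections applied when synthesizing raw data.

    ``scale_true`` and ``bias_true`` are the true counterparts of the
    calibration model: the emitted reading is
    ``Am = scale_true^-1 @ SA + bias_true + noise`` so that applying the
    calibration ``A = S (Am - B)`` with ``S = scale_true, B = bias_true``
    restores the uncorrupted signal exactly. ``mount_pitch``/``mount_roll``
    are the true tilt angles of the sensor on the foot (rad).
    """

    scale_true: np.ndarray = field(
        default_factory=lambda: np.diag([1.02, 0.98, 1.01])
    )
    bias_true: np.ndarray = field(
        default_factory=lambda: np.array([0.1, -0.05, 0.02])
    )
    gyro_bias: np.ndarray = field(
        default_factory=lambda: np.array([0.01, -0.02, 0.03])
    )
    accel_noise_sd: float = 0.05
    gyro_noise_sd: float = 0.01
    mount_pitch: float = np.deg2rad(5.0)
    mount_roll: float = np.deg2rad(3.0)
    seed: int = 0

    def __post_init__(self):
        self.scale_true = np.asarray(self.scale_true, dtype=float)
        self.bias_true = np.asarray(self.bias_true, dtype=float)
        self.gyro_bias = np.asarray(self.gyro_bias, dtype=float)
        if abs(np.linalg.det(self.scale_true)) < 1e-12:
            raise ValueError("scale_true must be invertible")
        if self.accel_noise_sd < 0 or self.gyro_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @classmethod
    def ideal(cls, seed: int = 0) -> "SensorErrorModel":
        """A perfect sensor: identity scale, zero biases/noise, aligned mount."""
        return cls(
            scale_true=np.eye(3),
            bias_true=np.zeros(3),
            gyro_bias=np.zeros(3),
            accel_noise_sd=0.0,
            gyro_noise_sd=0.0,
            mount_pitch=0.0,
            mount_roll=0.0,
            seed=seed,
        )


@dataclass
class GroundTruth:
    """Noise-free kinematic truth for one synthetic trial.

    ``orientation_true`` holds foot-to-global rotations (the sensor mount
    misalignment is part of :class:`SensorErrorModel`, not of the
    trajectory). ``accel_global_true`` rows are [vertical (X), forward (Y),
    lateral (Z)] gravity-free acceleration.
    """

    time: np.ndarray
    fs: float
    clearance_true: np.ndarray
    velocity_true: np.ndarray
    accel_vertical_true: np.ndarray
    accel_global_true: np.ndarray
    pitch_true: np.ndarray
    gyro_foot_true: np.ndarray
    orientation_true: np.ndarray
    foot_flat_mask: np.ndarray
    flat_intervals: list
    translation_onset_index: int

    @property
    def n_samples(self) -> int:
        return self.time.size


def _swing_fields(n: int, dt: float, peak: float, pitch_rate: float, speed_advance: float):
    """Closed-form swing kinematics over n samples of duration n*dt."""
    T = n * dt
    t = np.arange(n) * dt
    u = np.pi * t / T
    sin, cos = np.sin(u), np.cos(u)
    h = peak * sin**4
    v = peak * 4.0 * (np.pi / T) * sin**3 * cos
    a = peak * 4.0 * (np.pi / T) ** 2 * (3.0 * sin**2 * cos**2 - sin**4)
    A = pitch_rate / _RATE_SHAPE_PEAK
    rate = A * 2.0 * sin**3 * cos
    pitch = (A * T / (2.0 * np.pi)) * sin**4
    s = t / T
    y = speed_advance * (s - np.sin(2 * np.pi * s) / (2 * np.pi))
    ay = (2 * np.pi * speed_advance / T**2) * np.sin(2 * np.pi * s)
    return h, v, a, rate, pitch, y, ay


def make_trajectory(profile: GaitProfile, fs: float) -> GroundTruth:
    """Generate the analytic ground-truth trajectory for a gait profile.

    Segment boundaries are snapped to the sample grid, so every foot-flat
    interval is an exact [start, end) index range and the emitted
    derivatives are mutually consistent to machine precision.
    """
    if not np.isfinite(fs) or fs < 50.0:
        raise ValueError("sampling rate must be >= 50 Hz")
    dt = 1.0 / fs
    n_lead = int(round(profile.stationary_lead * fs))
    swing_dur = (1.0 - profile.foot_flat_fraction) * profile.stride_duration
    flat_dur = profile.foot_flat_fraction * profile.stride_duration
    n_swing = int(round(swing_dur * fs))
    n_flat = int(round(flat_dur * fs))
    n_pivot = int(round(profile.heel_pivot_duration * fs))
    if n_swing < 8 or n_flat < 2:
        raise ValueError(
            "degenerate profile: swing or foot-flat phase too short for the "
            "sampling rate"
        )
    peaks = profile.stride_peaks()
    advance = profile.walking_speed * profile.stride_duration

    n_total = n_lead + n_pivot + profile.n_strides * (n_swing + n_flat) + 1
    h = np.zeros(n_total)
    v = np.zeros(n_total)
    a = np.zeros(n_total)
    rate = np.zeros(n_total)
    pitch = np.zeros(n_total)
    y = np.zeros(n_total)
    ay = np.zeros(n_total)
    mask = np.zeros(n_total, dtype=bool)
    flats: list[tuple[int, int]] = []

    cursor = n_lead
    mask[:n_lead] = True
    flats.append((0, n_lead))

    if n_pivot > 0:
        # rotation about the heel with no translation: zero-net pitch bump
        A_p = 0.4 * profile.peak_pitch_rate / _RATE_SHAPE_PEAK
        tp = np.arange(n_pivot) * dt
        up = np.pi * tp / (n_pivot * dt)
        rate[cursor : cursor + n_pivot] = A_p * 2.0 * np.sin(up) ** 3 * np.cos(up)
        pitch[cursor : cursor + n_pivot] = (
            A_p * n_pivot * dt / (2.0 * np.pi)
        ) * np.sin(up) ** 4
        cursor += n_pivot

    onset = cursor
    y_base = 0.0
    for k in range(profile.n_strides):
        sl = slice(cursor, cursor + n_swing)
        hs, vs, as_, rs, ps, ys, ays = _swing_fields(
            n_swing, dt, peaks[k], profile.peak_pitch_rate, advance
        )
        h[sl], v[sl], a[sl] = hs, vs, as_
        rate[sl], pitch[sl] = rs, ps
        y[sl] = y_base + ys
        ay[sl] = ays
        cursor += n_swing
        y_base += advance
        flat_end = cursor + n_flat + (1 if k == profile.n_strides - 1 else 0)
        mask[cursor:flat_end] = True
        y[cursor:flat_end] = y_base
        flats.append((cursor, flat_end))
        cursor += n_flat

    time = np.arange(n_total) * dt
    c, s = np.cos(pitch), np.sin(pitch)
    R = np.zeros((n_total, 3, 3))
    R[:, 0, 0] = c
    R[:, 0, 1] = -s
    R[:, 1, 0] = s
    R[:, 1, 1] = c
    R[:, 2, 2] = 1.0

    accel_global = np.vstack([a, ay, np.zeros(n_total)])
    gyro_foot = np.vstack([np.zeros(n_total), np.zeros(n_total), rate])
    return GroundTruth(
        time=time,
        fs=fs,
        clearance_true=h,
        velocity_true=v,
        accel_vertical_true=a,
        accel_global_true=accel_global,
        pitch_true=pitch,
        gyro_foot_true=gyro_foot,
        orientation_true=R,
        foot_flat_mask=mask,
        flat_intervals=flats,
        translation_onset_index=onset,
    )


def synthesize_imu(
    truth: GroundTruth, err: SensorErrorModel, fs: float | None = None
) -> IMURecording:
    """Synthesize raw sensor channels from the trajectory and error model.

    The accelerometer channel is the sensor-frame projection of the true
    linear acceleration plus gravity (along global X), corrupted with the
    inverse calibration model and additive noise; the gyroscope channel is
    the true body rate plus bias and noise. With the ideal error model the
    stationary accelerometer reads exactly ``[9.81, 0, 0]``.
    """
    if fs is None:
        fs = truth.fs
    elif abs(fs - truth.fs) > 1e-9:
        raise ValueError("fs does not match the trajectory sampling rate")
    n = truth.n_samples
    R_mount = initial_tilt_matrix(err.mount_pitch, err.mount_roll)
    R_sensor = truth.orientation_true @ R_mount  # sensor -> global

    GA = truth.accel_global_true + np.array([[GRAVITY], [0.0], [0.0]])
    SA = np.einsum("nji,jn->in", R_sensor, GA)  # R^T @ GA per sample
    omega_sensor = R_mount.T @ truth.gyro_foot_true

    # noise arrays are always drawn (then scaled) so that recordings with
    # different noise amplitudes but the same seed share the same
    # realizations — paired noise-level comparisons stay paired
    rng = np.random.default_rng(err.seed)
    Am = np.linalg.solve(err.scale_true, SA) + err.bias_true[:, None]
    Am = Am + err.accel_noise_sd * rng.standard_normal((3, n))
    Gm = omega_sensor + err.gyro_bias[:, None]
    Gm = Gm + err.gyro_noise_sd * rng.standard_normal((3, n))
    return IMURecording(time=truth.time.copy(), accel=Am, gyro=Gm, fs=fs)


def synthesize_static_set(
    err: SensorErrorModel,
    n_orientations: int = 30,
    fs: float = 200.0,
    duration: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Mean static accelerometer readings in random orientations.

    Emulates the calibration protocol: the sensor is placed still in
    ``n_orientations`` random poses; each returned row is the mean raw
    reading over ``duration`` seconds of samples (noise suppressed by
    averaging). Returns an (n_orientations, 3) array.
    """
    rng = np.random.default_rng(err.seed if seed is None else seed)
    n_avg = max(1, int(round(fs * duration)))
    readings = np.empty((n_orientations, 3))
    for k in range(n_orientations):
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        sa = GRAVITY * d
        am = np.linalg.solve(err.scale_true, sa) + err.bias_true
        if err.accel_noise_sd > 0:
            am = am + rng.normal(0.0, err.accel_noise_sd, (n_avg, 3)).mean(axis=0)
        readings[k] = am
    return readings


_RECORDING_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]


def write_recording(rec: IMURecording, path) -> None:
    """Write a recording as CSV with columns ``t, ax, ay, az, gx, gy, gz``."""
    df = pd.DataFrame(
        {
            "t": rec.time,
            "ax": rec.accel[0],
            "ay": rec.accel[1],
            "az": rec.accel[2],
            "gx": rec.gyro[0],
            "gy": rec.gyro[1],
            "gz": rec.gyro[2],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_recording(path) -> IMURecording:
    """Read a recording CSV written by :func:`write_recording`.

    Round-trips bitwise with :func:`write_recording`. Raises
    :class:`RecordingFormatError` on a missing column or non-monotonic
    timestamps (reporting the offending column/index).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _RECORDING_COLUMNS:
        if col not in df.columns:
            raise RecordingFormatError(f"recording CSV is missing column '{col}'")
    t = df["t"].to_numpy(dtype=float)
    if t.size >= 2:
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise RecordingFormatError(
                f"timestamps not strictly increasing at row {int(bad[0]) + 1}"
            )
    fs = 1.0 / float(np.median(np.diff(t))) if t.size >= 2 else 200.0
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float).T
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float).T
    return IMURecording(time=t, accel=accel, gyro=gyro, fs=fs)


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Write the truth trace as CSV ``t, clearance, foot_flat``."""
    pd.DataFrame(
        {
            "t": truth.time,
            "clearance": truth.clearance_true,
            "foot_flat": truth.foot_flat_mask.astype(int),
        }
    ).to_csv(path, index=False)


def read_ground_truth(path) -> pd.DataFrame:
    """Read a ground-truth CSV (``t, clearance, foot_flat``)."""
    df = pd.read_csv(path)
    for col in ("t", "clearance"):
        if col not in df.columns:
            raise RecordingFormatError(f"ground-truth CSV is missing column '{col}'")
    return df
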