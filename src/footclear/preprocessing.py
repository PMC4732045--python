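"""Raw IMU signal conditioning: stationary-window detection, Butterworth
filtering and gyroscope bias removal.

The pipeline assumes every trial begins with the subject standing still.
That stationary lead serves two purposes: the mean angular rate over it is
the gyroscope bias (subtracted from the whole trace), and the mean
accelerometer reading over it is the gravity projection used to estimate
the initial sensor tilt.

Filters follow the offline protocol: a first-order Butterworth band-pass
(0.001–5 Hz) on each gyroscope axis and a first-order 10 Hz low-pass on
each accelerometer axis. Both are applied forward–backward (zero-phase) by
default so that no group delay shifts the gait events; a causal mode is
available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .exceptions import RecordingFormatError, StationaryDetectionError

__all__ = [
    "IMURecording",
    "StationaryWindow",
    "detect_stationary",
    "filter_gyro",
    "filter_accel",
    "remove_gyro_bias",
]


@dataclass
class IMURecording:
    """Synchronized raw accelerometer + gyroscope time series.

    Parameters
    ----------
    time : (n,) array
        Sample timestamps in seconds, uniformly spaced.
    accel : (3, n) array
        Sensor-frame acceleration in m/s^2 (gravity included).
    gyro : (3, n) array
        Sensor-frame angular rate in rad/s.
    fs : float
        Sampling rate in Hz (nominally ~200 Hz).
    """

    time: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    fs: float

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        n = self.time.size
        if self.accel.shape != (3, n) or self.gyro.shape != (3, n):
            raise RecordingFormatError(
                f"channel shapes {self.accel.shape}, {self.gyro.shape} do not "
                f"match {n} timestamps (expected (3, {n}))"
            )
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                idx = int(np.argmax(dt <= 0))
                raise RecordingFormatError(
                    f"timestamps not strictly increasing at index {idx + 1}"
                )
            mean_dt = dt.mean()
            if np.max(np.abs(dt - mean_dt)) > 0.01 * mean_dt:
                raise RecordingFormatError(
                    "sampling is non-uniform beyond 1% jitter"
                )
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise RecordingFormatError(f"invalid sampling rate {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.n_samples else 0.0


@dataclass(frozen=True)
class StationaryWindow:
    """Initial still period, as a [start, end) sample-index range."""

    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("stationary window must have end > start")

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    def slice(self) -> slice:
        return slice(self.start, self.end)


def detect_stationary(
    rec: IMURecording,
    rate_threshold: float = 0.05,
    min_duration: float = 0.5,
) -> StationaryWindow:
    """Find the initial stationary window from the raw gyroscope.

    The angular-rate magnitude is computed after centring each axis on its
    mean over the first ``min_duration`` seconds (so an uncorrected gyro
    bias does not mask stillness). The window is the longest prefix in
    which that magnitude stays below ``rate_threshold``; the coarse
    threshold crossing is then backtracked to the near-zero rate floor so
    the boundary lands where motion actually begins rather than where the
    smooth rate ramp first exceeds the threshold.

    Raises
    ------
    StationaryDetectionError
        If the recording does not begin with at least ``min_duration``
        seconds of stillness.
    """
    n0 = int(round(min_duration * rec.fs))
    if rec.n_samples < n0 or n0 < 2:
        raise StationaryDetectionError(
            "recording shorter than the minimum stationary duration; "
            "trials must start with the sensor at rest"
        )
    bias = rec.gyro[:, :n0].mean(axis=1)
    centred = rec.gyro - bias[:, None]
    mag = np.linalg.norm(centred, axis=0)

    above = np.nonzero(mag >= rate_threshold)[0]
    end = int(above[0]) if above.size else rec.n_samples

    # Backtrack: a C2-smooth motion onset crosses the threshold late; trim
    # back to where the rate is indistinguishable from the still-phase floor.
    floor = mag[:n0]
    eps = max(1e-3, float(floor.mean() + 4.0 * floor.std()))
    while end > n0 and mag[end - 1] > eps:
        end -= 1

    if end < n0:
        raise StationaryDetectionError(
            f"no stationary window of at least {min_duration} s at the start "
            "of the recording; trials must begin with the subject still"
        )
    return StationaryWindow(0, end)


def _butter_sos(order: int, cutoff_hz, fs: float, btype: str):
    return signal.butter(order, cutoff_hz, btype=btype, fs=fs, output="sos")


def _apply(sos, data: np.ndarray, zero_phase: bool) -> np.ndarray:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if zero_phase:
        return signal.sosfiltfilt(sos, data, axis=-1)
    return signal.sosfilt(sos, data, axis=-1)


def filter_gyro(
    gyro: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.001, 5.0),
    zero_phase: bool = True,
) -> np.ndarray:
    """Band-pass each gyroscope axis (first-order Butterworth).

    Realized as a cascade of a first-order high-pass at ``band[0]`` and a
    first-order low-pass at ``band[1]``. Applied forward-backward when
    ``zero_phase`` so foot-flat event timing is not shifted.
    """
    low, high = band
    if fs <= 2.0 * high:
        raise ValueError(
            f"sampling rate {fs} Hz must exceed twice the upper cutoff {high} Hz"
        )
    if not 0 < low < high:
        raise ValueError(f"invalid band {band}")
    # The first-order high-pass is realized as identity minus the
    # complementary first-order low-pass at the same corner (exact for a
    # first-order Butterworth). At a 0.001 Hz corner the pole sits within
    # 1e-7 of the unit circle and its transient far exceeds a trial, so the
    # trend filter needs Gustafsson initial conditions (chosen to minimize
    # edge transients) instead of the default padding.
    b_tr, a_tr = signal.butter(1, low, btype="lowpass", fs=fs)
    lp = _butter_sos(1, high, fs, "lowpass")
    gyro = np.atleast_2d(np.asarray(gyro, dtype=float))
    if zero_phase:
        trend = signal.filtfilt(b_tr, a_tr, gyro, axis=-1, method="gust")
    else:
        trend = signal.lfilter(b_tr, a_tr, gyro, axis=-1)
    return _apply(lp, gyro - trend, zero_phase)


def filter_accel(
    accel: np.ndarray,
    fs: float,
    cutoff: float = 10.0,
    zero_phase: bool = True,
) -> np.ndarray:
    """Low-pass each accelerometer axis (first-order Butterworth).

    Low-pass only: the constant component is the gravity projection, which
    changes with sensor orientation and must be preserved for the tilt
    estimate and the global-frame transformation.
    """
    if fs <= 2.0 * cutoff:
        raise ValueError(
            f"sampling rate {fs} Hz must exceed twice the cutoff {cutoff} Hz"
        )
    lp = _butter_sos(1, cutoff, fs, "lowpass")
    return _apply(lp, accel, zero_phase)


def remove_gyro_bias(
    gyro: np.ndarray, window: StationaryWindow
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the stationary-window mean from the whole gyro trace.

    Returns ``(corrected, bias)`` where ``bias`` is the per-axis mean over
    the stationary window — the quantified gyroscope bias.
    """
    gyro = np.atleast_2d(np.asarray(gyro, dtype=float))
    bias = gyro[:, window.slice()].mean(axis=1)
    return gyro - bias[:, None], bias
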