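"""Foot clearance from gravity-free vertical acceleration: frame
transformation, stride-wise drift-cancelled double integration, and the
end-to-end estimation pipeline.

Per stride (from one foot-flat end to the next, duration T, local time t
measured from the stride start):

    Vx(t)           = trapezoidal integral of the gravity-free vertical
                      acceleration, from zero initial velocity (ZVU)
    Vx_corr(t)      = Vx(t) - (Vx(T) / T) * t
    Dx(t)           = trapezoidal integral of Vx_corr, from zero
    Dx_corr(t)      = Dx(t) - (Dx(T) / T) * t

The linear ramps force the corrected terminal velocity and displacement to
zero exactly — the zero-velocity and zero-displacement updates valid on
flat horizontal ground — and absorb any constant within-stride
acceleration bias exactly. ``Dx_corr`` is the estimated foot clearance;
it is clamped to zero on detected foot-flat samples (never mid-swing).
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .calibration import CalibrationModel, apply_calibration
from .config import PipelineConfig
from .exceptions import FootclearError, PipelineStageError
from .orientation import (
    GRAVITY,
    OrientationTrack,
    estimate_initial_tilt,
    strapdown_integrate,
)
from .preprocessing import (
    IMURecording,
    detect_stationary,
    filter_accel,
    filter_gyro,
    remove_gyro_bias,
)
from .segmentation import StrideSegmentation, detect_foot_flat, refine_first_event

__all__ = [
    "GlobalAcceleration",
    "StrideResult",
    "ClearanceTrace",
    "to_global_gravity_free",
    "integrate_stride_velocity",
    "integrate_stride_clearance",
    "estimate_clearance",
]


@dataclass
class GlobalAcceleration:
    """Acceleration in the global frame, with and without gravity.

    ``GA`` includes gravity; ``Ga = GA - [9.81, 0, 0]`` per sample is the
    gravity-free acceleration. ``vertical`` is the first row of ``Ga``.
    """

    GA: np.ndarray
    Ga: np.ndarray

    @property
    def vertical(self) -> np.ndarray:
        return self.Ga[0]

    def norm(self) -> np.ndarray:
        return np.linalg.norm(self.Ga, axis=0)


def to_global_gravity_free(
    accel_calibrated: np.ndarray, track: OrientationTrack
) -> GlobalAcceleration:
    """Rotate sensor-frame acceleration to the global frame, drop gravity."""
    accel = np.atleast_2d(np.asarray(accel_calibrated, dtype=float))
    if accel.shape[1] != len(track):
        raise ValueError(
            f"acceleration length {accel.shape[1]} does not match "
            f"orientation track length {len(track)}"
        )
    GA = np.einsum("nij,jn->in", track.R, accel)
    Ga = GA - np.array([[GRAVITY], [0.0], [0.0]])
    return GlobalAcceleration(GA=GA, Ga=Ga)


def _check_stride(start: int, end: int):
    if end - start < 3:
        raise ValueError(f"stride [{start}, {end}) is shorter than 3 samples")


def integrate_stride_velocity(
    gax: np.ndarray, stride: tuple[int, int], dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Stride velocity by trapezoidal integration plus linear de-drift.

    Returns ``(Vx, Vx_corrected)`` over the stride samples. Velocity starts
    at zero (zero-velocity update at the stride start) and the corrected
    trace ends at exactly zero.
    """
    start, end = stride
    _check_stride(start, end)
    seg = np.asarray(gax, dtype=float)[start:end]
    v = cumulative_trapezoid(seg, dx=dt, initial=0.0)
    t = np.arange(seg.size) * dt
    T = t[-1]
    v_corr = v - (v[-1] / T) * t
    return v, v_corr


def integrate_stride_clearance(
    v_corrected: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Stride displacement from corrected velocity, linear de-drift again.

    Returns ``(Dx, Dx_corrected)``; the corrected displacement is the foot
    clearance over the stride and ends at exactly zero (zero-displacement
    update: the stride ends in a foot-flat phase at ground level).
    """
    v_corrected = np.asarray(v_corrected, dtype=float)
    if v_corrected.size < 3:
        raise ValueError("corrected velocity shorter than 3 samples")
    d = cumulative_trapezoid(v_corrected, dx=dt, initial=0.0)
    t = np.arange(v_corrected.size) * dt
    T = t[-1]
    d_corr = d - (d[-1] / T) * t
    return d, d_corr


@dataclass(frozen=True)
class StrideResult:
    """Per-stride diagnostics: the raw terminal drifts removed by Eq-style
    linear corrections."""

    start: int
    end: int
    v_end_raw: float
    d_end_raw: float

    @property
    def duration_samples(self) -> int:
        return self.end - self.start


@dataclass
class ClearanceTrace:
    """Estimated clearance and corrected vertical velocity for a recording."""

    time: np.ndarray
    clearance: np.ndarray
    velocity: np.ndarray
    stride_ids: np.ndarray
    foot_flat: np.ndarray
    strides: list
    segmentation: StrideSegmentation
    tilt_theta_z0: float = 0.0
    tilt_theta_y0: float = 0.0
    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def to_frame(self) -> pd.DataFrame:
        """Tabular output: ``t, clearance_m, velocity_ms, stride_id, foot_flat``."""
        return pd.DataFrame(
            {
                "t": self.time,
                "clearance_m": self.clearance,
                "velocity_ms": self.velocity,
                "stride_id": self.stride_ids,
                "foot_flat": self.foot_flat.astype(int),
            }
        )

    def diagnostics_frame(self) -> pd.DataFrame:
        """Per-stride raw terminal drifts (before correction)."""
        return pd.DataFrame(
            {
                "stride_id": np.arange(len(self.strides)),
                "start": [s.start for s in self.strides],
                "end": [s.end for s in self.strides],
                "v_end_raw_ms": [s.v_end_raw for s in self.strides],
                "d_end_raw_m": [s.d_end_raw for s in self.strides],
            }
        )


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineStageError:
        raise
    except (FootclearError, ValueError) as exc:
        raise PipelineStageError(name, str(exc)) from exc


def estimate_clearance(
    rec: IMURecording,
    model: CalibrationModel | None = None,
    config: PipelineConfig | None = None,
) -> ClearanceTrace:
    """Run the full estimation pipeline on a raw recording.

    Stages: calibration -> filtering -> stationary detection -> gyro bias
    removal -> initial tilt -> strapdown integration -> global-frame
    gravity-free acceleration -> foot-flat segmentation (with first-event
    refinement) -> stride-wise drift-cancelled double integration.

    Errors raised by any stage are re-raised as
    :class:`~footclear.exceptions.PipelineStageError` carrying the stage
    name.
    """
    cfg = config or PipelineConfig()
    fs = rec.fs
    dt = 1.0 / fs
    n = rec.n_samples

    with _stage("calibration"):
        accel_cal = (
            apply_calibration(model, rec.accel) if model is not None else rec.accel
        )
    with _stage("filtering"):
        gyro_f = filter_gyro(rec.gyro, fs, cfg.gyro_band, cfg.zero_phase)
        accel_f = filter_accel(accel_cal, fs, cfg.accel_cutoff, cfg.zero_phase)
    with _stage("stationary detection"):
        window = detect_stationary(
            rec, cfg.stationary_rate_threshold, cfg.stationary_min_duration
        )
    with _stage("gyro bias removal"):
        gyro_c, gyro_bias = remove_gyro_bias(gyro_f, window)
    with _stage("initial tilt"):
        sg = accel_f[:, window.slice()].mean(axis=1)
        tilt = estimate_initial_tilt(sg, g=cfg.g)
    with _stage("strapdown integration"):
        track = strapdown_integrate(gyro_c, dt, tilt.matrix)
    with _stage("frame transformation"):
        ga = to_global_gravity_free(accel_f, track)
    with _stage("segmentation"):
        seg = detect_foot_flat(gyro_c[2], fs, cfg.flat_params)
        seg = refine_first_event(seg, ga.norm(), cfg.flat_params)

    clearance = np.zeros(n)
    velocity = np.zeros(n)
    stride_ids = np.full(n, -1, dtype=int)
    stride_results: list[StrideResult] = []
    with _stage("stride integration"):
        for k, (s, e) in enumerate(seg.strides):
            v_raw, v_corr = integrate_stride_velocity(ga.vertical, (s, e), dt)
            d_raw, d_corr = integrate_stride_clearance(v_corr, dt)
            clearance[s:e] = d_corr[: e - s]
            velocity[s:e] = v_corr[: e - s]
            stride_ids[s:e] = k
            stride_results.append(
                StrideResult(
                    start=s, end=e,
                    v_end_raw=float(v_raw[-1]), d_end_raw=float(d_raw[-1]),
                )
            )

    foot_flat = seg.foot_flat_mask(n)
    clearance[foot_flat] = 0.0
    velocity[foot_flat] = 0.0
    return ClearanceTrace(
        time=rec.time.copy(),
        clearance=clearance,
        velocity=velocity,
        stride_ids=stride_ids,
        foot_flat=foot_flat,
        strides=stride_results,
        segmentation=seg,
        tilt_theta_z0=tilt.theta_z0,
        tilt_theta_y0=tilt.theta_y0,
        gyro_bias=gyro_bias,
    )
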