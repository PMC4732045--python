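"""Sensor orientation: initial tilt from the stationary gravity vector and
strapdown integration of angular rate into per-sample rotation matrices.

Conventions
-----------
The global vertical is the X axis, so gravity is ``[9.81, 0, 0]`` in the
global frame. "Pitch" is the rotation about Z (sagittal plane for a
foot-mounted sensor) and "roll" the rotation about Y. The initial
transformation matrix ``G_R0`` maps sensor-frame vectors to the global
frame and is pinned by the identity ``G_R0 @ SG = [9.81, 0, 0]`` where
``SG`` is the gravity vector measured on the sensor axes while the foot
is still. The heading about the vertical is unobservable from gravity and
is left at zero; only the vertical acceleration component is integrated
downstream, so this is harmless.

The strapdown recursion is the first-order additive update

    R_i = R_{i-1} + R_{i-1} [dt * w_i]_x

with no re-orthonormalization, which is the faithful offline formulation;
an exact matrix-exponential mode exists for oracle comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GRAVITY = 9.81

__all__ = [
    "GRAVITY",
    "skew",
    "rotation_z",
    "rotation_y",
    "initial_tilt_matrix",
    "InitialTilt",
    "estimate_initial_tilt",
    "OrientationTrack",
    "strapdown_integrate",
    "rotation_angle_deg",
]


def skew(v) -> np.ndarray:
    """Skew-symmetric cross-product matrix ``[v]_x`` with layout
    ``[[0, -vz, vy], [vz, 0, -vx], [-vy, vx, 0]]``."""
    x, y, z = np.asarray(v, dtype=float)
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def rotation_z(angle: float) -> np.ndarray:
    """Rotation about Z, layout ``[[c, s, 0], [-s, c, 0], [0, 0, 1]]``."""
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_y(angle: float) -> np.ndarray:
    """Rotation about Y, layout ``[[c, 0, s], [0, 1, 0], [-s, 0, c]]``."""
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def initial_tilt_matrix(theta_z: float, theta_y: float) -> np.ndarray:
    """Assemble ``G_R0`` from pitch ``theta_z`` and roll ``theta_y``.

    The composition ``rotation_y(theta_y) @ rotation_z(theta_z)`` is the
    unique order for which the arctan tilt formulas below are exact, i.e.
    ``G_R0 @ SG == [g, 0, 0]`` for any gravity reading ``SG``.
    """
    return rotation_y(theta_y) @ rotation_z(theta_z)


@dataclass(frozen=True)
class InitialTilt:
    """Initial sensor tilt: pitch/roll angles and the assembled matrix."""

    theta_z0: float
    theta_y0: float
    matrix: np.ndarray


def estimate_initial_tilt(gravity_sensor, g: float = GRAVITY) -> InitialTilt:
    """Estimate initial pitch/roll from the stationary gravity projection.

    Parameters
    ----------
    gravity_sensor : (3,) array
        Mean accelerometer reading (m/s^2) over the stationary window.
    g : float
        Gravity magnitude used for the sanity check.

    Notes
    -----
    ``theta_z0 = arctan2(SG_y, SG_x)`` and
    ``theta_y0 = arctan2(SG_z, sqrt(SG_x^2 + SG_y^2))``. The two-argument
    arctangent is quadrant-safe; for a foot-mounted sensor roughly upright
    both angles are small and the plain arctan would agree.
    """
    sg = np.asarray(gravity_sensor, dtype=float)
    norm = float(np.linalg.norm(sg))
    if norm < 1e-6:
        raise ValueError(
            "stationary acceleration is near zero; the sensor is not "
            "measuring gravity"
        )
    if abs(norm - g) > 0.2 * g:
        raise ValueError(
            f"stationary acceleration norm {norm:.3f} m/s^2 deviates more "
            f"than 20% from gravity ({g} m/s^2); check calibration and the "
            "stationary window"
        )
    theta_z0 = float(np.arctan2(sg[1], sg[0]))
    theta_y0 = float(np.arctan2(sg[2], np.hypot(sg[0], sg[1])))
    return InitialTilt(theta_z0, theta_y0, initial_tilt_matrix(theta_z0, theta_y0))


@dataclass
class OrientationTrack:
    """Per-sample sensor-to-global rotation matrices.

    ``R`` has shape (n, 3, 3); ``R[i]`` maps sensor-frame vectors at sample
    i to the global frame. ``dt`` is the sample interval in seconds.
    """

    R: np.ndarray
    dt: float

    def __len__(self) -> int:
        return self.R.shape[0]

    def determinants(self) -> np.ndarray:
        return np.linalg.det(self.R)


def _rodrigues(w: np.ndarray, dt: float) -> np.ndarray:
    angle = np.linalg.norm(w) * dt
    if angle < 1e-14:
        return np.eye(3)
    K = skew(w / np.linalg.norm(w))
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def strapdown_integrate(
    gyro: np.ndarray,
    dt: float,
    R0: np.ndarray | None = None,
    method: str = "euler",
) -> OrientationTrack:
    """Integrate bias-free angular rates into an orientation track.

    Parameters
    ----------
    gyro : (3, n) array
        Bias-removed sensor-frame angular rates, rad/s.
    dt : float
        Sample interval, seconds.
    R0 : (3, 3) array, optional
        Initial sensor-to-global matrix (the initial tilt). Identity if
        omitted.
    method : {"euler", "exact"}
        "euler" is the faithful first-order additive update (default, no
        re-orthonormalization); "exact" composes per-sample matrix
        exponentials (Rodrigues) and is intended as a high-accuracy oracle.
    """
    gyro = np.atleast_2d(np.asarray(gyro, dtype=float))
    if not np.all(np.isfinite(gyro)):
        raise ValueError("gyro stream contains NaN or infinite values")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if R0 is None:
        R0 = np.eye(3)
    R0 = np.asarray(R0, dtype=float)
    if np.max(np.abs(R0 @ R0.T - np.eye(3))) > 1e-6:
        raise ValueError("R0 is not orthonormal")

    n = gyro.shape[1]
    R = np.empty((n, 3, 3))
    R[0] = R0
    if method == "euler":
        for i in range(1, n):
            Ri = R[i - 1]
            R[i] = Ri + Ri @ (dt * skew(gyro[:, i]))
    elif method == "exact":
        for i in range(1, n):
            R[i] = R[i - 1] @ _rodrigues(gyro[:, i], dt)
    else:
        raise ValueError(f"unknown method {method!r}")
    return OrientationTrack(R=R, dt=dt)


def _polar_orthonormal(R: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(R)
    Q = U @ Vt
    if np.linalg.det(Q) < 0:  # keep a proper rotation
        U = U.copy()
        U[:, -1] *= -1
        Q = U @ Vt
    return Q


def rotation_angle_deg(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Relative rotation angle (degrees) between two matrices.

    Each input is projected to its nearest proper rotation (polar factor)
    first, so the Euler track's mild non-orthonormality does not corrupt
    the angle.
    """
    Qa = _polar_orthonormal(np.asarray(Ra, dtype=float))
    Qb = _polar_orthonormal(np.asarray(Rb, dtype=float))
    c = (np.trace(Qa.T @ Qb) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
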