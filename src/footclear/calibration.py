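"""Accelerometer scale/bias calibration from static multi-orientation readings.

The calibrated acceleration is ``A = S (Am - B)`` with scale matrix ``S``
and bias vector ``B``. Both are identified by a Newton-type iteration that
minimizes the quadratic error between the norm of every calibrated static
reading and the gravity norm:

    cost(S, B) = sum_k ( ||S (Am_k - B)|| - g )^2

over N > 20 random static orientations. The norm constraint cannot
distinguish ``S`` from ``Q S`` for any rotation ``Q``, so ``S`` is
parameterized as symmetric (6 parameters, capturing per-axis scale and
cross-axis sensitivity without rotation ambiguity); a diagonal-only mode
(3 parameters) is also available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .exceptions import CalibrationError
from .orientation import GRAVITY

__all__ = [
    "CalibrationModel",
    "StaticOrientationSet",
    "fit_calibration",
    "apply_calibration",
    "calibration_cost",
    "save_model",
    "load_model",
]

MIN_ORIENTATIONS = 20  # the protocol requires strictly more than this


@dataclass
class CalibrationModel:
    """Fitted calibration: scale matrix ``S``, bias ``B`` and diagnostics."""

    S: np.ndarray
    B: np.ndarray
    residual: float
    n_iterations: int = 0
    gradient_norm: float = 0.0

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if abs(np.linalg.det(self.S)) < 1e-12:
            raise CalibrationError("scale matrix S is singular")
        if self.residual < 0:
            raise CalibrationError("residual must be >= 0")

    @classmethod
    def identity(cls) -> "CalibrationModel":
        return cls(S=np.eye(3), B=np.zeros(3), residual=0.0)


@dataclass
class StaticOrientationSet:
    """Mean accelerometer readings, one 3-vector per static orientation."""

    readings: np.ndarray

    def __post_init__(self):
        self.readings = np.atleast_2d(np.asarray(self.readings, dtype=float))
        if self.readings.ndim != 2 or self.readings.shape[1] != 3:
            raise CalibrationError(
                f"readings must be (N, 3), got {self.readings.shape}"
            )

    @property
    def count(self) -> int:
        return self.readings.shape[0]


def calibration_cost(S, B, readings, g: float = GRAVITY) -> float:
    """Brute-force objective: sum over readings of (||S(Am - B)|| - g)^2."""
    readings = np.atleast_2d(np.asarray(readings, dtype=float))
    norms = np.linalg.norm((np.asarray(S) @ (readings - np.asarray(B)).T), axis=0)
    return float(np.sum((norms - g) ** 2))


# -- symmetric-matrix parameter packing ------------------------------------

_SYM_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def _unpack(theta: np.ndarray, diagonal: bool):
    S = np.zeros((3, 3))
    if diagonal:
        S[np.diag_indices(3)] = theta[:3]
        B = theta[3:6]
    else:
        for val, (i, j) in zip(theta[:6], _SYM_IDX):
            S[i, j] = val
            S[j, i] = val
        B = theta[6:9]
    return S, B


def _pack(S: np.ndarray, B: np.ndarray, diagonal: bool) -> np.ndarray:
    if diagonal:
        return np.concatenate([np.diag(S), B])
    return np.concatenate([[S[i, j] for (i, j) in _SYM_IDX], B])


def _residuals_jacobian(theta, readings, g, diagonal):
    S, B = _unpack(theta, diagonal)
    W = readings - B  # (N, 3)
    U = W @ S.T  # u_k = S w_k
    norms = np.linalg.norm(U, axis=1)
    if np.any(norms < 1e-12):
        raise CalibrationError("degenerate reading collapsed to zero norm")
    r = norms - g
    un = U / norms[:, None]
    n_params = 6 if diagonal else 9
    J = np.empty((readings.shape[0], n_params))
    if diagonal:
        for p in range(3):
            J[:, p] = un[:, p] * W[:, p]
        J[:, 3:6] = -(un @ S)
    else:
        for p, (i, j) in enumerate(_SYM_IDX):
            if i == j:
                J[:, p] = un[:, i] * W[:, i]
            else:
                J[:, p] = un[:, i] * W[:, j] + un[:, j] * W[:, i]
        J[:, 6:9] = -(un @ S)  # S symmetric: dr/dB = -S^T un = -S un
    return r, J


def fit_calibration(
    obs: StaticOrientationSet | np.ndarray,
    g: float = GRAVITY,
    max_iter: int = 100,
    tol: float = 1e-10,
    diagonal: bool = False,
) -> CalibrationModel:
    """Identify (S, B) by damped Gauss-Newton from ``S = I, B = 0``.

    Parameters
    ----------
    obs : StaticOrientationSet or (N, 3) array
        One mean reading per static orientation, N > 20.
    g : float
        Gravity norm the calibrated readings are driven to.
    max_iter, tol : int, float
        Iteration budget and convergence tolerance on the infinity norm of
        the cost gradient.
    diagonal : bool
        Restrict ``S`` to diagonal (3 scale parameters) instead of the
        symmetric 6-parameter form.

    Raises
    ------
    CalibrationError
        If N <= 20, the orientations are degenerate (collinear), or the
        iteration fails to reach ``tol`` within ``max_iter`` accepted steps
        (the message reports the final gradient norm).
    """
    if not isinstance(obs, StaticOrientationSet):
        obs = StaticOrientationSet(obs)
    if obs.count <= MIN_ORIENTATIONS:
        raise CalibrationError(
            f"calibration requires more than {MIN_ORIENTATIONS} static "
            f"orientations, got {obs.count}"
        )
    readings = obs.readings
    centred = readings - readings.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-8) < 3:
        raise CalibrationError(
            "static orientations are degenerate (coplanar or collinear); "
            "re-record with the sensor in more varied poses"
        )

    diagonalize = diagonal
    theta = _pack(np.eye(3), np.zeros(3), diagonalize)
    r, J = _residuals_jacobian(theta, readings, g, diagonalize)
    cost = float(r @ r)
    lam = 1e-4
    n_accepted = 0
    grad = J.T @ r
    for _ in range(max_iter):
        grad = J.T @ r
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm < tol:
            S, B = _unpack(theta, diagonalize)
            return CalibrationModel(
                S=S, B=B, residual=cost,
                n_iterations=n_accepted, gradient_norm=grad_norm,
            )
        JtJ = J.T @ J
        accepted = False
        for _ in range(40):
            try:
                step = np.linalg.solve(
                    JtJ + lam * np.eye(JtJ.shape[0]), -grad
                )
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            trial = theta + step
            try:
                r_t, J_t = _residuals_jacobian(trial, readings, g, diagonalize)
            except CalibrationError:
                lam *= 10.0
                continue
            cost_t = float(r_t @ r_t)
            if cost_t <= cost:  # monotone over accepted iterations
                theta, r, J, cost = trial, r_t, J_t, cost_t
                lam = max(lam / 10.0, 1e-12)
                accepted = True
                n_accepted += 1
                break
            lam *= 10.0
        if not accepted:
            break
    # Either the iteration budget is exhausted or no damped step can reduce
    # the cost any further. A stalled iteration with a small gradient has
    # converged to the machine-precision floor of the noisy objective
    # (descent steps of size |g|^2 fall below the representable change in
    # cost); only a stall with a substantial gradient is a genuine failure.
    grad_norm = float(np.max(np.abs(J.T @ r)))
    if grad_norm < max(tol, 1e-6):
        S, B = _unpack(theta, diagonalize)
        return CalibrationModel(
            S=S, B=B, residual=cost,
            n_iterations=n_accepted, gradient_norm=grad_norm,
        )
    raise CalibrationError(
        f"calibration did not converge after {max_iter} iterations "
        f"(gradient norm {grad_norm:.3e}, cost {cost:.3e})"
    )


def apply_calibration(model: CalibrationModel, raw: np.ndarray) -> np.ndarray:
    """Apply ``A = S (Am - B)`` to a (3,) vector or (3, n) series."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:
        return model.S @ (raw - model.B)
    return model.S @ (raw - model.B[:, None])


def save_model(model: CalibrationModel, path) -> None:
    """Persist a model as a small structured text (YAML) file."""
    payload = {
        "S": [[float(x) for x in row] for row in model.S],
        "B": [float(x) for x in model.B],
        "residual": float(model.residual),
        "n_iterations": int(model.n_iterations),
        "gradient_norm": float(model.gradient_norm),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_model(path) -> CalibrationModel:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return CalibrationModel(
        S=np.array(payload["S"], dtype=float),
        B=np.array(payload["B"], dtype=float),
        residual=float(payload.get("residual", 0.0)),
        n_iterations=int(payload.get("n_iterations", 0)),
        gradient_norm=float(payload.get("gradient_norm", 0.0)),
    )
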