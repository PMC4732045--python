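"""Comparison of an estimated clearance trace against a reference trace:
peak-based synchronization, RMSE and normalized RMSE (percent of the
maximum reference clearance).

The reference is typically a motion-capture height trace; here it is most
often the synthetic generator's ground truth. Following the validation
protocol, the two series are aligned by matching their clearance peaks,
trimmed to common support, and compared with

    RMSE  = sqrt( (1/N) * sum (Xm - Xe)^2 )
    NRMSE = RMSE / max(Xm) * 100

where Xm is the reference (measured) and Xe the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .exceptions import SynchronizationError

__all__ = [
    "ComparisonReport",
    "synchronize_by_peaks",
    "align",
    "rmse",
    "nrmse",
    "compare",
    "batch_report",
    "BatchReport",
    "read_reference",
]


@dataclass(frozen=True)
class ComparisonReport:
    """Per-trial comparison numbers (centimetres / percent)."""

    rmse_cm: float
    nrmse_percent: float
    max_reference_cm: float
    n_samples: int
    lag_applied: int

    def __str__(self) -> str:
        return (
            f"RMSE {self.rmse_cm:.3f} cm | NRMSE {self.nrmse_percent:.2f}% "
            f"of max reference clearance {self.max_reference_cm:.2f} cm "
            f"(N={self.n_samples}, lag {self.lag_applied} samples)"
        )


def _peaks(x: np.ndarray, fs: float, prominence_frac: float, min_separation: float):
    x = np.asarray(x, dtype=float)
    top = float(np.max(x)) if x.size else 0.0
    if top <= 0:
        return np.array([], dtype=int)
    idx, _ = find_peaks(
        x,
        prominence=prominence_frac * top,
        distance=max(1, int(round(min_separation * fs))),
    )
    return idx


def synchronize_by_peaks(
    reference: np.ndarray,
    estimate: np.ndarray,
    fs: float = 200.0,
    prominence_frac: float = 0.2,
    min_separation: float = 0.3,
) -> int:
    """Integer lag (samples) aligning estimate to reference via peak matching.

    Peaks are local maxima with prominence at least ``prominence_frac`` of
    the global maximum and minimum separation ``min_separation`` seconds.
    Each estimate peak is matched to its nearest reference peak and the lag
    is the median index offset; applying the lag co-locates the matched
    peaks.
    """
    ref_peaks = _peaks(reference, fs, prominence_frac, min_separation)
    est_peaks = _peaks(estimate, fs, prominence_frac, min_separation)
    if ref_peaks.size == 0 or est_peaks.size == 0:
        raise SynchronizationError(
            "no clearance peaks found in one of the series; cannot "
            "synchronize flat traces"
        )
    offsets = [int(ref_peaks[np.argmin(np.abs(ref_peaks - p))]) - int(p)
               for p in est_peaks]
    return int(round(np.median(offsets)))


def align(
    reference: np.ndarray, estimate: np.ndarray, lag: int
) -> tuple[np.ndarray, np.ndarray]:
    """Apply an integer lag to the estimate and trim both series to the
    overlapping support."""
    reference = np.asarray(reference, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if lag >= 0:
        est = estimate[: estimate.size - lag] if lag else estimate
        ref = reference[lag:]
    else:
        est = estimate[-lag:]
        ref = reference[: reference.size + lag]
    n = min(ref.size, est.size)
    return ref[:n], est[:n]


def rmse(reference: np.ndarray, estimate: np.ndarray) -> float:
    """Root-mean-square error between two equal-length series (input units)."""
    reference = np.asarray(reference, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if reference.shape != estimate.shape:
        raise ValueError(
            f"series lengths differ ({reference.shape} vs {estimate.shape}); "
            "synchronize and trim first"
        )
    return float(np.sqrt(np.mean((reference - estimate) ** 2)))


def nrmse(rmse_value: float, reference: np.ndarray) -> float:
    """Normalized RMSE in percent of the maximum reference clearance."""
    top = float(np.max(np.asarray(reference, dtype=float)))
    if top <= 0:
        raise ValueError("maximum reference clearance must be positive")
    return rmse_value / top * 100.0


def compare(
    reference_m: np.ndarray,
    estimate_m: np.ndarray,
    fs: float = 200.0,
    synchronize: bool = True,
) -> ComparisonReport:
    """Full comparison of two clearance traces given in metres.

    Synchronizes by peaks (unless ``synchronize=False``), trims to common
    support, and reports RMSE in centimetres and NRMSE in percent.
    """
    lag = synchronize_by_peaks(reference_m, estimate_m, fs) if synchronize else 0
    ref, est = align(reference_m, estimate_m, lag)
    r_cm = rmse(ref * 100.0, est * 100.0)
    return ComparisonReport(
        rmse_cm=r_cm,
        nrmse_percent=nrmse(r_cm, ref * 100.0),
        max_reference_cm=float(np.max(ref) * 100.0),
        n_samples=ref.size,
        lag_applied=lag,
    )


@dataclass
class BatchReport:
    """Per-trial table plus grouped summary of a batch comparison."""

    trials: pd.DataFrame
    summary: pd.DataFrame

    def __str__(self) -> str:
        return (
            "Per-trial results:\n"
            + self.trials.to_string(index=False)
            + "\n\nSummary by group:\n"
            + self.summary.to_string(index=False)
        )


def batch_report(
    pairs,
    labels=None,
    fs: float = 200.0,
    thresholds: tuple[float, ...] = (10.0, 15.0),
) -> BatchReport:
    """Compare a batch of (reference, estimate) pairs (metres).

    Returns per-trial RMSE/NRMSE plus, per group label, mean RMSE, mean
    NRMSE and the fraction of trials whose NRMSE falls below each
    threshold.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("batch_report requires at least one (reference, estimate) pair")
    if labels is None:
        labels = ["all"] * len(pairs)
    labels = list(labels)
    if len(labels) != len(pairs):
        raise ValueError("labels length does not match number of pairs")

    rows = []
    for (ref, est), label in zip(pairs, labels):
        rep = compare(ref, est, fs)
        rows.append(
            {
                "label": label,
                "rmse_cm": rep.rmse_cm,
                "nrmse_percent": rep.nrmse_percent,
                "max_reference_cm": rep.max_reference_cm,
                "lag_samples": rep.lag_applied,
            }
        )
    trials = pd.DataFrame(rows)
    agg = {"rmse_cm": "mean", "nrmse_percent": "mean"}
    summary = trials.groupby("label", as_index=False).agg(agg)
    summary = summary.rename(
        columns={"rmse_cm": "mean_rmse_cm", "nrmse_percent": "mean_nrmse_percent"}
    )
    for thr in thresholds:
        frac = trials.groupby("label")["nrmse_percent"].apply(
            lambda x: float(np.mean(x < thr))
        )
        summary[f"frac_nrmse_below_{thr:g}"] = summary["label"].map(frac)
    return BatchReport(trials=trials, summary=summary)


def read_reference(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a reference trace CSV with columns ``t, height_m``."""
    df = pd.read_csv(path)
    if "height_m" in df.columns:
        h = df["height_m"].to_numpy(dtype=float)
    elif "clearance" in df.columns:  # ground-truth CSV dialect
        h = df["clearance"].to_numpy(dtype=float)
    else:
        raise ValueError("reference CSV needs a 'height_m' (or 'clearance') column")
    if "t" not in df.columns:
        raise ValueError("reference CSV needs a 't' column")
    return df["t"].to_numpy(dtype=float), h
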