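"""Foot-flat detection and stride segmentation from the Z-axis angular rate.

During the foot-flat phase (heel-strike to heel-off) the foot is in full
ground contact and the sagittal angular rate is near zero. Contiguous runs
where |gyro_z| stays small are foot-flat intervals; a stride runs from the
end of one foot-flat interval to the end of the next, so every stride
terminates on a foot-flat sample — the anchor the stride-wise velocity and
displacement corrections rely on.

Detection uses a magnitude threshold with hysteresis (enter flat below
``enter_threshold``, leave above ``exit_threshold``) plus a minimum flat
duration to reject the brief mid-swing rate reversal. Because the rate
approaches zero smoothly, the raw threshold crossings sit several samples
inside the swing; each interval is therefore trimmed inward to where the
rate falls to a near-zero floor (``refine_eps``), which places boundaries
within a few samples of the true contact events on clean signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import SegmentationError

logger = logging.getLogger(__name__)

__all__ = [
    "FootFlatParams",
    "StrideSegmentation",
    "detect_foot_flat",
    "refine_first_event",
]


@dataclass(frozen=True)
class FootFlatParams:
    """Thresholds for foot-flat detection (all configurable).

    ``enter_threshold``/``exit_threshold`` (rad/s) implement the hysteresis;
    ``min_flat_duration`` (s) drops spurious micro-intervals;
    ``refine_eps`` (rad/s) is the near-zero floor for boundary trimming;
    ``min_stride``/``max_stride`` (s) are plausibility gates on stride
    duration; ``onset_threshold`` (m/s^2) and ``onset_sustain`` control the
    acceleration-based refinement of the first heel-off event;
    ``agree_tolerance`` (s) is the discrepancy below which the gyro- and
    acceleration-based first events are considered identical.
    """

    enter_threshold: float = 0.3
    exit_threshold: float = 0.5
    min_flat_duration: float = 0.1
    refine_eps: float = 0.01
    min_stride: float = 0.3
    max_stride: float = 3.0
    onset_threshold: float = 0.5
    onset_sustain: int = 3
    agree_tolerance: float = 0.025


@dataclass
class StrideSegmentation:
    """Foot-flat intervals and the strides they delimit.

    ``foot_flat_intervals`` and ``strides`` are lists of [start, end)
    sample-index pairs; stride k spans from the end of flat interval k to
    the end of flat interval k+1.
    """

    foot_flat_intervals: list
    strides: list
    fs: float

    @property
    def n_strides(self) -> int:
        return len(self.strides)

    def foot_flat_mask(self, n: int) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        for s, e in self.foot_flat_intervals:
            mask[s:e] = True
        return mask


def _strides_from_flats(flats, fs, params: FootFlatParams):
    strides = []
    for (s0, e0), (s1, e1) in zip(flats[:-1], flats[1:]):
        dur = (e1 - e0) / fs
        if params.min_stride <= dur <= params.max_stride:
            strides.append((e0, e1))
        else:
            logger.warning(
                "dropping implausible stride of %.2f s (gates %.2f-%.2f s)",
                dur, params.min_stride, params.max_stride,
            )
    return strides


def detect_foot_flat(
    gyro_z: np.ndarray,
    fs: float,
    params: FootFlatParams | None = None,
) -> StrideSegmentation:
    """Segment a bias-free Z-rate trace into foot-flat intervals and strides.

    The detection is invariant to the sign of ``gyro_z`` (left/right foot
    mirror) because it thresholds the magnitude.

    Raises
    ------
    SegmentationError
        If no foot-flat interval is found; the trial likely does not start
        at rest or the thresholds need review.
    """
    params = params or FootFlatParams()
    a = np.abs(np.asarray(gyro_z, dtype=float))
    n = a.size
    min_n = max(2, int(round(params.min_flat_duration * fs)))

    runs = []
    inside = a[0] < params.enter_threshold
    start = 0
    for i in range(1, n):
        if inside:
            if a[i] > params.exit_threshold:
                runs.append((start, i))
                inside = False
        elif a[i] < params.enter_threshold:
            inside = True
            start = i
    if inside:
        runs.append((start, n))

    flats = []
    for s, e in runs:
        if e - s < min_n:
            continue
        # trim the smooth rate tails back to the run's near-zero floor; the
        # floor tracks the noise ceiling of the run core so that correlated
        # noise humps riding the tail do not drag the boundary inward
        quarter = (e - s) // 4
        core = a[s + quarter : e - quarter]
        floor = params.refine_eps
        if core.size:
            floor = max(floor, 1.1 * float(np.percentile(core, 98.0)))
        s_t, e_t = s, e
        while s_t < e_t and a[s_t] > floor:
            s_t += 1
        while e_t > s_t and a[e_t - 1] > floor:
            e_t -= 1
        if e_t - s_t >= min_n:
            flats.append((s_t, e_t))
        elif e - s >= 2 * min_n:
            # filter smearing from the adjacent swings can keep a short but
            # real flat above epsilon; a real flat spans its full duration
            # plus smeared tails (unlike a brief mid-swing rate reversal),
            # so keep the flattest admissible window of the run
            csum = np.concatenate([[0.0], np.cumsum(a[s:e])])
            win = csum[min_n:] - csum[:-min_n]
            s_w = s + int(np.argmin(win))
            flats.append((s_w, s_w + min_n))

    if not flats:
        raise SegmentationError(
            "no foot-flat interval detected; check that the trial starts at "
            "rest and review the detection thresholds"
        )
    return StrideSegmentation(
        foot_flat_intervals=flats,
        strides=_strides_from_flats(flats, fs, params),
        fs=fs,
    )


def refine_first_event(
    seg: StrideSegmentation,
    accel_norm: np.ndarray,
    params: FootFlatParams | None = None,
) -> StrideSegmentation:
    """Refine the first heel-off using the gravity-free acceleration onset.

    The foot that stands at the start rotates about the heel before it
    actually leaves the ground, so the gyro-based end of the first
    foot-flat interval can precede the true translation onset. The boundary
    is moved to the first sample where the gravity-free acceleration norm
    exceeds ``onset_threshold`` for ``onset_sustain`` consecutive samples,
    when that disagrees with the gyro boundary by more than
    ``agree_tolerance``. If no acceleration burst is found the segmentation
    is returned unchanged (with a logged warning).
    """
    params = params or FootFlatParams()
    if not seg.foot_flat_intervals:
        return seg
    accel_norm = np.asarray(accel_norm, dtype=float)
    f0_start, f0_end = seg.foot_flat_intervals[0]
    search_end = (
        seg.foot_flat_intervals[1][0]
        if len(seg.foot_flat_intervals) > 1
        else accel_norm.size
    )
    # translation can lag the gyro-detected heel-off (heel pivot) but never
    # leads it by much; restricting the search window keeps noise bursts in
    # the stationary lead from faking an early onset
    search_start = max(f0_start, f0_end - int(round(params.agree_tolerance * seg.fs)))
    above = accel_norm[search_start:search_end] > params.onset_threshold
    sustain = max(1, params.onset_sustain)
    onset = None
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= sustain:
            onset = search_start + i - sustain + 1
            break
    if onset is None:
        logger.warning(
            "no acceleration onset above %.2f m/s^2 before the second "
            "foot-flat interval; first event left unchanged",
            params.onset_threshold,
        )
        return seg
    if abs(onset - f0_end) <= params.agree_tolerance * seg.fs:
        return seg
    new_end = max(f0_start + 1, min(onset, search_end))
    flats = [(f0_start, new_end)] + list(seg.foot_flat_intervals[1:])
    return StrideSegmentation(
        foot_flat_intervals=flats,
        strides=_strides_from_flats(flats, seg.fs, params),
        fs=seg.fs,
    )
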