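"""Pipeline configuration: one structured (YAML) file drives every command.

Defaults reproduce the acquisition and filtering protocol: 200 Hz sampling,
gyro band-pass 0.001–5 Hz, accelerometer low-pass 10 Hz, zero-phase
application, plus the detection thresholds that the protocol leaves open.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .segmentation import FootFlatParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    fs: float = 200.0
    g: float = 9.81
    gyro_highpass: float = 0.001
    gyro_lowpass: float = 5.0
    accel_lowpass: float = 10.0
    zero_phase: bool = True
    stationary_rate_threshold: float = 0.05
    stationary_min_duration: float = 0.5
    flat_enter_threshold: float = 0.3
    flat_exit_threshold: float = 0.5
    min_flat_duration: float = 0.1
    flat_refine_eps: float = 0.01
    min_stride: float = 0.3
    max_stride: float = 3.0
    onset_threshold: float = 0.5
    onset_sustain: int = 3
    agree_tolerance: float = 0.025
    calibration_diagonal: bool = False
    seed: int = 0

    def __post_init__(self):
        nyquist = self.fs / 2.0
        for name in ("gyro_lowpass", "accel_lowpass"):
            if getattr(self, name) >= nyquist:
                raise ValueError(
                    f"{name} ({getattr(self, name)} Hz) must be below the "
                    f"Nyquist frequency ({nyquist} Hz)"
                )
        if not 0 < self.gyro_highpass < self.gyro_lowpass:
            raise ValueError("gyro band must satisfy 0 < highpass < lowpass")

    @property
    def gyro_band(self) -> tuple[float, float]:
        return (self.gyro_highpass, self.gyro_lowpass)

    @property
    def accel_cutoff(self) -> float:
        return self.accel_lowpass

    @property
    def flat_params(self) -> FootFlatParams:
        return FootFlatParams(
            enter_threshold=self.flat_enter_threshold,
            exit_threshold=self.flat_exit_threshold,
            min_flat_duration=self.min_flat_duration,
            refine_eps=self.flat_refine_eps,
            min_stride=self.min_stride,
            max_stride=self.max_stride,
            onset_threshold=self.onset_threshold,
            onset_sustain=self.onset_sustain,
            agree_tolerance=self.agree_tolerance,
        )

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
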