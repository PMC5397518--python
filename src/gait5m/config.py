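"""Pipeline configuration.

All tunable constants of the analysis live here: the relative velocity
thresholds that delimit the walk, the low-pass filter used for heel-strike
detection, the template-matching floor, and the statistical protocol
(significance level, correlation cut-off, stepwise entry/removal criteria,
number of cross-validation folds).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError

SAMPLING_RATE_HZ = 100.0


@dataclass(frozen=True)
class SegmentationConfig:
    """Constants of the event detectors.

    start_frac / end_frac_* are fractions of the maximal AP velocity that
    define the start and end of movement (end threshold is condition
    dependent: self-selected vs fast walking).  The heel-strike detector
    low-pass filters vertical acceleration with a bi-directional (zero-phase)
    Butterworth filter of the given order and cut-off.
    """

    start_frac: float = 0.30
    end_frac_ss: float = 0.20
    end_frac_fs: float = 0.15
    filter_order: int = 4
    filter_cutoff_hz: float = 3.5
    bidirectional: bool = True
    correlation_floor: float = 0.4
    refractory_frac: float = 0.5
    provisional_min_separation_s: float = 0.3
    peak_prominence_frac: float = 0.1

    def validate(self) -> None:
        for name in ("start_frac", "end_frac_ss", "end_frac_fs",
                     "refractory_frac", "peak_prominence_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if not 0.0 < self.filter_cutoff_hz < SAMPLING_RATE_HZ / 2:
            raise ValidationError(
                f"filter cutoff must lie below Nyquist "
                f"({SAMPLING_RATE_HZ / 2:.0f} Hz), got {self.filter_cutoff_hz}")
        if self.filter_order < 1:
            raise ValidationError("filter order must be >= 1")
        if not 0.0 <= self.correlation_floor < 1.0:
            raise ValidationError("correlation_floor must be in [0, 1)")


@dataclass(frozen=True)
class KinematicsConfig:
    """Zero-velocity anchor windows and the static-subject criterion.

    The pre-walk window is expressed relative to the acoustic start signal;
    the post-walk window is the final ``post_window_s`` seconds of the trial.
    Both lie inside the protocol's guaranteed 3-s standing phases.
    """

    pre_window_rel_acoustic_s: tuple[float, float] = (-2.0, -0.5)
    post_window_s: float = 1.5
    static_gyro_rms_max_dps: float = 5.0
    gravity_mps2: float = 9.81

    def validate(self) -> None:
        a, b = self.pre_window_rel_acoustic_s
        if b <= a:
            raise ValidationError("pre-window must have positive length")
        if self.post_window_s < 1.0:
            raise ValidationError("post-window must span at least 1 s")
        if self.static_gyro_rms_max_dps <= 0:
            raise ValidationError("static gyro RMS threshold must be > 0")


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    corr_cutoff: float = 0.7
    p_enter: float = 0.05
    p_remove: float = 0.10
    folds: int = 10
    welch: bool = False  # Student's pooled-variance t by default

    def validate(self) -> None:
        for name in ("alpha", "corr_cutoff", "p_enter", "p_remove"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")


@dataclass(frozen=True)
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def validate(self) -> None:
        self.segmentation.validate()
        self.kinematics.validate()
        self.stats.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Stable hash of the full configuration, embedded in every report."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, sub):
            known = {f.name for f in dataclasses.fields(klass)}
            bad = set(sub) - known
            if bad:
                raise ValidationError(f"unknown config keys: {sorted(bad)}")
            sub = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in sub.items()}
            return klass(**sub)

        cfg = cls(
            segmentation=build(SegmentationConfig, d.get("segmentation", {})),
            kinematics=build(KinematicsConfig, d.get("kinematics", {})),
            stats=build(StatsConfig, d.get("stats", {})),
            seed=int(d.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValidationError(f"config file {path} is not a mapping")
        return cls.from_dict(d)
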