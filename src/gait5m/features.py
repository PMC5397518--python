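"""Per-trial kinematic-parameter inventory.

Nine features per gait phase -- duration, AP displacement, AP velocity
range, and the RMS of the mean-subtracted signal (within-phase population
standard deviation) for the three acceleration and three angular-velocity
channels -- computed in absolute form for the eight named phases and, for
each, relative to the unweighted mean of that feature across all steps of
the trial.  The across-step means themselves and two trial-level quantities
(average gait speed between start and end of movement, and the step count)
complete the inventory: 155 parameters per speed condition.

Relative values are ratios (value / across-step mean); when a mean is zero
the ratio is flagged undefined (NaN), never silently zeroed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FeatureError
from .kinematics import KinematicTrace
from .segmentation import PHASE_NAMES, GaitSegmentation

__all__ = [
    "FEATURE_NAMES", "FeatureSet",
    "phase_features", "across_step_means", "relative_features",
    "trial_features", "inventory_keys",
]

FEATURE_NAMES = (
    "duration_s",
    "displacement_m",
    "vel_range_mps",
    "rms_acc_vt",
    "rms_acc_ml",
    "rms_acc_ap",
    "rms_gyr_vt",
    "rms_gyr_ml",
    "rms_gyr_ap",
)

_RMS_CHANNELS = {
    "rms_acc_vt": "acc_vt", "rms_acc_ml": "acc_ml", "rms_acc_ap": "acc_ap",
    "rms_gyr_vt": "gyr_vt", "rms_gyr_ml": "gyr_ml", "rms_gyr_ap": "gyr_ap",
}


def inventory_keys() -> tuple[str, ...]:
    """Canonical ordered key list of the per-condition parameter inventory.

    The key set is identical for every successful trial of a condition:
    ``<phase>|<feature>|abs``, ``<phase>|<feature>|rel``,
    ``step_mean|<feature>``, ``gait_speed_mps`` and ``n_steps``.
    """
    keys: list[str] = []
    for phase in PHASE_NAMES:
        for feat in FEATURE_NAMES:
            keys.append(f"{phase}|{feat}|abs")
    for phase in PHASE_NAMES:
        for feat in FEATURE_NAMES:
            keys.append(f"{phase}|{feat}|rel")
    for feat in FEATURE_NAMES:
        keys.append(f"step_mean|{feat}")
    keys += ["gait_speed_mps", "n_steps"]
    return tuple(keys)


@dataclass
class FeatureSet:
    """Full kinematic-parameter inventory of one trial."""

    entries: dict[str, float]
    condition: str
    subject_id: str = "S00"
    trial_id: str = "T0"
    per_step: list[dict[str, float]] = field(default_factory=list)

    def as_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {
            "subject_id": self.subject_id,
            "trial_id": self.trial_id,
            "condition": self.condition,
        }
        row.update(self.entries)
        return row


def _slice(trace: KinematicTrace, interval: tuple[float, float]) -> slice:
    a, b = interval
    t = trace.time_s
    if b <= a:
        raise FeatureError(f"interval {interval} has non-positive length")
    if a < t[0] - 1e-9 or b > t[-1] + 1e-9:
        raise FeatureError(f"interval {interval} outside the trace")
    i = int(np.searchsorted(t, a - 1e-9))
    j = int(np.searchsorted(t, b + 1e-9))
    if j - i < 3:
        raise FeatureError(f"interval {interval} has < 3 samples")
    return slice(i, j)


def phase_features(trace: KinematicTrace,
                   interval: tuple[float, float]) -> dict[str, float]:
    """The nine features of one phase interval."""
    sl = _slice(trace, interval)
    a, b = interval
    out = {
        "duration_s": float(b - a),
        "displacement_m": float(trace.disp_ap[sl.stop - 1]
                                - trace.disp_ap[sl.start]),
        "vel_range_mps": float(np.ptp(trace.vel_ap[sl])),
    }
    for feat, chan in _RMS_CHANNELS.items():
        out[feat] = float(np.std(getattr(trace, chan)[sl]))
    return out


def across_step_means(per_step: list[dict[str, float]]) -> dict[str, float]:
    """Unweighted arithmetic mean of each feature over all steps."""
    if not per_step:
        raise FeatureError("across-step means need at least one step")
    return {feat: float(np.mean([s[feat] for s in per_step]))
            for feat in FEATURE_NAMES}


def relative_features(absolute: dict[str, float],
                      means: dict[str, float]) -> dict[str, float]:
    """Ratio of each phase feature to its across-step mean (dimensionless).

    A zero mean makes the ratio undefined; it propagates as NaN.
    """
    out = {}
    for feat, value in absolute.items():
        m = means[feat]
        out[feat] = value / m if m != 0 else float("nan")
    return out


def trial_features(trace: KinematicTrace, seg: GaitSegmentation,
                   condition: str | None = None) -> FeatureSet:
    """Assemble the full 155-key inventory for one segmented trial."""
    cond = condition or trace.condition
    if seg.n_steps < 5:
        raise FeatureError("segmentation has < 5 steps")
    per_step = [phase_features(trace, step) for step in seg.steps]
    means = across_step_means(per_step)

    entries: dict[str, float] = {}
    for phase in PHASE_NAMES:
        absolute = phase_features(trace, seg.phases[phase])
        for feat in FEATURE_NAMES:
            entries[f"{phase}|{feat}|abs"] = absolute[feat]
        rel = relative_features(absolute, means)
        for feat in FEATURE_NAMES:
            entries[f"{phase}|{feat}|rel"] = rel[feat]
    for feat in FEATURE_NAMES:
        entries[f"step_mean|{feat}"] = means[feat]

    walk = seg.phases["full_walk"]
    wf = phase_features(trace, walk)
    entries["gait_speed_mps"] = wf["displacement_m"] / wf["duration_s"]
    entries["n_steps"] = float(seg.n_steps)

    ordered = {k: entries[k] for k in inventory_keys()}
    return FeatureSet(entries=ordered, condition=cond,
                      subject_id=trace.subject_id, trial_id=trace.trial_id,
                      per_step=per_step)
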