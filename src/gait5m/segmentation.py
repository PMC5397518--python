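"""Gait-event detection and phase construction.

The walk is delimited on the drift-corrected AP velocity by relative
thresholds (start: first instant at or above 30% of the maximal velocity;
end: last instant at or above 20% for self-selected speed, 15% for fast).
The first heel strike is the first prominent peak of the 3.5 Hz zero-phase
low-pass filtered VT acceleration after the start of movement.  Step cycles
inside the walk are found by normalized cross-correlation of a
subject-specific template (the average of provisional step segments of raw
AP acceleration) against the raw AP acceleration.  Eight named phases are
then assembled; the final heel strike is excluded (the last analysed step
runs from the last detected event to the end of movement, i.e. the terminal
positioning step is never analysed).

Step indexing convention: steps are numbered 1..m with step i spanning
[e_i, e_{i+1}] for i < m and step m spanning [e_m, t_end].  "Second step" is
step 2, "middle step" is step floor((m+1)/2) (ties toward earlier),
"pre-last" is step m-1 and "last" is step m.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks, lfilter

from .config import SAMPLING_RATE_HZ, SegmentationConfig
from .errors import NoMovementError, SegmentationError, ValidationError
from .kinematics import KinematicTrace

__all__ = [
    "GaitSegmentation", "StepTemplate",
    "detect_start_end", "detect_first_heel_strike",
    "build_template", "match_steps", "construct_phases", "segment_trial",
    "PHASE_NAMES",
]

PHASE_NAMES = (
    "full_walk",
    "acoustic_to_start",
    "acoustic_to_first_hs",
    "second_step",
    "third_step",
    "middle_step",
    "prelast_step",
    "last_step",
)

_DT = 1.0 / SAMPLING_RATE_HZ


@dataclass(frozen=True)
class StepTemplate:
    """Zero-mean, unit-norm AP-acceleration step template."""

    waveform: np.ndarray
    length_s: float

    def validate(self) -> None:
        if abs(float(np.mean(self.waveform))) > 1e-9:
            raise ValidationError("template must be zero-mean")
        if abs(float(np.linalg.norm(self.waveform)) - 1.0) > 1e-9:
            raise ValidationError("template must be unit-norm")


@dataclass
class GaitSegmentation:
    """Start/end of movement, first heel strike, step events and phases."""

    t_start_s: float
    t_end_s: float
    t_first_hs_s: float
    step_events_s: np.ndarray
    steps: list[tuple[float, float]]
    phases: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def validate(self) -> None:
        ev = np.asarray(self.step_events_s)
        if not self.t_start_s < self.t_first_hs_s <= ev[0]:
            raise ValidationError(
                "require t_start < first heel strike <= first step event")
        if np.any(np.diff(ev) <= 0):
            raise ValidationError("step events must strictly increase")
        for a, b in self.steps:
            if not (self.t_start_s <= a < b <= self.t_end_s + 1e-9):
                raise ValidationError("step interval outside the walk")
        missing = set(PHASE_NAMES) - set(self.phases)
        if missing:
            raise ValidationError(f"missing phases: {sorted(missing)}")
        for name, (a, b) in self.phases.items():
            if b - a <= 0:
                raise ValidationError(f"phase {name} has non-positive duration")


def _lowpass(x: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    b, a = butter(cfg.filter_order,
                  cfg.filter_cutoff_hz / (SAMPLING_RATE_HZ / 2.0))
    return filtfilt(b, a, x) if cfg.bidirectional else lfilter(b, a, x)


def detect_start_end(time_s: np.ndarray, vel_ap: np.ndarray, condition: str,
                     config: SegmentationConfig | None = None,
                     ) -> tuple[float, float]:
    """Start and end of movement from relative AP-velocity thresholds."""
    cfg = config or SegmentationConfig()
    if condition not in ("SS", "FS"):
        raise ValidationError(f"unknown condition {condition!r}")
    vmax = float(np.max(vel_ap))
    if vmax <= 0:
        raise NoMovementError("no movement detected: AP velocity never > 0")
    end_frac = cfg.end_frac_ss if condition == "SS" else cfg.end_frac_fs
    above_start = np.flatnonzero(vel_ap >= cfg.start_frac * vmax)
    above_end = np.flatnonzero(vel_ap >= end_frac * vmax)
    if len(above_start) == 0 or len(above_end) == 0:
        raise NoMovementError("no movement detected: thresholds never crossed")
    t_start = float(time_s[above_start[0]])
    t_end = float(time_s[above_end[-1]])
    if not t_start < t_end:
        raise NoMovementError("degenerate movement bounds")
    return t_start, t_end


def detect_first_heel_strike(time_s: np.ndarray, acc_vt: np.ndarray,
                             t_start_s: float,
                             config: SegmentationConfig | None = None,
                             ) -> float:
    """First prominent peak of low-pass filtered VT acceleration after start.

    A relative prominence floor (``peak_prominence_frac`` of the filtered
    signal's range) rejects noise ripples between the start of movement and
    the first genuine heel-strike peak.
    """
    cfg = config or SegmentationConfig()
    if not time_s[0] <= t_start_s <= time_s[-1]:
        raise ValidationError("t_start outside the trace")
    filt = _lowpass(acc_vt, cfg)
    prominence = cfg.peak_prominence_frac * float(np.ptp(filt))
    peaks, _ = find_peaks(filt, prominence=max(prominence, 1e-12))
    peaks = peaks[time_s[peaks] > t_start_s]
    if len(peaks) == 0:
        raise SegmentationError("no VT peak found after start of movement")
    return float(time_s[peaks[0]])


def provisional_events(time_s: np.ndarray, acc_vt: np.ndarray,
                       t_start_s: float, t_end_s: float,
                       config: SegmentationConfig | None = None) -> np.ndarray:
    """Heel-strike surrogates for template building: filtered-VT peaks."""
    cfg = config or SegmentationConfig()
    filt = _lowpass(acc_vt, cfg)
    sel = (time_s >= t_start_s) & (time_s <= t_end_s)
    sub = filt[sel]
    prominence = cfg.peak_prominence_frac * float(np.ptp(sub))
    distance = max(1, int(round(cfg.provisional_min_separation_s
                                * SAMPLING_RATE_HZ)))
    peaks, _ = find_peaks(sub, prominence=max(prominence, 1e-12),
                          distance=distance)
    return time_s[sel][peaks]


def build_template(time_s: np.ndarray, acc_ap: np.ndarray,
                   provisional_events_s: np.ndarray) -> StepTemplate:
    """Average AP-acceleration step segment, time-normalized.

    Segments between consecutive provisional events are linearly resampled
    to the median segment length (in samples), averaged, mean-subtracted and
    scaled to unit norm.
    """
    ev = np.asarray(provisional_events_s, dtype=float)
    if len(ev) < 3:
        raise SegmentationError(
            f"need >= 3 provisional events to build a template, got {len(ev)}")
    idx = np.searchsorted(time_s, ev)
    lengths = np.diff(idx)
    if np.any(lengths < 2):
        raise SegmentationError("provisional events too close together")
    target = int(np.median(lengths))
    xi = np.arange(target) / target
    segments = []
    for a, b in zip(idx[:-1], idx[1:]):
        seg = acc_ap[a:b]
        segments.append(np.interp(xi, np.arange(len(seg)) / len(seg), seg))
    tpl = np.mean(segments, axis=0)
    tpl = _detrend(tpl)
    norm = float(np.linalg.norm(tpl))
    if norm == 0:
        raise SegmentationError("degenerate (constant) template")
    return StepTemplate(waveform=tpl / norm, length_s=target * _DT)


def _detrend(seg: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend (cyclic shape extraction)."""
    n = len(seg)
    t = np.arange(n) - (n - 1) / 2.0
    return seg - seg.mean() - (t @ seg) / (t @ t) * t


def _normalized_correlation(x: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Trend-insensitive normalized cross-correlation.

    Entry k is the correlation of the (zero-mean, unit-norm) template with
    the window starting at sample k, each window linearly detrended and
    norm-scaled; values in [-1, 1].  Detrending makes the match respond to
    the cyclic step shape rather than to the walk's acceleration/
    deceleration trend.
    """
    L = len(template)
    n = len(x) - L + 1
    if n < 1:
        raise SegmentationError("signal shorter than template")
    win = np.lib.stride_tricks.sliding_window_view(x, L)
    t = np.arange(L) - (L - 1) / 2.0
    tt = float(t @ t)
    mean = win.mean(axis=1)
    slope = (win @ t) / tt
    # template is zero-mean and linearly detrended, so only the window's
    # detrended part contributes to the inner product
    num = win @ template - slope * float(t @ template)
    sq = (np.einsum("ij,ij->i", win, win) - L * mean**2 - slope**2 * tt)
    denom = np.sqrt(np.maximum(sq, 0.0))
    out = np.zeros(n)
    ok = denom > 1e-12
    out[ok] = num[ok] / denom[ok]
    return np.clip(out, -1.0, 1.0)


def match_steps(time_s: np.ndarray, acc_ap: np.ndarray,
                template: StepTemplate, t_start_s: float, t_end_s: float,
                config: SegmentationConfig | None = None) -> np.ndarray:
    """Step events as maxima of template/signal normalized cross-correlation.

    Events are correlation local maxima above ``correlation_floor``,
    separated by at least ``refractory_frac`` of the template duration, with
    event time taken at the window start (the template starts at a
    heel-strike surrogate).  Only events inside [t_start, t_end] are
    returned.  At plateau maxima the earliest sample wins; event times are
    sample-aligned.
    """
    cfg = config or SegmentationConfig()
    template.validate()
    if not t_start_s < t_end_s:
        raise ValidationError("require t_start < t_end")
    corr = _normalized_correlation(acc_ap, template.waveform)
    distance = max(1, int(round(cfg.refractory_frac * template.length_s
                                * SAMPLING_RATE_HZ)))
    peaks, _ = find_peaks(corr, height=cfg.correlation_floor,
                          distance=distance)
    t_ev = time_s[peaks]
    t_ev = t_ev[(t_ev >= t_start_s) & (t_ev <= t_end_s)]
    if len(t_ev) == 0:
        raise SegmentationError(
            "no correlation peak above floor inside the walk")
    return t_ev


def construct_phases(t_acoustic_s: float, t_start_s: float, t_end_s: float,
                     t_first_hs_s: float,
                     step_events_s: np.ndarray) -> GaitSegmentation:
    """Assemble steps and the eight named gait phases from detected events."""
    ev = np.asarray(step_events_s, dtype=float)
    if len(ev) < 5:
        raise SegmentationError(
            f"trial too short for phase inventory: {len(ev)} step events < 5")
    m = len(ev)
    steps = [(float(ev[i]), float(ev[i + 1])) for i in range(m - 1)]
    steps.append((float(ev[-1]), t_end_s))
    mid = (m + 1) // 2  # 1-based, ties toward earlier
    phases = {
        "full_walk": (t_start_s, t_end_s),
        "acoustic_to_start": (t_acoustic_s, t_start_s),
        "acoustic_to_first_hs": (t_acoustic_s, t_first_hs_s),
        "second_step": steps[1],
        "third_step": steps[2],
        "middle_step": steps[mid - 1],
        "prelast_step": steps[m - 2],
        "last_step": steps[m - 1],
    }
    seg = GaitSegmentation(
        t_start_s=t_start_s, t_end_s=t_end_s, t_first_hs_s=t_first_hs_s,
        step_events_s=ev, steps=steps, phases=phases)
    seg.validate()
    return seg


def segment_trial(trace: KinematicTrace,
                  config: SegmentationConfig | None = None) -> GaitSegmentation:
    """Run the full detector chain on a reconstructed trial.

    The VT-peak first-heel-strike estimate and the first template-matched
    event target the same physical event; when they agree within 80 ms the
    earlier of the two is taken as the first heel strike so that event
    ordering is always consistent.
    """
    cfg = config or SegmentationConfig()
    t_start, t_end = detect_start_end(
        trace.time_s, trace.vel_ap, trace.condition, cfg)
    t_hs = detect_first_heel_strike(trace.time_s, trace.acc_vt, t_start, cfg)
    prov = provisional_events(trace.time_s, trace.acc_vt, t_start, t_end, cfg)
    # template from steady mid-walk cycles: drop the first and last
    # provisional segment (gait initiation / termination) when enough remain
    tpl_events = prov[1:-1] if len(prov) >= 6 else prov
    template = build_template(trace.time_s, trace.acc_ap, tpl_events)
    events = match_steps(trace.time_s, trace.acc_ap, template,
                         t_start, t_end, cfg)
    if abs(events[0] - t_hs) <= 0.08:
        t_hs = min(t_hs, float(events[0]))
    return construct_phases(trace.acoustic_time_s, t_start, t_end, t_hs,
                            events)
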