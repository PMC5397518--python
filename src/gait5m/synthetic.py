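"""Seeded synthetic lower-back IMU recordings of 5-m walks.

The generator emulates the structure of an instrumented 5-m walking trial
recorded at 100 samples/s from a 6-axis sensor at L5: quiet standing, an
acoustic start signal, a reaction delay, gait initiation, a handful of steps
with a velocity envelope (ramp up - plateau - ramp down), terminal
positioning, and quiet standing again.  Every trial carries full ground-truth
event annotations so each downstream detector can be validated without
external data.

Signal model
------------
* AP velocity is built analytically: a raised-cosine ramp up over the first
  ``accel_phase_steps`` steps, a plateau, a raised-cosine ramp down over the
  final ``decel_phase_steps`` steps plus the positioning step, with a
  zero-mean per-step sinusoidal oscillation superimposed (windowed by the
  envelope).  The peak velocity is solved so the enclosed area equals the
  track length (5 m by default).
* AP acceleration is emitted as the exact discrete inverse of trapezoidal
  integration of that velocity, so integrating the emitted signal recovers
  the ground-truth velocity and displacement to float precision.
* VT acceleration carries a per-step cosine peaking at each heel strike plus
  a short (~60 ms) positive Gaussian transient at each ground-truth heel
  strike; ML acceleration and the three angular-velocity channels carry step-
  or stride-periodic oscillations.
* The accelerometer is DC-coupled: gravity appears on the VT axis and the
  whole 6-axis signal is rotated by a static sensor-tilt (pitch) before
  white Gaussian sensor noise is added.

Group effects (PD vs healthy controls) scale the reaction delay, the mean
step duration and the roll (AP-axis) angular-velocity amplitude.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np

from .config import SAMPLING_RATE_HZ
from .errors import ValidationError

__all__ = [
    "GaitProfile",
    "GroundTruthEvents",
    "ImuTrial",
    "make_group_profile",
    "simulate_trial",
    "simulate_cohort",
]

_DT = 1.0 / SAMPLING_RATE_HZ
_TRANSIENT_SIGMA_S = 0.012  # ~60 ms full width at each heel strike

#: fields multiplied by lognormal jitter when drawing a subject from a group
_TIMING_JITTER_FIELDS = ("step_duration_mean_s",)
_AMPLITUDE_JITTER_FIELDS = (
    "reaction_delay_s",
    "vt_acc_amplitude",
    "ml_acc_amplitude",
    "ap_acc_amplitude",
    "gyro_amplitude_vt",
    "gyro_amplitude_ml",
    "gyro_amplitude_ap",
    "heelstrike_transient_amplitude",
)


@dataclass(frozen=True)
class GaitProfile:
    """Parameters of one simulated walker.

    Amplitudes are in m/s^2 (accelerations) and deg/s (angular velocities);
    durations in seconds.  ``sensor_tilt_deg`` is a static pitch misalignment
    of the sensor relative to the anatomical frame.
    """

    reaction_delay_s: float = 0.40
    n_steps: int = 8
    step_duration_mean_s: float = 0.55
    step_duration_sd_s: float = 0.02
    peak_ap_velocity_mps: float = 1.38
    accel_phase_steps: int = 2
    decel_phase_steps: int = 2
    vt_acc_amplitude: float = 2.0
    ml_acc_amplitude: float = 1.2
    ap_acc_amplitude: float = 1.5
    gyro_amplitude_vt: float = 25.0
    gyro_amplitude_ml: float = 30.0
    gyro_amplitude_ap: float = 20.0
    heelstrike_transient_amplitude: float = 3.0
    sensor_tilt_deg: float = 5.0
    noise_sd_acc: float = 0.05
    noise_sd_gyro: float = 1.0
    standing_pre_s: float = 3.5
    standing_post_s: float = 3.5
    track_length_m: float = 5.0
    first_step_frac: float = 0.9  # gait-initiation time as fraction of a step

    def validate(self) -> None:
        if self.n_steps < 5:
            raise ValidationError("n_steps must be >= 5")
        if self.standing_pre_s < 3.0 or self.standing_post_s < 3.0:
            raise ValidationError("standing phases must each span >= 3 s")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in ("n_steps", "accel_phase_steps", "decel_phase_steps"):
                continue
            if v < 0:
                raise ValidationError(f"{f.name} must be >= 0, got {v}")
        if self.accel_phase_steps < 1 or self.decel_phase_steps < 1:
            raise ValidationError("accel/decel phases must span >= 1 step")
        if self.accel_phase_steps + self.decel_phase_steps >= self.n_steps:
            raise ValidationError(
                "accel + decel phases must leave at least one plateau step")
        if self.track_length_m <= 0:
            raise ValidationError("track_length_m must be > 0")
        # the envelope implied by the profile's own fields must enclose the
        # configured track length to within 1%
        vp = _solve_peak_velocity(self, self._nominal_durations())
        err = abs(vp - self.peak_ap_velocity_mps) / vp
        if err > 0.01:
            raise ValidationError(
                f"peak_ap_velocity_mps inconsistent with track length "
                f"({self.peak_ap_velocity_mps:.3f} vs required {vp:.3f})")

    def _nominal_durations(self) -> np.ndarray:
        return np.full(self.n_steps, self.step_duration_mean_s)


@dataclass(frozen=True)
class GroundTruthEvents:
    """True event annotations of one simulated trial."""

    acoustic_time_s: float
    movement_onset_s: float
    heel_strike_times_s: np.ndarray
    movement_end_s: float
    true_step_durations_s: np.ndarray
    true_displacement_m: float

    def validate(self) -> None:
        hs = np.asarray(self.heel_strike_times_s)
        if not (self.acoustic_time_s < self.movement_onset_s
                < hs[0] < self.movement_end_s):
            raise ValidationError("ground-truth event times out of order")
        if np.any(np.diff(hs) <= 0):
            raise ValidationError("heel-strike times must strictly increase")
        if len(self.true_step_durations_s) != len(hs):
            raise ValidationError(
                "step-duration list inconsistent with heel strikes")


@dataclass
class ImuTrial:
    """One trial's 6-axis sensor-frame signals plus metadata.

    ``acc`` and ``gyr`` are (n, 3) arrays with columns (VT, ML, AP);
    accelerations in m/s^2 (DC-coupled, gravity included), angular velocities
    in deg/s.
    """

    time_s: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    acoustic_time_s: float
    condition: str
    subject_id: str = "S00"
    trial_id: str = "T0"

    def validate(self) -> None:
        dt = np.diff(self.time_s)
        if len(self.time_s) < 2 or np.any(np.abs(dt - _DT) > 1e-6):
            raise ValidationError("trial must be uniformly sampled at 100/s")
        if self.acc.shape != (len(self.time_s), 3):
            raise ValidationError("acc must be (n, 3)")
        if self.gyr.shape != (len(self.time_s), 3):
            raise ValidationError("gyr must be (n, 3)")
        if self.condition not in ("SS", "FS"):
            raise ValidationError(f"unknown condition {self.condition!r}")


def make_group_profile(group_label: str, effect_scale: float = 1.0,
                       condition: str = "SS") -> GaitProfile:
    """Build the nominal gait profile of a group.

    Healthy controls (``HC``) are the reference.  For ``PD`` with
    ``effect_scale > 0`` the profile has a longer reaction delay, a shorter
    mean step duration and a larger roll (AP-axis) angular-velocity
    amplitude; ``effect_scale = 0`` makes the groups identical.

    The fast condition (``FS``) takes one step fewer with ~15% shorter steps;
    the peak velocity rises accordingly because the track length is fixed.
    """
    if group_label not in ("HC", "PD"):
        raise ValidationError(f"unknown group label {group_label!r}")
    if effect_scale < 0:
        raise ValidationError("effect_scale must be >= 0")
    if condition not in ("SS", "FS"):
        raise ValidationError(f"unknown condition {condition!r}")

    prof = GaitProfile()
    if condition == "FS":
        prof = replace(
            prof,
            n_steps=prof.n_steps - 1,
            step_duration_mean_s=prof.step_duration_mean_s * 0.85,
            step_duration_sd_s=prof.step_duration_sd_s * 0.85,
            reaction_delay_s=prof.reaction_delay_s * 0.9,
        )
    if group_label == "PD" and effect_scale > 0:
        s = effect_scale
        # shorter, more numerous steps keep gait speed roughly matched
        prof = replace(
            prof,
            reaction_delay_s=prof.reaction_delay_s * (1.0 + 0.5 * s),
            step_duration_mean_s=prof.step_duration_mean_s * max(
                0.5, 1.0 - 0.08 * s),
            n_steps=int(round(prof.n_steps * (1.0 + 0.10 * s))),
            gyro_amplitude_ap=prof.gyro_amplitude_ap * (1.0 + 0.35 * s),
        )
    vp = _solve_peak_velocity(prof, prof._nominal_durations())
    prof = replace(prof, peak_ap_velocity_mps=vp)
    prof.validate()
    return prof


# ----------------------------------------------------------------------
# envelope construction helpers

def _event_grid(profile: GaitProfile, durations: np.ndarray):
    """Timing skeleton: onset, heel strikes, positioning strike, envelope end.

    Heel strike i+1 = heel strike i + duration of step i; the final
    (positioning) strike ends the last counted step but carries no transient
    and is excluded from the ground-truth heel-strike list, mirroring a
    subject's final foot placement after forward progression has dropped.
    """
    t_ac = profile.standing_pre_s
    t0 = t_ac + profile.reaction_delay_s
    r0 = profile.first_step_frac * durations[0]
    hs = t0 + r0 + np.concatenate(([0.0], np.cumsum(durations[:-1])))
    pos_strike = hs[-1] + durations[-1]
    env_end = pos_strike + 0.3 * float(np.mean(durations))
    plateau_start = hs[profile.accel_phase_steps - 1]
    decel_start = hs[profile.n_steps - profile.decel_phase_steps - 1]
    return t_ac, t0, hs, pos_strike, env_end, plateau_start, decel_start


def _solve_peak_velocity(profile: GaitProfile, durations: np.ndarray) -> float:
    """Peak AP velocity such that the envelope area equals the track length."""
    _, t0, _, _, env_end, ps, ds = _event_grid(profile, durations)
    t_up, t_down = ps - t0, env_end - ds
    area_per_vp = 0.5 * t_up + (ds - ps) + 0.5 * t_down
    return profile.track_length_m / area_per_vp


def _envelope(t: np.ndarray, t0: float, plateau_start: float,
              decel_start: float, env_end: float, vp: float) -> np.ndarray:
    env = np.zeros_like(t)
    up = (t >= t0) & (t < plateau_start)
    env[up] = 0.5 * vp * (1 - np.cos(np.pi * (t[up] - t0)
                                     / (plateau_start - t0)))
    env[(t >= plateau_start) & (t < decel_start)] = vp
    down = (t >= decel_start) & (t < env_end)
    env[down] = 0.5 * vp * (1 + np.cos(np.pi * (t[down] - decel_start)
                                       / (env_end - decel_start)))
    return env


def _step_phase(t: np.ndarray, bounds: np.ndarray):
    """Per-sample step index (0-based, -1 outside) and phase in [0, 1)."""
    idx = np.searchsorted(bounds, t, side="right") - 1
    inside = (idx >= 0) & (idx < len(bounds) - 1)
    idx = np.where(inside, idx, -1)
    tau = np.zeros_like(t)
    ok = idx >= 0
    lo = bounds[idx[ok]]
    hi = bounds[idx[ok] + 1]
    tau[ok] = (t[ok] - lo) / (hi - lo)
    return idx, tau


def _trapezoid_inverse(vel: np.ndarray, dt: float) -> np.ndarray:
    """Acceleration whose cumulative trapezoid exactly reproduces ``vel``.

    Solves a[k+1] = 2*(v[k+1]-v[k])/dt - a[k] with a[0] = 0.  The residual
    against the analytic derivative is a bounded alternating Nyquist
    component of order dt^2 * |v'''|, well below sensor noise.
    """
    c = 2.0 * np.diff(vel) / dt
    sign = (-1.0) ** np.arange(1, len(vel))
    acc = np.empty_like(vel)
    acc[0] = 0.0
    acc[1:] = sign * np.cumsum(sign * c)
    return acc


def _tilt_rotation(tilt_deg: float) -> np.ndarray:
    """Rotation (anatomical -> sensor frame) for a pitch tilt about ML."""
    th = np.deg2rad(tilt_deg)
    c, s = np.cos(th), np.sin(th)
    # columns/rows ordered (VT, ML, AP); pitch mixes VT and AP
    return np.array([[c, 0.0, -s],
                     [0.0, 1.0, 0.0],
                     [s, 0.0, c]])


# ----------------------------------------------------------------------

def simulate_trial(profile: GaitProfile, condition: str, seed: int,
                   subject_id: str = "S00", trial_id: str = "T0",
                   ) -> tuple[ImuTrial, GroundTruthEvents]:
    """Simulate one 5-m walking trial.

    Identical ``(profile, condition, seed)`` give bit-identical output.  The
    ``condition`` label is recorded on the trial and selects the end-of-walk
    threshold downstream; speed differences between conditions are encoded in
    the profile itself (see :func:`make_group_profile`).
    """
    profile.validate()
    if condition not in ("SS", "FS"):
        raise ValidationError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)

    mean_d, sd_d = profile.step_duration_mean_s, profile.step_duration_sd_s
    durations = rng.normal(mean_d, sd_d, profile.n_steps)
    durations = np.clip(durations, 0.3 * mean_d, 2.0 * mean_d)

    t_ac, t0, hs, pos_strike, env_end, ps, ds = _event_grid(profile, durations)
    vp = _solve_peak_velocity(profile, durations)

    total_s = env_end + profile.standing_post_s
    n = int(round(total_s / _DT)) + 1
    t = np.arange(n) * _DT

    env = _envelope(t, t0, ps, ds, env_end, vp)

    # step grid for oscillations: counted steps plus the positioning step
    bounds = np.concatenate((hs, [pos_strike, env_end]))
    idx, tau = _step_phase(t, bounds)
    in_step = (idx >= 0) & (idx < profile.n_steps)
    in_pos = idx == profile.n_steps  # terminal positioning step
    d_of = np.where(idx >= 0, np.diff(bounds)[np.maximum(idx, 0)], 1.0)
    parity = np.where(idx >= 0, (-1.0) ** np.maximum(idx, 0), 0.0)
    # step-cycle amplitude: full during counted steps, cosine taper over the
    # terminal positioning step (cadence-linked sway does not scale with the
    # forward-speed envelope)
    amp = np.where(in_step, 1.0, 0.0) \
        + np.where(in_pos, 0.5 * (1 + np.cos(np.pi * tau)), 0.0)
    moving = in_step | in_pos

    # AP velocity: envelope + zero-mean per-step oscillation (exact zero net
    # displacement per step while the amplitude is constant)
    v_osc = np.where(
        moving,
        profile.ap_acc_amplitude * d_of / (2 * np.pi)
        * np.sin(2 * np.pi * tau),
        0.0)
    vel_ap = env + amp * v_osc
    acc_ap = _trapezoid_inverse(vel_ap, _DT)

    osc = np.where(moving, np.cos(2 * np.pi * tau), 0.0)
    acc_vt = profile.vt_acc_amplitude * amp * osc
    for h in hs:  # heel-strike transients, counted steps only
        acc_vt += profile.heelstrike_transient_amplitude * np.exp(
            -0.5 * ((t - h) / _TRANSIENT_SIGMA_S) ** 2)
    acc_ml = profile.ml_acc_amplitude * amp * parity * np.where(
        moving, np.sin(np.pi * tau), 0.0)

    gyr_vt = profile.gyro_amplitude_vt * amp * parity * np.where(
        moving, np.sin(np.pi * tau + 0.4), 0.0)
    gyr_ml = profile.gyro_amplitude_ml * amp * np.where(
        moving, np.sin(2 * np.pi * tau + 0.5 * np.pi), 0.0)
    gyr_ap = profile.gyro_amplitude_ap * amp * parity * np.where(
        moving, np.sin(np.pi * tau + 1.0), 0.0)

    acc_body = np.column_stack((acc_vt + 9.81, acc_ml, acc_ap))
    gyr_body = np.column_stack((gyr_vt, gyr_ml, gyr_ap))
    rot = _tilt_rotation(profile.sensor_tilt_deg)
    acc_sensor = acc_body @ rot.T
    gyr_sensor = gyr_body @ rot.T
    acc_sensor = acc_sensor + rng.normal(0.0, profile.noise_sd_acc, (n, 3))
    gyr_sensor = gyr_sensor + rng.normal(0.0, profile.noise_sd_gyro, (n, 3))

    trial = ImuTrial(time_s=t, acc=acc_sensor, gyr=gyr_sensor,
                     acoustic_time_s=t_ac, condition=condition,
                     subject_id=subject_id, trial_id=trial_id)
    true_disp = float(np.trapezoid(vel_ap, dx=_DT))
    step_durations = np.append(np.diff(hs), pos_strike - hs[-1])
    truth = GroundTruthEvents(
        acoustic_time_s=t_ac,
        movement_onset_s=t0,
        heel_strike_times_s=hs,
        movement_end_s=env_end,
        true_step_durations_s=step_durations,
        true_displacement_m=true_disp,
    )
    truth.validate()
    return trial, truth


@dataclass(frozen=True)
class CohortRecord:
    subject_id: str
    group: str
    trial: ImuTrial
    truth: GroundTruthEvents


def _jitter_profile(profile: GaitProfile, rng: np.random.Generator,
                    timing_sigma: float = 0.05,
                    amplitude_sigma: float = 0.15) -> GaitProfile:
    """Lognormal multiplicative between-subject jitter (keeps values > 0)."""
    updates = {}
    for f in _TIMING_JITTER_FIELDS:
        updates[f] = getattr(profile, f) * rng.lognormal(0.0, timing_sigma)
    for f in _AMPLITUDE_JITTER_FIELDS:
        updates[f] = getattr(profile, f) * rng.lognormal(0.0, amplitude_sigma)
    updates["n_steps"] = max(6, profile.n_steps + int(rng.integers(-1, 2)))
    prof = replace(profile, **updates)
    return replace(prof, peak_ap_velocity_mps=_solve_peak_velocity(
        prof, prof._nominal_durations()))


def simulate_cohort(n_pd: int, n_hc: int, effect_scale: float,
                    condition: str, trials_per_subject: int,
                    seed: int) -> list[CohortRecord]:
    """Simulate a two-group cohort with per-subject parameter jitter.

    Deterministic for fixed arguments: all randomness flows from ``seed``.
    """
    if n_pd < 1 or n_hc < 1 or trials_per_subject < 1:
        raise ValidationError("cohort counts must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[CohortRecord] = []
    for group, count in (("PD", n_pd), ("HC", n_hc)):
        base = make_group_profile(group, effect_scale, condition)
        for i in range(count):
            sid = f"{group}{i + 1:02d}"
            prof = _jitter_profile(base, rng)
            for k in range(trials_per_subject):
                trial_seed = int(rng.integers(0, 2**31))
                trial, truth = simulate_trial(
                    prof, condition, trial_seed,
                    subject_id=sid, trial_id=f"{condition}{k + 1}")
                records.append(CohortRecord(sid, group, trial, truth))
    return records
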