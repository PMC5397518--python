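"""Sensor-frame signals -> anatomically aligned, gravity-free kinematics.

The reconstruction uses the protocol's guaranteed quiet-standing phases
before and after the walk:

1. gravity alignment -- the mean accelerometer vector over a static standing
   window defines "up"; the minimal rotation mapping it onto the VT axis is
   applied to all six channels, then gravity (9.81 m/s^2) is subtracted from
   the VT channel;
2. trapezoidal integration of AP acceleration to velocity;
3. zero-velocity update -- the straight line through the mean velocities of
   the pre- and post-walk standing windows is subtracted, absorbing
   integration drift and any constant accelerometer bias;
4. integration of corrected velocity to AP displacement, zeroed at trial
   start.

Orientation is assumed constant over the walk (no gyroscope-updated attitude
tracking): over a 5-m straight walk, trunk-orientation changes are small and
their residual effect on AP velocity is absorbed by the linear detrend.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .config import KinematicsConfig
from .errors import NotStaticError, ValidationError
from .synthetic import ImuTrial

__all__ = ["KinematicTrace", "align_to_anatomical", "integrate_ap",
           "reconstruct_trial"]


@dataclass
class KinematicTrace:
    """Gravity-free anatomical-frame signals with AP velocity/displacement.

    Axes: VT up, ML lateral, AP forward.  Accelerations m/s^2, angular
    velocities deg/s, velocity m/s, displacement m.
    """

    time_s: np.ndarray
    acc_vt: np.ndarray
    acc_ml: np.ndarray
    acc_ap: np.ndarray
    gyr_vt: np.ndarray
    gyr_ml: np.ndarray
    gyr_ap: np.ndarray
    vel_ap: np.ndarray
    disp_ap: np.ndarray
    acoustic_time_s: float
    condition: str
    subject_id: str = "S00"
    trial_id: str = "T0"


def _window_mask(time_s: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    a, b = window
    if b <= a:
        raise ValidationError(f"window {window} has non-positive length")
    if a < time_s[0] - 1e-9 or b > time_s[-1] + 1e-9:
        raise ValidationError(f"window {window} not fully inside the trial")
    mask = (time_s >= a) & (time_s <= b)
    if mask.sum() < 2:
        raise ValidationError(f"window {window} contains < 2 samples")
    return mask


def _require_static(gyr: np.ndarray, mask: np.ndarray, limit_dps: float,
                    what: str) -> None:
    rms = float(np.sqrt(np.mean(np.sum(gyr[mask] ** 2, axis=1))))
    if rms > limit_dps:
        raise NotStaticError(
            f"subject not static in {what} window "
            f"(gyro RMS {rms:.1f} deg/s > {limit_dps:.1f} deg/s)")


def _rotation_to_vertical(g_mean: np.ndarray) -> np.ndarray:
    """Minimal rotation taking the measured gravity direction onto VT.

    Rodrigues' formula about the axis g x e_vt; yaw about the vertical is
    unobservable from gravity and left untouched.
    """
    g_unit = g_mean / np.linalg.norm(g_mean)
    target = np.array([1.0, 0.0, 0.0])  # (VT, ML, AP)
    v = np.cross(g_unit, target)
    s2 = float(np.dot(v, v))
    c = float(np.dot(g_unit, target))
    if s2 < 1e-24:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    k = np.array([[0, -v[2], v[1]],
                  [v[2], 0, -v[0]],
                  [-v[1], v[0], 0]])
    return np.eye(3) + k + (k @ k) * ((1 - c) / s2)


def align_to_anatomical(trial: ImuTrial,
                        standing_window_s: tuple[float, float],
                        config: KinematicsConfig | None = None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the 6-axis signal into the anatomical frame, remove gravity.

    The rotation maps the mean accelerometer vector over the standing window
    to (g, 0, 0); the same rotation is applied to accelerometer and
    gyroscope, then 9.81 m/s^2 is subtracted from the VT acceleration.

    Returns ``(acc, gyr)`` as (n, 3) arrays in (VT, ML, AP) order.
    """
    cfg = config or KinematicsConfig()
    trial.validate()
    mask = _window_mask(trial.time_s, standing_window_s)
    if standing_window_s[1] - standing_window_s[0] < 1.0:
        raise ValidationError("standing window must span >= 1 s")
    _require_static(trial.gyr, mask, cfg.static_gyro_rms_max_dps, "standing")
    g_mean = trial.acc[mask].mean(axis=0)
    rot = _rotation_to_vertical(g_mean)
    acc = trial.acc @ rot.T
    gyr = trial.gyr @ rot.T
    acc[:, 0] -= cfg.gravity_mps2
    return acc, gyr


def integrate_ap(time_s: np.ndarray, acc_ap: np.ndarray,
                 pre_window_s: tuple[float, float],
                 post_window_s: tuple[float, float],
                 gyr: np.ndarray | None = None,
                 config: KinematicsConfig | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Drift-corrected AP velocity and displacement.

    Cumulative trapezoidal integration of AP acceleration, followed by
    subtraction of the straight line through the mean raw velocities of the
    two standing anchor windows (a two-point zero-velocity update).  A
    constant accelerometer bias produces a linear velocity ramp and is
    removed exactly.  Displacement is the integral of corrected velocity,
    zeroed at trial start.
    """
    cfg = config or KinematicsConfig()
    pre = _window_mask(time_s, pre_window_s)
    post = _window_mask(time_s, post_window_s)
    if gyr is not None:
        _require_static(gyr, pre, cfg.static_gyro_rms_max_dps, "pre-walk")
        _require_static(gyr, post, cfg.static_gyro_rms_max_dps, "post-walk")
    v_raw = cumulative_trapezoid(acc_ap, time_s, initial=0.0)
    t1, m1 = float(time_s[pre].mean()), float(v_raw[pre].mean())
    t2, m2 = float(time_s[post].mean()), float(v_raw[post].mean())
    slope = (m2 - m1) / (t2 - t1)
    vel = v_raw - (m1 + slope * (time_s - t1))
    disp = cumulative_trapezoid(vel, time_s, initial=0.0)
    return vel, disp


def reconstruct_trial(trial: ImuTrial,
                      config: KinematicsConfig | None = None) -> KinematicTrace:
    """Full reconstruction of one trial using the default anchor windows.

    Pre-walk window: [acoustic - 2 s, acoustic - 0.5 s]; post-walk window:
    the final 1.5 s of the trial.  Both must be static.
    """
    cfg = config or KinematicsConfig()
    a, b = cfg.pre_window_rel_acoustic_s
    pre = (trial.acoustic_time_s + a, trial.acoustic_time_s + b)
    post = (float(trial.time_s[-1]) - cfg.post_window_s, float(trial.time_s[-1]))
    acc, gyr = align_to_anatomical(trial, pre, cfg)
    vel, disp = integrate_ap(trial.time_s, acc[:, 2], pre, post, gyr, cfg)
    return KinematicTrace(
        time_s=trial.time_s,
        acc_vt=acc[:, 0], acc_ml=acc[:, 1], acc_ap=acc[:, 2],
        gyr_vt=gyr[:, 0], gyr_ml=gyr[:, 1], gyr_ap=gyr[:, 2],
        vel_ap=vel, disp_ap=disp,
        acoustic_time_s=trial.acoustic_time_s,
        condition=trial.condition,
        subject_id=trial.subject_id, trial_id=trial.trial_id,
    )
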