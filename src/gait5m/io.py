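"""File formats: trial CSV + JSON sidecar, cohort manifest, reports.

A trial is a CSV with header ``time_s,acc_vt,acc_ml,acc_ap,gyr_vt,gyr_ml,
gyr_ap`` (sensor frame; m/s^2 and deg/s; '.' decimal, UTF-8) plus a JSON
sidecar ``<stem>.json`` carrying the acoustic-signal time, condition,
identifiers, optional unit declarations and optional ground-truth events.
A cohort manifest is a CSV with columns ``subject_id,group,condition,
trial_path``.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SAMPLING_RATE_HZ
from .errors import ValidationError
from .kinematics import KinematicTrace
from .synthetic import CohortRecord, GroundTruthEvents, ImuTrial

__all__ = ["write_trial", "read_trial", "read_ground_truth",
           "write_cohort", "read_manifest", "write_trace"]

TRIAL_COLUMNS = ["time_s", "acc_vt", "acc_ml", "acc_ap",
                 "gyr_vt", "gyr_ml", "gyr_ap"]
_DT = 1.0 / SAMPLING_RATE_HZ


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trial(trial: ImuTrial, path: str | Path,
                truth: GroundTruthEvents | None = None) -> Path:
    """Write one trial as CSV plus JSON sidecar (lossless round-trip)."""
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack((trial.time_s, trial.acc, trial.gyr)),
        columns=TRIAL_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")
    meta: dict = {
        "acoustic_time_s": trial.acoustic_time_s,
        "condition": trial.condition,
        "subject_id": trial.subject_id,
        "trial_id": trial.trial_id,
        "acc_units": "m/s^2",
        "gyr_units": "deg/s",
    }
    if truth is not None:
        d = dataclasses.asdict(truth)
        meta["ground_truth"] = {
            k: (list(np.asarray(v)) if isinstance(v, np.ndarray) else v)
            for k, v in d.items()}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_trial(path: str | Path) -> ImuTrial:
    """Read a trial CSV + sidecar; validates schema, units and sampling.

    Angular velocities declared in rad/s are converted to deg/s on read.
    Non-uniform timestamps (any gap above 1.5 sample periods) are rejected
    with the location of the first gap.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != TRIAL_COLUMNS:
        raise ValidationError(
            f"{path}: expected columns {TRIAL_COLUMNS}, got {list(df.columns)}")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # header is line 1
        raise ValidationError(f"{path}: malformed row at line {bad}")
    t = df["time_s"].to_numpy()
    gaps = np.diff(t)
    bad = np.flatnonzero(gaps > 1.5 * _DT)
    if len(bad):
        raise ValidationError(
            f"{path}: sampling gap of {gaps[bad[0]]:.4f} s after "
            f"t = {t[bad[0]]:.3f} s (line {bad[0] + 2})")
    if np.any(np.abs(gaps - _DT) > 1e-5):  # 100 +/- 0.001 samples/s
        raise ValidationError(f"{path}: sampling is not uniform at 100/s")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValidationError(f"{path}: missing sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    gyr = df[["gyr_vt", "gyr_ml", "gyr_ap"]].to_numpy()
    if meta.get("gyr_units", "deg/s") == "rad/s":
        gyr = np.rad2deg(gyr)
    elif meta.get("gyr_units", "deg/s") != "deg/s":
        raise ValidationError(
            f"{path}: unknown gyr_units {meta.get('gyr_units')!r}")
    trial = ImuTrial(
        time_s=t,
        acc=df[["acc_vt", "acc_ml", "acc_ap"]].to_numpy(),
        gyr=gyr,
        acoustic_time_s=float(meta["acoustic_time_s"]),
        condition=str(meta["condition"]),
        subject_id=str(meta.get("subject_id", "S00")),
        trial_id=str(meta.get("trial_id", "T0")),
    )
    trial.validate()
    return trial


def read_ground_truth(path: str | Path) -> GroundTruthEvents | None:
    meta = json.loads(_sidecar_path(Path(path)).read_text())
    gt = meta.get("ground_truth")
    if gt is None:
        return None
    return GroundTruthEvents(
        acoustic_time_s=gt["acoustic_time_s"],
        movement_onset_s=gt["movement_onset_s"],
        heel_strike_times_s=np.asarray(gt["heel_strike_times_s"]),
        movement_end_s=gt["movement_end_s"],
        true_step_durations_s=np.asarray(gt["true_step_durations_s"]),
        true_displacement_m=gt["true_displacement_m"],
    )


def write_cohort(records: list[CohortRecord], out_dir: str | Path) -> Path:
    """Write all cohort trials and a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        name = f"{rec.subject_id}_{rec.trial.trial_id}.csv"
        write_trial(rec.trial, out_dir / name, rec.truth)
        rows.append({"subject_id": rec.subject_id, "group": rec.group,
                     "condition": rec.trial.condition, "trial_path": name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "group", "condition", "trial_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: manifest missing {sorted(missing)}")
    if len(df) == 0:
        raise ValidationError(f"{path}: manifest is empty")
    df["trial_path"] = [str((path.parent / p)) if not Path(p).is_absolute()
                        else p for p in df["trial_path"]]
    return df


def write_trace(trace: KinematicTrace, path: str | Path) -> Path:
    path = Path(path)
    cols = {c: getattr(trace, c) for c in
            ("time_s", "acc_vt", "acc_ml", "acc_ap",
             "gyr_vt", "gyr_ml", "gyr_ap", "vel_ap", "disp_ap")}
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
    return path
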