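"""End-to-end orchestration: manifest -> features -> statistics -> reports.

Per trial: kinematic reconstruction -> segmentation -> feature extraction.
Self-selected-speed trials are averaged per subject before statistics (the
fast trial is single).  Per condition: group comparisons over the full
parameter inventory, predictor preselection, forward stepwise discriminant
analysis and stratified 10-fold cross-validation.  Per-trial failures are
recorded in an exclusions table and never silently imputed.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as gio
from . import stats as gstats
from .config import PipelineConfig
from .errors import Gait5mError, ValidationError
from .features import inventory_keys, trial_features
from .kinematics import reconstruct_trial
from .segmentation import segment_trial

__all__ = ["PipelineResult", "run_pipeline", "extract_features",
           "analyze_condition", "write_report"]

log = logging.getLogger("gait5m")


@dataclass
class ConditionAnalysis:
    condition: str
    comparisons: pd.DataFrame
    predictors: list[str]
    model: gstats.DiscriminantModel | None
    error: str | None = None


@dataclass
class PipelineResult:
    features: pd.DataFrame            # one row per trial
    subject_features: pd.DataFrame    # SS trials averaged per subject
    exclusions: pd.DataFrame
    analyses: dict[str, ConditionAnalysis] = field(default_factory=dict)
    config_hash: str = ""
    seed: int = 0


def extract_features(manifest: pd.DataFrame, config: PipelineConfig,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial feature rows and the exclusions table."""
    rows, excluded = [], []
    for _, rec in manifest.iterrows():
        try:
            trial = gio.read_trial(rec["trial_path"])
            trace = reconstruct_trial(trial, config.kinematics)
            seg = segment_trial(trace, config.segmentation)
            fs = trial_features(trace, seg)
            row = fs.as_row()
            row["subject_id"] = rec["subject_id"]
            row["group"] = rec["group"]
            row["condition"] = rec["condition"]
            rows.append(row)
            log.debug("extracted %s %s: %d steps", rec["subject_id"],
                      rec.get("trial_path"), seg.n_steps)
        except (Gait5mError, OSError) as exc:
            excluded.append({"subject_id": rec["subject_id"],
                             "trial_path": rec["trial_path"],
                             "reason": str(exc)})
            log.warning("excluded %s: %s", rec["trial_path"], exc)
    features = pd.DataFrame(rows)
    exclusions = pd.DataFrame(excluded,
                              columns=["subject_id", "trial_path", "reason"])
    return features, exclusions


def average_per_subject(features: pd.DataFrame) -> pd.DataFrame:
    """Average repeated trials of a subject within each condition."""
    keys = [k for k in inventory_keys() if k in features.columns]
    grouped = (features
               .groupby(["subject_id", "group", "condition"], as_index=False)
               [keys].mean())
    return grouped


def analyze_condition(subject_features: pd.DataFrame, condition: str,
                      config: PipelineConfig) -> ConditionAnalysis:
    sub = subject_features[subject_features["condition"] == condition]
    sc = config.stats
    try:
        comparisons = gstats.compare_table(sub, keys=list(inventory_keys()),
                                           alpha=sc.alpha, welch=sc.welch)
    except Gait5mError as exc:
        log.warning("condition %s comparisons: %s", condition, exc)
        return ConditionAnalysis(condition, pd.DataFrame(), [], None,
                                 error=str(exc))
    try:
        predictors = gstats.preselect_predictors(
            comparisons, sub, alpha=sc.alpha, corr_cutoff=sc.corr_cutoff)
        model = gstats.stepwise_lda(sub, sub["group"], predictors,
                                    p_enter=sc.p_enter, p_remove=sc.p_remove)
    except Gait5mError as exc:
        log.warning("condition %s: %s", condition, exc)
        return ConditionAnalysis(condition, comparisons, [], None,
                                 error=str(exc))
    error = None
    try:
        model.cv = gstats.cross_validate_lda(
            sub, sub["group"], predictors, folds=sc.folds, seed=config.seed,
            p_enter=sc.p_enter, p_remove=sc.p_remove)
    except Gait5mError as exc:  # keep the fitted model, flag the CV
        log.warning("condition %s cross-validation: %s", condition, exc)
        error = f"cross-validation skipped: {exc}"
    return ConditionAnalysis(condition, comparisons, predictors, model,
                             error=error)


def run_pipeline(manifest_path: str | Path, config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis on a cohort manifest."""
    config = config or PipelineConfig()
    config.validate()
    manifest = gio.read_manifest(manifest_path)
    log.info("pipeline start: %d trials, config %s", len(manifest),
             config.hash())
    features, exclusions = extract_features(manifest, config)
    if features.empty:
        raise ValidationError("no trial could be analyzed")
    subject_features = average_per_subject(features)
    result = PipelineResult(features=features,
                            subject_features=subject_features,
                            exclusions=exclusions,
                            config_hash=config.hash(), seed=config.seed)
    for condition in sorted(subject_features["condition"].unique()):
        result.analyses[condition] = analyze_condition(
            subject_features, condition, config)
        log.info("analyzed condition %s", condition)
    if out_dir is not None:
        write_report(result, out_dir, config)
    return result


def write_report(result: PipelineResult, out_dir: str | Path,
                 config: PipelineConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / "features.csv", index=False,
                           float_format="%.10g")
    result.subject_features.to_csv(out / "subject_features.csv", index=False,
                                   float_format="%.10g")
    result.exclusions.to_csv(out / "exclusions.csv", index=False)
    for cond, analysis in result.analyses.items():
        analysis.comparisons.to_csv(out / f"comparisons_{cond}.csv",
                                    float_format="%.10g")
        model = analysis.model.to_dict() if analysis.model else None
        blob = {"condition": cond,
                "preselected_predictors": analysis.predictors,
                "model": model,
                "error": analysis.error,
                "config_hash": result.config_hash,
                "seed": result.seed}
        (out / f"model_{cond}.json").write_text(json.dumps(blob, indent=1))
    (out / "run.json").write_text(json.dumps(
        {"config": config.to_dict(), "config_hash": result.config_hash,
         "n_trials_in": len(result.features) + len(result.exclusions),
         "n_trials_analyzed": len(result.features),
         "n_excluded": len(result.exclusions)}, indent=1))
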