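"""Group comparison and discriminant classification.

Protocol, per kinematic parameter: normality of each group is tested with
Shapiro-Wilk for platykurtic samples (negative excess kurtosis) and
Shapiro-Francia for leptokurtic samples; if both groups look normal an
unpaired Student's t-test is used, otherwise the Wilcoxon rank-sum test.
Percentage differences are expressed relative to the healthy-control mean.
For discriminating parameters, the best single threshold is found by
exhaustive scan, scored by the harmonic mean of sensitivity and specificity
(F1).  Predictors are pre-selected (significant, normal in both groups,
pairwise |Pearson r| <= 0.7 after greedy pruning) and fed to a forward
stepwise two-group linear discriminant analysis driven by Wilks' Lambda,
with Bartlett's chi-square significance, resubstitution classification, and
stratified 10-fold cross-validation in which the whole stepwise selection is
re-run inside every training fold.

PD is the positive class throughout: sensitivity is the fraction of PD
subjects recognized, specificity the fraction of controls.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .errors import StatsError, ValidationError

__all__ = [
    "NormalityResult", "GroupComparison", "DiscriminantModel", "CvMetrics",
    "shapiro_francia", "route_normality_test", "compare_parameter",
    "compare_table", "best_threshold_f1", "preselect_predictors",
    "stepwise_lda", "cross_validate_lda", "stride_agreement",
    "pooled_stride_agreement",
]


# ----------------------------------------------------------------------
# normality

@dataclass(frozen=True)
class NormalityResult:
    test: str  # "shapiro_wilk" | "shapiro_francia"
    statistic: float
    p_value: float
    excess_kurtosis: float


def shapiro_francia(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Francia W' test of normality.

    W' is the squared correlation between the order statistics and Blom
    normal scores; the p-value uses Royston's (1993) log-normal
    approximation for ln(1 - W'), valid for 5 <= n <= 5000.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 5:
        raise StatsError("Shapiro-Francia needs n >= 5")
    m = sps.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    num = float(m @ x) ** 2
    den = float(m @ m) * float(np.sum((x - x.mean()) ** 2))
    if den == 0:
        return 1.0, 1.0
    w = num / den
    u, v = np.log(n), np.log(np.log(n))
    mu = -1.2725 + 1.0521 * (v - u)
    sigma = 1.0308 - 0.26758 * (v + 2.0 / u)
    z = (np.log(max(1.0 - w, 1e-300)) - mu) / sigma
    return float(w), float(sps.norm.sf(z))


def route_normality_test(values: np.ndarray) -> NormalityResult:
    """Kurtosis-routed normality test.

    Platykurtic samples (sample excess kurtosis < 0) go to Shapiro-Wilk,
    leptokurtic samples (>= 0) to Shapiro-Francia.  Samples of n = 4 (below
    the Shapiro-Francia validity range) always use Shapiro-Wilk.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise StatsError("normality testing needs n >= 4")
    if np.ptp(x) == 0:
        return NormalityResult("shapiro_wilk", 1.0, 1.0, 0.0)
    kurt = float(sps.kurtosis(x, fisher=True, bias=False))
    if kurt < 0 or len(x) < 5:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = sps.shapiro(x)
        return NormalityResult("shapiro_wilk", float(stat), float(p), kurt)
    stat, p = shapiro_francia(x)
    return NormalityResult("shapiro_francia", stat, p, kurt)


# ----------------------------------------------------------------------
# single-parameter comparison

@dataclass
class GroupComparison:
    key: str
    normal_pd: bool
    normal_hc: bool
    test_used: str  # "t_test" | "wilcoxon"
    p_value: float
    pct_difference: float
    threshold: float = float("nan")
    direction: str = ""
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    f1: float = float("nan")


def compare_parameter(pd_values: np.ndarray, hc_values: np.ndarray,
                      key: str = "", alpha: float = 0.05,
                      welch: bool = False) -> GroupComparison:
    """Two-group comparison of one parameter with test routing.

    Also scans for the best single-threshold classifier of the parameter
    (threshold, direction, sensitivity, specificity, F1).
    """
    x = np.asarray(pd_values, dtype=float)
    y = np.asarray(hc_values, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 4 or len(y) < 4:
        raise StatsError(f"{key or 'parameter'}: both groups need n >= 4")

    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        warnings.warn(f"{key or 'parameter'}: degenerate constant samples")
        return GroupComparison(key, True, True, "t_test", 1.0, 0.0)

    norm_pd = route_normality_test(x)
    norm_hc = route_normality_test(y)
    both_normal = norm_pd.p_value >= alpha and norm_hc.p_value >= alpha
    if both_normal:
        stat, p = sps.ttest_ind(x, y, equal_var=not welch)
        test = "t_test"
    else:
        stat, p = sps.ranksums(x, y)
        test = "wilcoxon"

    mean_hc = float(np.mean(y))
    pct = 100.0 * (float(np.mean(x)) - mean_hc) / mean_hc \
        if mean_hc != 0 else float("nan")

    cmp_ = GroupComparison(
        key=key, normal_pd=norm_pd.p_value >= alpha,
        normal_hc=norm_hc.p_value >= alpha, test_used=test,
        p_value=float(p), pct_difference=pct)
    try:
        thr, direction, sens, spec, f1 = best_threshold_f1(
            np.concatenate((x, y)),
            np.concatenate((np.ones(len(x), bool), np.zeros(len(y), bool))))
        cmp_.threshold, cmp_.direction = thr, direction
        cmp_.sensitivity, cmp_.specificity, cmp_.f1 = sens, spec, f1
    except StatsError:
        pass
    return cmp_


def compare_table(features: pd.DataFrame, group_col: str = "group",
                  keys: list[str] | None = None, alpha: float = 0.05,
                  welch: bool = False) -> pd.DataFrame:
    """Run :func:`compare_parameter` over every parameter column."""
    if group_col not in features:
        raise ValidationError(f"missing column {group_col!r}")
    groups = set(features[group_col])
    if groups != {"PD", "HC"}:
        raise ValidationError(f"expected groups PD and HC, got {groups}")
    keys = keys or [c for c in features.columns
                    if c not in (group_col, "subject_id", "trial_id",
                                 "condition")]
    pd_rows = features[features[group_col] == "PD"]
    hc_rows = features[features[group_col] == "HC"]
    out = []
    for key in keys:
        c = compare_parameter(pd_rows[key].to_numpy(),
                              hc_rows[key].to_numpy(),
                              key=key, alpha=alpha, welch=welch)
        out.append(vars(c))
    return pd.DataFrame(out).set_index("key")


# ----------------------------------------------------------------------
# threshold classification

def _confusion_at(values, labels, thr, greater_is_pd):
    pred = values > thr if greater_is_pd else values < thr
    tp = int(np.sum(pred & labels))
    tn = int(np.sum(~pred & ~labels))
    sens = tp / int(labels.sum())
    spec = tn / int((~labels).sum())
    f1 = 2 * sens * spec / (sens + spec) if sens + spec > 0 else 0.0
    return sens, spec, f1


def best_threshold_f1(values: np.ndarray, labels: np.ndarray,
                      ) -> tuple[float, str, float, float, float]:
    """Best single-threshold classifier by F1 (harmonic mean of sens/spec).

    Scans midpoints of consecutive sorted unique values in both directions.
    Ties break toward higher sensitivity, then lower threshold.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise StatsError("both classes must be present")
    uniq = np.unique(v)
    if len(uniq) < 2:
        raise StatsError("cannot place a threshold in a constant parameter")
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    best = None
    for greater in (True, False):
        direction = "greater_is_pd" if greater else "lesser_is_pd"
        for thr in mids:
            sens, spec, f1 = _confusion_at(v, y, thr, greater)
            cand = (f1, sens, -thr)
            if best is None or cand > best[0]:
                best = (cand, (float(thr), direction, sens, spec, f1))
    return best[1]


# ----------------------------------------------------------------------
# predictor preselection

def preselect_predictors(comparisons: pd.DataFrame, features: pd.DataFrame,
                         alpha: float = 0.05,
                         corr_cutoff: float = 0.7) -> list[str]:
    """Significant, normally distributed, decorrelated predictor keys.

    Keeps keys with p < alpha that pass normality in both groups, then
    greedily prunes correlated pairs (largest |Pearson r| first, iterated;
    the higher-p member of each offending pair is dropped).  Deterministic.
    """
    ok = comparisons[(comparisons["p_value"] < alpha)
                     & comparisons["normal_pd"] & comparisons["normal_hc"]]
    survivors = [k for k in ok.index if k in features.columns]
    if not survivors:
        raise StatsError("no eligible predictors after preselection")
    while len(survivors) > 1:
        corr = features[survivors].corr(method="pearson").abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(int(np.nanargmax(corr)), corr.shape)
        if not corr[i, j] > corr_cutoff:
            break
        a, b = survivors[i], survivors[j]
        drop = a if comparisons.loc[a, "p_value"] >= \
            comparisons.loc[b, "p_value"] else b
        survivors.remove(drop)
    return survivors


# ----------------------------------------------------------------------
# stepwise discriminant analysis

@dataclass
class CvMetrics:
    folds: int
    seed: int
    accuracy: float
    sensitivity: float
    specificity: float
    confusion: dict[str, int] = field(default_factory=dict)


@dataclass
class DiscriminantModel:
    predictors: list[str]
    coefficients: list[float]
    intercept: float
    wilks_lambda: float
    chi_square: float
    df: int
    p_value: float
    accuracy: float
    sensitivity: float
    specificity: float
    confusion: dict[str, int]
    lambda_path: list[float]
    cv: CvMetrics | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in vars(self).items() if k != "cv"}
        d["cv"] = vars(self.cv) if self.cv is not None else None
        return d


def _wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """Wilks' Lambda = det(W) / det(T) for the two-group design."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for g in (0, 1):
        Xg = X[y == g]
        Xgc = Xg - Xg.mean(axis=0)
        W += Xgc.T @ Xgc
    det_t = float(np.linalg.det(T))
    det_w = float(np.linalg.det(W))
    if det_t <= 0:
        return 1.0  # degenerate (constant/collinear) set: no separation info
    return max(min(det_w / det_t, 1.0), 1e-300)


def _partial_f(lam_without: float, lam_with: float, n: int, p_with: int,
               ) -> tuple[float, float]:
    """F statistic (and p) for the variable distinguishing the two subsets.

    ``p_with`` is the size of the larger subset; two groups assumed.
    """
    df2 = n - 2 - (p_with - 1)
    if df2 < 1 or lam_with <= 0:
        return 0.0, 1.0
    f = df2 * (lam_without / lam_with - 1.0)
    f = max(f, 0.0)
    return f, float(sps.f.sf(f, 1, df2))


def _stepwise_select(X: pd.DataFrame, y: np.ndarray, candidates: list[str],
                     p_enter: float, p_remove: float,
                     ) -> tuple[list[str], list[float]]:
    n = len(y)
    selected: list[str] = []
    lam_cur = 1.0
    path: list[float] = []
    seen: set[tuple[str, ...]] = set()
    for _ in range(2 * len(candidates) + 4):
        changed = False
        # entry: candidate with the largest F-to-enter
        best = None
        for c in candidates:
            if c in selected:
                continue
            lam_new = _wilks_lambda(X[selected + [c]].to_numpy(), y)
            f, p = _partial_f(lam_cur, lam_new, n, len(selected) + 1)
            if best is None or f > best[0]:
                best = (f, p, c, lam_new)
        entered = None
        if best is not None and best[1] <= p_enter:
            selected.append(best[2])
            lam_cur = best[3]
            path.append(lam_cur)
            entered = best[2]
            changed = True
        # removal: entered variable with the weakest F-to-remove
        if len(selected) > 1:
            worst = None
            for v in selected:
                if v == entered:
                    continue
                rest = [s for s in selected if s != v]
                lam_rest = _wilks_lambda(X[rest].to_numpy(), y)
                f, p = _partial_f(lam_rest, lam_cur, n, len(selected))
                if worst is None or p > worst[1]:
                    worst = (f, p, v, lam_rest)
            if worst is not None and worst[1] >= p_remove:
                selected.remove(worst[2])
                lam_cur = _wilks_lambda(X[selected].to_numpy(), y) \
                    if selected else 1.0
                changed = True
        state = tuple(sorted(selected))
        if not changed or state in seen:
            break
        seen.add(state)
    return selected, path


def _fit_lda(X: np.ndarray, y: np.ndarray) -> LinearDiscriminantAnalysis:
    lda = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
    lda.fit(X, y)
    return lda


def _classification_metrics(y_true: np.ndarray, y_pred: np.ndarray):
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    acc = (tp + tn) / len(y_true)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return acc, sens, spec, {"tp": tp, "tn": tn, "fp": fp, "fn": fn}


def _encode_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        return (y == "PD").astype(int)
    return y.astype(int)


def stepwise_lda(features: pd.DataFrame, labels, candidates: list[str],
                 p_enter: float = 0.05, p_remove: float = 0.10,
                 ) -> DiscriminantModel:
    """Forward stepwise linear discriminant analysis (two groups).

    At each step the candidate with the largest F-to-enter joins if its
    p <= ``p_enter``; entered variables whose F-to-remove p >= ``p_remove``
    are dropped; iteration stops at a fixed point.  The selected set is fit
    with a pooled-covariance, equal-prior linear discriminant.  Significance
    is Bartlett's chi-square, -(n - (k + g)/2 - 1) ln(Lambda) on k(g-1) df.
    """
    y = _encode_labels(labels)
    if not candidates:
        raise StatsError("no candidate predictors")
    n = len(y)
    if min(int((y == 0).sum()), int((y == 1).sum())) < 5:
        raise StatsError("need >= 5 subjects per group")
    selected, path = _stepwise_select(features, y, list(candidates),
                                      p_enter, p_remove)
    if not selected:
        raise StatsError("no candidate passed the entry criterion")
    lam = _wilks_lambda(features[selected].to_numpy(), y)
    k, g = len(selected), 2
    chi2 = -(n - (k + g) / 2.0 - 1.0) * np.log(lam)
    df = k * (g - 1)
    p = float(sps.chi2.sf(chi2, df))
    lda = _fit_lda(features[selected].to_numpy(), y)
    pred = lda.predict(features[selected].to_numpy())
    acc, sens, spec, conf = _classification_metrics(y, pred)
    return DiscriminantModel(
        predictors=selected,
        coefficients=[float(c) for c in lda.coef_.ravel()],
        intercept=float(lda.intercept_[0]),
        wilks_lambda=float(lam), chi_square=float(chi2), df=df, p_value=p,
        accuracy=acc, sensitivity=sens, specificity=spec, confusion=conf,
        lambda_path=[float(v) for v in path],
    )


def cross_validate_lda(features: pd.DataFrame, labels, candidates: list[str],
                       folds: int = 10, seed: int = 0,
                       p_enter: float = 0.05, p_remove: float = 0.10,
                       ) -> CvMetrics:
    """Stratified k-fold CV with per-fold re-run of the stepwise selection.

    Folds in which no candidate enters fall back to predicting the training
    majority class.  Fold-wise confusion counts are pooled.
    """
    y = _encode_labels(labels)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise StatsError(
            f"class of {counts.min()} subjects is too small for "
            f"{folds}-fold stratification")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    for train, test in skf.split(np.zeros(len(y)), y):
        Xtr = features.iloc[train]
        ytr = y[train]
        selected, _ = _stepwise_select(Xtr, ytr, list(candidates),
                                       p_enter, p_remove)
        if selected:
            lda = _fit_lda(Xtr[selected].to_numpy(), ytr)
            y_pred[test] = lda.predict(features.iloc[test][selected]
                                       .to_numpy())
        else:
            y_pred[test] = int(np.argmax(np.bincount(ytr)))
    acc, sens, spec, conf = _classification_metrics(y, y_pred)
    return CvMetrics(folds=folds, seed=seed, accuracy=acc,
                     sensitivity=sens, specificity=spec, confusion=conf)


# ----------------------------------------------------------------------
# stride-duration agreement

def _match_events(detected: np.ndarray, reference: np.ndarray,
                  tol_s: float = 0.15) -> tuple[np.ndarray, np.ndarray]:
    det = np.asarray(detected, dtype=float)
    ref = np.asarray(reference, dtype=float)
    used = np.zeros(len(det), dtype=bool)
    pairs = []
    orphans = []
    for r in ref:
        free = np.flatnonzero(~used)
        if len(free) == 0:
            orphans.append(r)
            continue
        j = free[np.argmin(np.abs(det[free] - r))]
        if abs(det[j] - r) <= tol_s:
            used[j] = True
            pairs.append((det[j], r))
        else:
            orphans.append(r)
    unmatched_det = det[~used]
    if orphans or len(unmatched_det):
        raise StatsError(
            f"unmatched events beyond {tol_s * 1000:.0f} ms: "
            f"reference {orphans}, detected {list(unmatched_det)}")
    d, r = np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs])
    return d, r


def _icc_absolute(a: np.ndarray, b: np.ndarray) -> float:
    """ICC(2,1): two-way random, single measure, absolute agreement."""
    import pingouin as pg
    n = len(a)
    df = pd.DataFrame({
        "targets": np.tile(np.arange(n), 2),
        "raters": np.repeat(["detected", "reference"], n),
        "ratings": np.concatenate((a, b)),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        icc = pg.intraclass_corr(data=df, targets="targets", raters="raters",
                                 ratings="ratings").set_index("Type")
    for label in ("ICC(A,1)", "ICC2"):  # two-way random, single, absolute
        if label in icc.index:
            return float(icc.loc[label, "ICC"])
    raise StatsError("absolute-agreement single-measure ICC not available")


def stride_agreement(detected_events: np.ndarray, reference_events: np.ndarray,
                     tol_s: float = 0.15,
                     ) -> tuple[float, float, float]:
    """Agreement of stride durations between two event streams.

    Events are matched one-to-one within ``tol_s``; stride durations are
    spans of two consecutive steps (event i to event i+2).  Returns the mean
    absolute stride-duration difference in ms, the same as a percentage of
    the mean reference step duration, and the absolute-agreement ICC of the
    pooled stride-duration pairs.  A constant time offset between the
    streams cancels exactly.
    """
    det, ref = _match_events(detected_events, reference_events, tol_s)
    if len(det) < 3:
        raise StatsError("need >= 3 matched events for stride durations")
    sd_det = det[2:] - det[:-2]
    sd_ref = ref[2:] - ref[:-2]
    diff_ms = float(np.mean(np.abs(sd_det - sd_ref)) * 1000.0)
    mean_step = float(np.mean(np.diff(ref)))
    pct = diff_ms / (mean_step * 1000.0) * 100.0
    if np.allclose(sd_det, sd_ref):
        icc = 1.0
    else:
        icc = _icc_absolute(sd_det, sd_ref)
    return diff_ms, pct, icc


def pooled_stride_agreement(pairs: list[tuple[np.ndarray, np.ndarray]],
                            tol_s: float = 0.15) -> tuple[float, float, float]:
    """Trial-averaged stride agreement with a pooled ICC across trials."""
    diffs, pcts, all_det, all_ref = [], [], [], []
    for detected, reference in pairs:
        det, ref = _match_events(detected, reference, tol_s)
        if len(det) < 3:
            continue
        sd_det, sd_ref = det[2:] - det[:-2], ref[2:] - ref[:-2]
        diffs.append(float(np.mean(np.abs(sd_det - sd_ref)) * 1000.0))
        pcts.append(diffs[-1] / (float(np.mean(np.diff(ref))) * 1000.0) * 100)
        all_det.append(sd_det)
        all_ref.append(sd_ref)
    if not diffs:
        raise StatsError("no trial yielded stride durations")
    det = np.concatenate(all_det)
    ref = np.concatenate(all_ref)
    icc = 1.0 if np.allclose(det, ref) else _icc_absolute(det, ref)
    return float(np.mean(diffs)), float(np.mean(pcts)), icc
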