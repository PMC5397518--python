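"""Statistical-protocol contracts: routing, thresholds, stepwise LDA."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gait5m.errors import StatsError
from gait5m.stats import (best_threshold_f1, compare_parameter,
                          cross_validate_lda, preselect_predictors,
                          route_normality_test, shapiro_francia, stepwise_lda,
                          stride_agreement)

# Shapiro-Francia W' and p frozen from R nortest::sf.test on the same
# seeded samples (independent oracle)
_SF_ORACLE = {
    "normal_n20": (0.9424295103, 0.2286365593),
    "laplace_n30": (0.9600117830, 0.2644038549),
    "uniform_n15": (0.8911202624, 0.06542866837),
    "lognormal_n25": (0.9320159287, 0.0897297861),
}


def _sf_samples():
    rng = np.random.default_rng(42)
    return {
        "normal_n20": rng.normal(0, 1, 20),
        "laplace_n30": rng.laplace(0, 1, 30),
        "uniform_n15": rng.uniform(0, 1, 15),
        "lognormal_n25": rng.lognormal(0, 0.8, 25),
    }


class TestNormalityRouting:
    @pytest.mark.parametrize("name", sorted(_SF_ORACLE))
    def test_shapiro_francia_matches_r_reference(self, name):
        x = np.round(_sf_samples()[name], 10)
        w, p = shapiro_francia(x)
        w_ref, p_ref = _SF_ORACLE[name]
        assert w == pytest.approx(w_ref, abs=1e-8)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_platykurtic_routes_to_shapiro_wilk(self):
        rng = np.random.default_rng(0)
        res = route_normality_test(rng.uniform(0, 1, 100))
        assert res.test == "shapiro_wilk"
        assert res.excess_kurtosis < 0

    def test_leptokurtic_routes_to_shapiro_francia(self):
        rng = np.random.default_rng(0)
        res = route_normality_test(rng.laplace(0, 1, 100))
        assert res.test == "shapiro_francia"
        assert res.excess_kurtosis >= 0

    def test_type_i_on_normal_samples(self):
        """The routed test keeps roughly nominal size on normal data."""
        rng = np.random.default_rng(1)
        rej = sum(route_normality_test(rng.normal(0, 1, 200)).p_value < 0.05
                  for _ in range(400))
        assert rej / 400 <= 0.07

    def test_small_sample_rejected(self):
        with pytest.raises(StatsError):
            route_normality_test(np.array([1.0, 2.0, 3.0]))


class TestCompareParameter:
    def test_pct_difference_arithmetic(self):
        rng = np.random.default_rng(3)
        c = compare_parameter(rng.normal(6.0, 1e-6, 10),
                              rng.normal(5.0, 1e-6, 10))
        assert c.pct_difference == pytest.approx(20.0, abs=0.01)

    def test_identical_samples(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 12)
        c = compare_parameter(x, x)
        assert c.p_value > 0.9
        assert c.pct_difference == pytest.approx(0.0, abs=1e-9)

    def test_constant_samples_warn_p_one(self):
        with pytest.warns(UserWarning):
            c = compare_parameter(np.full(8, 2.0), np.full(8, 2.0))
        assert c.p_value == 1.0

    def test_type_i_quick(self):
        rng = np.random.default_rng(5)
        rej = sum(compare_parameter(rng.normal(0, 1, 24),
                                    rng.normal(0, 1, 14)).p_value < 0.05
                  for _ in range(400))
        assert 0.02 <= rej / 400 <= 0.09

    def test_nonnormal_group_routes_to_wilcoxon(self):
        rng = np.random.default_rng(6)
        c = compare_parameter(np.exp(rng.normal(0, 1.5, 40)),
                              rng.normal(0, 1, 40))
        assert c.test_used == "wilcoxon"


def brute_force_threshold(values, labels):
    """Independent exhaustive scan over every (threshold, direction) pair."""
    uniq = np.sort(np.unique(values))
    best = None
    for direction in ("greater_is_pd", "lesser_is_pd"):
        for thr in 0.5 * (uniq[:-1] + uniq[1:]):
            pred = values > thr if direction == "greater_is_pd" \
                else values < thr
            sens = np.sum(pred & labels) / labels.sum()
            spec = np.sum(~pred & ~labels) / (~labels).sum()
            f1 = 2 * sens * spec / (sens + spec) if sens + spec else 0.0
            cand = (f1, sens, -thr)
            if best is None or cand > best[0]:
                best = (cand, (thr, direction, sens, spec, f1))
    return best[1]


class TestBestThreshold:
    def test_perfect_separation(self):
        v = np.concatenate((np.arange(10) + 10.0, np.arange(10)))
        y = np.concatenate((np.ones(10, bool), np.zeros(10, bool)))
        thr, direction, sens, spec, f1 = best_threshold_f1(v, y)
        assert sens == spec == f1 == 1.0
        assert direction == "greater_is_pd"

    def test_harmonic_mean_value(self):
        # one split with sens 1.0, spec 0.5 -> F1 = 2/3
        v = np.array([3.0, 4.0, 5.0, 1.0, 2.0, 3.5, 4.5, 0.5])
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0], bool)
        _, _, sens, spec, f1 = best_threshold_f1(v, y)
        assert f1 == pytest.approx(2 * sens * spec / (sens + spec))

    def test_single_class_is_error(self):
        with pytest.raises(StatsError):
            best_threshold_f1(np.arange(5.0), np.ones(5, bool))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 30))
        v = np.round(rng.normal(0, 1, n), 3)
        y = rng.random(n) < 0.5
        if y.all() or not y.any() or len(np.unique(v)) < 2:
            return
        assert best_threshold_f1(v, y) == pytest.approx(
            brute_force_threshold(v, y))


class TestPreselection:
    def _comparisons(self, features, labels):
        rows = []
        for k in features.columns:
            c = compare_parameter(features[k][labels == 1],
                                  features[k][labels == 0], key=k)
            rows.append(vars(c))
        return pd.DataFrame(rows).set_index("key")

    def test_duplicated_column_keeps_lower_p(self):
        rng = np.random.default_rng(7)
        y = np.array([1] * 12 + [0] * 12)
        strong = rng.normal(0, 1, 24) + 1.5 * y
        weak = rng.normal(0, 1, 24) + 0.8 * y
        X = pd.DataFrame({"strong": strong, "twin": strong + 1e-9,
                          "weak": weak})
        comp = self._comparisons(X, y)
        kept = preselect_predictors(comp, X)
        assert "weak" in kept or len(kept) >= 1
        assert not {"strong", "twin"} <= set(kept)
        # of the duplicated pair, the smaller p survives
        survivor = ({"strong", "twin"} & set(kept)).pop()
        other = ({"strong", "twin"} - {survivor}).pop()
        assert comp.loc[survivor, "p_value"] <= comp.loc[other, "p_value"]

    def test_nothing_significant_is_error(self):
        rng = np.random.default_rng(8)
        y = np.array([1] * 10 + [0] * 10)
        X = pd.DataFrame({f"k{i}": rng.normal(0, 1, 20) for i in range(5)})
        comp = self._comparisons(X, y)
        comp["p_value"] = 0.5
        with pytest.raises(StatsError):
            preselect_predictors(comp, X)

    def test_survivors_mostly_informative(self):
        """Planted informative features survive; noise features survive only
        at roughly the chance-significance rate."""
        rng = np.random.default_rng(9)
        n_noise_kept = n_info_kept = 0
        for _ in range(40):
            y = np.array([1] * 19 + [0] * 19)
            X = pd.DataFrame(
                {f"noise{i}": rng.normal(0, 1, 38) for i in range(17)})
            for i in range(3):
                X[f"info{i}"] = rng.normal(0, 1, 38) + 1.2 * y
            comp = self._comparisons(X, y)
            try:
                kept = preselect_predictors(comp, X)
            except StatsError:
                continue
            n_info_kept += sum(k.startswith("info") for k in kept)
            n_noise_kept += sum(k.startswith("noise") for k in kept)
        assert n_info_kept / (40 * 3) > 0.8
        assert n_noise_kept / (40 * 17) < 0.12


class TestStepwiseLda:
    def test_separable_single_predictor(self):
        rng = np.random.default_rng(15)
        y = np.array([1] * 10 + [0] * 10)
        X = pd.DataFrame({"sep": y * 10.0 + rng.normal(0, 0.5, 20),
                          "noise": rng.normal(0, 1, 20)})
        m = stepwise_lda(X, y, ["sep", "noise"])
        assert m.predictors == ["sep"]
        assert m.accuracy == 1.0
        assert m.wilks_lambda < 0.5

    def test_lambda_path_monotone(self):
        rng = np.random.default_rng(10)
        y = np.array([1] * 20 + [0] * 20)
        X = pd.DataFrame(rng.normal(0, 1, (40, 6)),
                         columns=[f"k{i}" for i in range(6)])
        X["k0"] += 2.0 * y
        X["k1"] -= 1.0 * y
        m = stepwise_lda(X, y, list(X.columns))
        assert all(b <= a + 1e-12 for a, b in zip(m.lambda_path,
                                                  m.lambda_path[1:]))
        assert 0 < m.wilks_lambda <= 1

    def test_bartlett_statistic_definition(self):
        rng = np.random.default_rng(11)
        y = np.array([1] * 15 + [0] * 15)
        X = pd.DataFrame({"a": rng.normal(0, 1, 30) + 1.5 * y,
                          "b": rng.normal(0, 1, 30) - 1.2 * y})
        m = stepwise_lda(X, y, ["a", "b"])
        n, k = 30, len(m.predictors)
        expected = -(n - (k + 2) / 2 - 1) * np.log(m.wilks_lambda)
        assert m.chi_square == pytest.approx(expected)
        assert m.df == k

    def test_pure_noise_often_yields_no_model(self):
        produced = 0
        for s in range(40):
            rng = np.random.default_rng(100 + s)
            y = np.array([1] * 24 + [0] * 14)
            X = pd.DataFrame(rng.normal(0, 1, (38, 10)),
                             columns=[f"k{i}" for i in range(10)])
            try:
                stepwise_lda(X, y, list(X.columns))
                produced += 1
            except StatsError:
                pass
        # P(any of 10 null candidates enters) ~ 1 - 0.95^10 ~ 0.40
        assert 0.15 <= produced / 40 <= 0.70


class TestCrossValidation:
    def test_deterministic(self):
        rng = np.random.default_rng(12)
        y = np.array([1] * 20 + [0] * 20)
        X = pd.DataFrame(rng.normal(0, 1, (40, 5)),
                         columns=[f"k{i}" for i in range(5)])
        X["k0"] += 1.5 * y
        a = cross_validate_lda(X, y, list(X.columns), folds=10, seed=3)
        b = cross_validate_lda(X, y, list(X.columns), folds=10, seed=3)
        assert vars(a) == vars(b)

    def test_separable_signal_high_accuracy(self):
        rng = np.random.default_rng(13)
        y = np.array([1] * 19 + [0] * 19)
        X = pd.DataFrame(rng.normal(0, 1, (38, 6)),
                         columns=[f"k{i}" for i in range(6)])
        X["k0"] += 4.0 * y
        cv = cross_validate_lda(X, y, list(X.columns), folds=10, seed=1)
        assert cv.accuracy >= 0.9

    def test_cv_below_resubstitution_on_average(self):
        res_accs, cv_accs = [], []
        for s in range(8):
            rng = np.random.default_rng(200 + s)
            y = np.array([1] * 19 + [0] * 19)
            X = pd.DataFrame(rng.normal(0, 1, (38, 8)),
                             columns=[f"k{i}" for i in range(8)])
            X["k0"] += 1.2 * y
            try:
                res_accs.append(stepwise_lda(X, y, list(X.columns)).accuracy)
                cv_accs.append(cross_validate_lda(X, y, list(X.columns),
                                                  folds=10, seed=s).accuracy)
            except StatsError:
                continue
        assert np.mean(cv_accs) <= np.mean(res_accs)

    def test_tiny_class_rejected(self):
        y = np.array([1] * 20 + [0] * 3)
        X = pd.DataFrame({"k": np.random.default_rng(0).normal(0, 1, 23)})
        with pytest.raises(StatsError):
            cross_validate_lda(X, y, ["k"], folds=10, seed=0)


class TestStrideAgreement:
    def test_identical_streams(self):
        ev = np.array([1.0, 1.55, 2.12, 2.66, 3.2, 3.74])
        d, pct, icc = stride_agreement(ev, ev)
        assert d == 0.0 and pct == 0.0 and icc == 1.0

    def test_constant_offset_cancels(self):
        ev = np.array([1.0, 1.55, 2.12, 2.66, 3.2, 3.74])
        d, pct, icc = stride_agreement(ev + 0.02, ev)
        assert d == pytest.approx(0.0, abs=1e-9)
        assert icc == 1.0

    def test_orphan_event_is_error(self):
        ref = np.array([1.0, 1.5, 2.0, 2.5])
        det = np.array([1.0, 1.5, 2.0, 2.5, 4.0])
        with pytest.raises(StatsError):
            stride_agreement(det, ref)

    def test_jittered_events_small_error(self):
        """Small detection jitter on variable step durations: stride error a
        few ms, a small fraction of step time, high agreement."""
        rng = np.random.default_rng(14)
        ref = 1.0 + np.cumsum(rng.normal(0.55, 0.06, 10))
        det = ref + rng.normal(0, 0.01, 10)
        d, pct, icc = stride_agreement(det, ref)
        assert d < 40.0
        assert pct < 8.0
        assert icc > 0.8
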