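"""Detector contracts: analytic crossings, template matching, phases."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gait5m as g
from gait5m.errors import NoMovementError, SegmentationError, ValidationError
from gait5m.segmentation import (build_template, construct_phases,
                                 detect_first_heel_strike, detect_start_end,
                                 match_steps, provisional_events)


def triangle(peak_t=1.0, end_t=2.0, fs=100.0):
    """Unit triangular velocity 0 -> 1 -> 0 over [0, end_t]."""
    t = np.arange(0.0, end_t + 1e-9, 1.0 / fs)
    v = np.where(t <= peak_t, t / peak_t, (end_t - t) / (end_t - peak_t))
    return t, v


class TestStartEnd:
    def test_triangular_crossings_ss(self):
        t, v = triangle()
        ts, te = detect_start_end(t, v, "SS")
        assert ts == pytest.approx(0.30, abs=0.011)
        assert te == pytest.approx(1.80, abs=0.011)

    def test_triangular_crossings_fs(self):
        t, v = triangle()
        ts, te = detect_start_end(t, v, "FS")
        assert ts == pytest.approx(0.30, abs=0.011)
        assert te == pytest.approx(1.85, abs=0.011)

    def test_zero_velocity_is_error(self):
        t = np.arange(0, 2, 0.01)
        with pytest.raises(NoMovementError):
            detect_start_end(t, np.zeros_like(t), "SS")

    def test_unknown_condition_rejected(self):
        t, v = triangle()
        with pytest.raises(ValidationError):
            detect_start_end(t, v, "XX")


class TestFirstHeelStrike:
    def test_sinusoid_crest(self):
        """A 1 Hz sinusoid passes the 3.5 Hz filter unchanged; the first
        crest after t_start is returned."""
        t = np.arange(0, 5, 0.01)
        x = np.sin(2 * np.pi * (t - 1.0))  # crests at 1.25, 2.25, ...
        assert detect_first_heel_strike(t, x, 0.5) == pytest.approx(
            1.25, abs=0.011)
        assert detect_first_heel_strike(t, x, 1.5) == pytest.approx(
            2.25, abs=0.011)

    def test_monotone_signal_is_error(self):
        t = np.arange(0, 3, 0.01)
        with pytest.raises(SegmentationError):
            detect_first_heel_strike(t, t.copy(), 0.5)

    def test_matches_ground_truth(self, clean_trial, clean_trace):
        _, truth = clean_trial
        ts, _ = detect_start_end(clean_trace.time_s, clean_trace.vel_ap, "SS")
        hs = detect_first_heel_strike(clean_trace.time_s, clean_trace.acc_vt,
                                      ts)
        assert hs == pytest.approx(truth.heel_strike_times_s[0], abs=0.040)


class TestTemplate:
    def test_periodic_signal_average(self):
        """Averaging identical periods reproduces one normalized period."""
        period = np.sin(2 * np.pi * np.arange(50) / 50) \
            + 0.3 * np.cos(4 * np.pi * np.arange(50) / 50)
        x = np.tile(period, 6)
        t = np.arange(len(x)) * 0.01
        events = t[::50][:6]
        tpl = build_template(t, x, events)
        ref = period - period.mean()
        trend = np.arange(50) - 24.5
        ref = ref - (trend @ ref) / (trend @ trend) * trend
        ref /= np.linalg.norm(ref)
        assert tpl.waveform == pytest.approx(ref, abs=1e-6)
        assert tpl.length_s == pytest.approx(0.50)

    def test_median_length_rule(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 6, 0.01)
        x = rng.normal(size=len(t))
        events = np.array([0.5, 1.0, 1.62, 2.1, 2.77])  # lengths 50,62,48,67
        tpl = build_template(t, x, events)
        assert len(tpl.waveform) == 56  # median of 50,62,48,67
        tpl.validate()

    def test_too_few_events_is_error(self):
        t = np.arange(0, 3, 0.01)
        with pytest.raises(SegmentationError):
            build_template(t, np.sin(t), np.array([0.5, 1.5]))


class TestMatchSteps:
    def test_exact_periodic_repetition(self):
        period = np.sin(2 * np.pi * np.arange(60) / 60) \
            + 0.4 * np.sin(4 * np.pi * np.arange(60) / 60 + 1.0)
        k = 7
        x = np.concatenate((np.zeros(100), np.tile(period, k), np.zeros(100)))
        t = np.arange(len(x)) * 0.01
        events = 1.0 + 0.6 * np.arange(4)
        tpl = build_template(t, x, events)
        found = match_steps(t, x, tpl, 0.5, t[-1] - 0.5)
        expected = 1.0 + 0.6 * np.arange(k)
        assert len(found) == k
        assert found == pytest.approx(expected, abs=0.011)

    def test_white_noise_rejected_by_floor(self):
        """The correlation floor suppresses noise matches: across 100 seeded
        noise traces the majority yield no event at all and none yields a
        periodic step train (isolated chance peaks above the floor are
        expected for a normalized correlation on finite noise)."""
        period = np.cos(2 * np.pi * np.arange(55) / 55)
        tpl = build_template(np.arange(165) * 0.01, np.tile(period, 3),
                             np.array([0.0, 0.55, 1.10]))
        n_with_events = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=800)
            t = np.arange(len(x)) * 0.01
            try:
                ev = match_steps(t, x, tpl, 0.5, t[-1] - 0.5)
            except SegmentationError:
                continue
            n_with_events += 1
            assert len(ev) < 5, "noise must never yield a full step train"
        assert n_with_events < 50

    def test_ground_truth_recovery(self, clean_trial, clean_trace):
        _, truth = clean_trial
        seg = g.segment_trial(clean_trace)
        assert len(seg.step_events_s) == len(truth.heel_strike_times_s)
        assert np.max(np.abs(seg.step_events_s
                             - truth.heel_strike_times_s)) < 0.040


class TestPhases:
    def test_enumerated_indexing_example(self):
        events = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        seg = construct_phases(0.0, 0.8, 6.5, 1.0, events)
        assert seg.steps == [(1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 6.5)]
        assert seg.phases["second_step"] == (2, 3)
        assert seg.phases["third_step"] == (3, 4)
        assert seg.phases["middle_step"] == (3, 4)  # floor((6+1)/2) = 3
        assert seg.phases["prelast_step"] == (5, 6)
        assert seg.phases["last_step"] == (6, 6.5)

    def test_acoustic_phases(self):
        events = np.linspace(1.1, 5.1, 5)
        seg = construct_phases(0.0, 0.8, 5.6, 1.1, events)
        assert seg.phases["acoustic_to_start"] == (0.0, 0.8)
        assert seg.phases["acoustic_to_first_hs"] == (0.0, 1.1)
        assert seg.phases["full_walk"] == (0.8, 5.6)

    def test_too_few_events_is_error(self):
        with pytest.raises(SegmentationError):
            construct_phases(0.0, 0.8, 5.0, 1.0,
                             np.array([1.0, 2.0, 3.0, 4.0]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(m=st.integers(5, 15), t0=st.floats(0.5, 2.0))
    def test_phase_invariants_hold(self, m, t0):
        """For any event count the named steps are well defined, ordered,
        and inside the walk."""
        events = t0 + 0.55 * np.arange(m)
        t_end = float(events[-1]) + 0.3
        seg = construct_phases(0.0, t0 - 0.2, t_end, t0, events)
        seg.validate()
        assert seg.n_steps == m
        mid = seg.phases["middle_step"]
        assert seg.steps.index(mid) == (m + 1) // 2 - 1

    def test_full_segmentation_invariants(self, segmented):
        segmented.validate()
        assert segmented.t_start_s < segmented.t_first_hs_s
        assert segmented.n_steps >= 5


class TestProvisionalEvents:
    def test_surrogates_near_heel_strikes(self, clean_trial, clean_trace):
        _, truth = clean_trial
        ts, te = detect_start_end(clean_trace.time_s, clean_trace.vel_ap, "SS")
        prov = provisional_events(clean_trace.time_s, clean_trace.acc_vt,
                                  ts, te)
        assert len(prov) >= 3
        for p in prov:
            assert np.min(np.abs(truth.heel_strike_times_s - p)) < 0.05
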