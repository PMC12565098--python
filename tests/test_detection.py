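"""I-VT detector: velocity computation, thresholding, classification,
fixation complement, head turns, and oracle equivalence against the
generator's injection logs."""

import dataclasses

import numpy as np
import pytest

from crossgaze.detection import (DetectorConfig, angular_velocity,
                                 classify_saccade, detect_all,
                                 detect_fixations, detect_head_turns,
                                 detect_saccades)
from crossgaze.scenario import make_default_scenario
from crossgaze.synthetic import (BehaviourParams, GazeTrace, GroupBehaviour,
                                 Participant, TaskBehaviour, simulate_trace)

HZ = 120.0


def make_trace(az, el=None, t=None, valid=None, head_t=None, head_yaw=None):
    az = np.asarray(az, dtype=float)
    n = az.size
    t = np.arange(n) / HZ if t is None else np.asarray(t, float)
    el = np.zeros(n) if el is None else np.asarray(el, float)
    valid = np.ones(n, bool) if valid is None else np.asarray(valid, bool)
    if head_t is None:
        head_t = np.arange(int(n * 90 / HZ)) / 90.0
        head_yaw = np.zeros(head_t.size)
    return GazeTrace(participant_id="x", task="safe_crossing",
                     t_gaze=t, gaze_az=az, gaze_el=el, valid=valid,
                     t_head=head_t, head_yaw=head_yaw,
                     head_pitch=np.zeros(head_t.size))


def raised_cosine_saccade(amplitude, duration, n=240, onset_frac=0.4):
    """Sampled saccade with closed-form peak velocity 2*A/duration."""
    t = np.arange(n) / HZ
    on = onset_frac * n / HZ
    x = np.clip((t - on) / duration, 0.0, 1.0)
    az = amplitude * (x - np.sin(2 * np.pi * x) / (2 * np.pi))
    return make_trace(az)


class TestAngularVelocity:
    def test_constant_gaze_zero_velocity(self):
        _, v = angular_velocity(make_trace(np.full(100, 5.0)))
        assert np.nanmax(v) == pytest.approx(0.0, abs=1e-9)

    def test_azimuth_ramp_recovers_rate(self):
        az = 30.0 * np.arange(120) / HZ  # 30 deg/s planar rotation
        _, v = angular_velocity(make_trace(az))
        assert np.nanmedian(v) == pytest.approx(30.0, rel=1e-6)

    def test_raised_cosine_peak_within_5pct_of_closed_form(self):
        # duration long relative to the 2-sample central-difference support,
        # so the numerical peak approaches the analytic 2*A/dur
        A, dur = 10.0, 0.15
        _, v = angular_velocity(raised_cosine_saccade(A, dur))
        assert np.nanmax(v) == pytest.approx(2 * A / dur, rel=0.05)

    def test_too_short_trace_errors(self):
        with pytest.raises(ValueError, match="too short"):
            angular_velocity(make_trace([0.0, 1.0]))

    def test_invalid_samples_propagate_as_nan(self):
        valid = np.ones(100, bool)
        valid[50] = False
        _, v = angular_velocity(make_trace(np.zeros(100), valid=valid))
        assert np.isnan(v[49:52]).all()


class TestClassifySaccade:
    @pytest.mark.parametrize("amp, kind", [
        (1.19, "micro"), (1.20, "macro"), (0.0, "micro"), (15.0, "macro"),
    ])
    def test_boundary(self, amp, kind):
        assert classify_saccade(amp) == kind

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            classify_saccade(-0.1)


class TestDetectSaccades:
    def test_subthreshold_drift_yields_no_events(self):
        rng = np.random.default_rng(0)
        az = np.cumsum(rng.normal(0, 2.0 / HZ, 600))  # ~2 deg/s walk
        assert detect_saccades(make_trace(az)) == []

    def test_single_saccade_amplitude_recovered(self):
        events = detect_saccades(raised_cosine_saccade(5.0, 0.04))
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "macro"
        assert ev.amplitude == pytest.approx(5.0, abs=0.2)
        assert ev.peak_velocity > 50

    @pytest.mark.parametrize("ramp_rate", [30.0, 49.0, 51.0, 80.0])
    def test_detection_switches_exactly_at_the_velocity_threshold(self, ramp_rate):
        az = ramp_rate * np.arange(240) / HZ
        events = detect_saccades(make_trace(az))
        if ramp_rate > 50.0:
            assert len(events) == 1
        else:
            assert events == []

    def test_threshold_monotonicity(self):
        trace = self._busy_trace()
        counts = []
        for thr in (30.0, 50.0, 80.0, 150.0):
            cfg = DetectorConfig(velocity_threshold=thr)
            counts.append(len(detect_saccades(trace, cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_amplitude_boundary_monotonicity(self):
        trace = self._busy_trace()
        macro_counts, micro_counts = [], []
        for boundary in (0.5, 1.2, 3.0, 8.0):
            cfg = DetectorConfig(amplitude_boundary=boundary)
            ev = detect_saccades(trace, cfg)
            macro_counts.append(sum(e.kind == "macro" for e in ev))
            micro_counts.append(sum(e.kind == "micro" for e in ev))
        assert macro_counts == sorted(macro_counts, reverse=True)
        assert micro_counts == sorted(micro_counts)

    def test_time_reversal_preserves_events(self):
        trace = self._busy_trace()
        fwd = detect_saccades(trace)
        rev = make_trace(trace.gaze_az[::-1], el=trace.gaze_el[::-1],
                         valid=trace.valid[::-1])
        bwd = detect_saccades(rev)
        assert len(fwd) == len(bwd)
        assert np.allclose(sorted(e.amplitude for e in fwd),
                           sorted(e.amplitude for e in bwd), atol=1e-9)

    def test_event_overlapping_invalid_samples_discarded(self):
        trace = raised_cosine_saccade(5.0, 0.04)
        assert len(detect_saccades(trace)) == 1
        trace.valid[94:104] = False  # blanket the saccade with dropouts
        assert detect_saccades(trace) == []

    @staticmethod
    def _busy_trace():
        scenario = make_default_scenario()
        p = Participant(participant_id="x", group="control", age=50, moca=22,
                        va_decimal=1.0, vf_radius=85)
        params = BehaviourParams.default()
        trace, _ = simulate_trace(p, "safe_crossing", scenario, params, 11)
        return trace


class TestFixations:
    def test_no_macrosaccades_single_fixation(self):
        trace = make_trace(np.zeros(300))
        fix = detect_fixations(trace, [])
        assert len(fix) == 1
        assert fix[0].duration == pytest.approx(trace.duration)

    def test_k_macrosaccades_give_k_plus_one_fixations(self):
        scenario = make_default_scenario()
        p = Participant(participant_id="x", group="central", age=70, moca=20,
                        va_decimal=0.3, vf_radius=80)
        trace, _ = simulate_trace(p, "safe_crossing", scenario,
                                  BehaviourParams.default(), 5)
        saccades = detect_saccades(trace)
        macros = [s for s in saccades if s.kind == "macro"]
        fix = detect_fixations(trace, macros)
        assert len(fix) == len(macros) + 1

    def test_partition_of_trace_duration(self):
        scenario = make_default_scenario()
        p = Participant(participant_id="x", group="control", age=50, moca=22,
                        va_decimal=1.0, vf_radius=85)
        trace, _ = simulate_trace(p, "car_counting", scenario,
                                  BehaviourParams.default(), 13)
        macros = [s for s in detect_saccades(trace) if s.kind == "macro"]
        fix = detect_fixations(trace, macros)
        total = sum(f.duration for f in fix) + sum(s.duration for s in macros)
        assert total == pytest.approx(trace.duration, abs=1.0 / HZ)

    def test_unsorted_macrosaccades_rejected(self):
        trace = make_trace(np.zeros(300))
        ev = detect_saccades(raised_cosine_saccade(5.0, 0.04))[0]
        with pytest.raises(ValueError):
            detect_fixations(trace, [ev, ev])


class TestHeadTurns:
    def test_static_head_no_turns(self):
        t = np.arange(450) / 90.0
        assert detect_head_turns(t, np.zeros(450)) == []

    def test_single_ramp_amplitude_recovered(self):
        t = np.arange(450) / 90.0
        x = np.clip((t - 2.0) / 0.6, 0, 1)
        yaw = 30.0 * (x - np.sin(2 * np.pi * x) / (2 * np.pi))
        turns = detect_head_turns(t, yaw)
        assert len(turns) == 1
        assert turns[0].amplitude == pytest.approx(30.0, abs=1.0)
        assert turns[0].direction == "right"

    def test_small_excursions_below_min_amplitude_ignored(self):
        t = np.arange(450) / 90.0
        x = np.clip((t - 2.0) / 0.3, 0, 1)
        yaw = 4.0 * x  # 4 deg net, above velocity threshold but too small
        assert detect_head_turns(t, yaw) == []


@pytest.fixture(scope="module")
def clean_run():
    """Detector-oracle regime: events >= 80 ms apart, low tracker noise and
    drift, micro amplitudes well inside the detectable band, no dropouts."""
    tb = TaskBehaviour(
        macrosaccade_rate=2.0, macrosaccade_amplitude_median=10.0,
        microsaccade_rate=1.5, microsaccade_amplitude_median=0.96,
        microsaccade_amplitude_sigma=0.02,
        head_turn_rate=0.5, head_turn_amplitude_median=25.0,
        crossing_delay_median=1.8, crossing_delay_median_w2=1.8,
        gaze_noise_sd=0.1, drift_velocity_rms=1.5)
    params = BehaviourParams(groups={"control": GroupBehaviour(
        tasks={"safe_crossing": tb, "car_counting": tb})})
    scenario = make_default_scenario()
    p = Participant(participant_id="x", group="control", age=50, moca=22,
                    va_decimal=1.0, vf_radius=85)
    runs = []
    for seed in (3, 4, 5):
        trace, log = simulate_trace(p, "safe_crossing", scenario, params, seed)
        trace.valid[:] = True
        runs.append((trace, log, detect_all(trace)))
    return runs


class TestInjectionOracle:
    """Detector vs ground truth on clean generator traces."""

    def test_macrosaccade_count_exact(self, clean_run):
        for trace, log, (saccades, _, _) in clean_run:
            inj = len(log.of_kind("macrosaccade"))
            det = sum(1 for s in saccades if s.kind == "macro")
            assert det == inj

    def test_microsaccade_recall_at_least_95pct(self, clean_run):
        inj = det = 0
        for trace, log, (saccades, _, _) in clean_run:
            inj += len(log.of_kind("microsaccade"))
            det += sum(1 for s in saccades if s.kind == "micro")
        assert det >= 0.95 * inj

    def test_head_turn_count_within_one(self, clean_run):
        for trace, log, (_, _, turns) in clean_run:
            assert abs(len(turns) - len(log.of_kind("head_turn"))) <= 1

    def test_macro_amplitudes_match_injected(self, clean_run):
        for trace, log, (saccades, _, _) in clean_run:
            det = [s for s in saccades if s.kind == "macro"]
            for inj in log.of_kind("macrosaccade"):
                match = min(det, key=lambda s: abs(s.onset - inj.onset))
                assert abs(match.onset - inj.onset) < 0.05
                assert match.amplitude == pytest.approx(inj.amplitude, abs=0.6)

    def test_default_calibration_macro_count_within_5pct(self, scenario, params,
                                                         control_participant):
        trace, log = simulate_trace(control_participant, "safe_crossing",
                                    scenario, params, 21)
        det = sum(1 for s in detect_saccades(trace) if s.kind == "macro")
        inj = len(log.of_kind("macrosaccade"))
        assert det == pytest.approx(inj, rel=0.05)


def test_smoothing_window_validation():
    with pytest.raises(ValueError):
        DetectorConfig(smoothing_window=2)
    with pytest.raises(ValueError):
        DetectorConfig(velocity_threshold=0)
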