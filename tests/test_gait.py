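"""Event detection, cycle segmentation, turn exclusion and gait metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitdbs import gait
from gaitdbs.types import GaitCycle, GaitEvent, PHASES, Signal


def _events_from_truth(gt):
    ev = []
    for t in gt.lhs:
        ev.append(GaitEvent(t, "LHS"))
    for t in gt.rhs:
        ev.append(GaitEvent(t, "RHS"))
    for t in gt.rto:
        ev.append(GaitEvent(t, "RTO"))
    for t in gt.lto:
        ev.append(GaitEvent(t, "LTO"))
    return sorted(ev, key=lambda e: e.time_s)


class TestDetectEventsFsr:
    def test_recovers_ground_truth_events(self, trial):
        events, flags = gait.detect_events_fsr(trial.kinematics)
        assert not any(flags.values())
        rate = trial.kinematics["fsr_l_heel"].rate_hz
        gt = trial.ground_truth
        det_lhs = np.array([e.time_s for e in events if e.label == "LHS"])
        for t in gt.lhs:
            assert np.min(np.abs(det_lhs - t)) <= 1.0 / rate + 1e-9
        det_lto = np.array([e.time_s for e in events if e.label == "LTO"])
        for t in gt.lto[:-1]:
            assert np.min(np.abs(det_lto - t)) <= 1.0 / rate + 1e-9

    def test_flat_heel_channel_sets_quality_flag(self, trial):
        streams = dict(trial.kinematics)
        flat = streams["fsr_l_heel"]
        streams["fsr_l_heel"] = Signal(
            np.zeros(flat.n), flat.rate_hz, name="fsr_l_heel"
        )
        events, flags = gait.detect_events_fsr(streams)
        assert flags["l"] is True
        assert not any(e.label == "LHS" for e in events)

    def test_square_pulses_one_event_per_edge(self):
        rate = 100.0
        t = np.arange(int(10 * rate)) / rate
        x = ((t % 1.0) < 0.6).astype(float)
        n_pulses = 10
        streams = {
            "fsr_l_heel": Signal(x, rate),
            "fsr_l_met1": Signal(x, rate),
            "fsr_l_met5": Signal(x, rate),
            "fsr_l_toe": Signal(x, rate),
            "fsr_r_heel": Signal(np.zeros_like(x) + 1.0, rate),
            "fsr_r_met1": Signal(np.ones_like(x), rate),
            "fsr_r_met5": Signal(np.ones_like(x), rate),
            "fsr_r_toe": Signal(np.ones_like(x), rate),
        }
        events, flags = gait.detect_events_fsr(streams)
        lhs = [e for e in events if e.label == "LHS"]
        lto = [e for e in events if e.label == "LTO"]
        assert len(lhs) == n_pulses - 1 or len(lhs) == n_pulses
        assert len(lto) == n_pulses


class TestDetectEventsGoniometer:
    def test_recovers_events_within_20ms(self, trial):
        events, flags = gait.detect_events_goniometer(trial.kinematics)
        assert not any(flags.values())
        gt = trial.ground_truth
        det_lhs = np.array([e.time_s for e in events if e.label == "LHS"])
        hits = [np.min(np.abs(det_lhs - t)) for t in gt.lhs[1:-1]]
        assert np.median(hits) <= 0.020 + 1e-9
        det_lto = np.array([e.time_s for e in events if e.label == "LTO"])
        hits = [np.min(np.abs(det_lto - t)) for t in gt.lto[1:-2]]
        assert np.median(hits) <= 0.020 + 1e-9

    def test_constant_angle_flags_and_returns_empty(self):
        streams = {
            "ankle_angle_l": Signal(np.zeros(1000), 100.0),
            "ankle_angle_r": Signal(np.zeros(1000), 100.0),
        }
        events, flags = gait.detect_events_goniometer(streams)
        assert flags["l"] and flags["r"] and events == []

    def test_agrees_with_fsr_on_clean_trial(self, trial):
        ev_f, _ = gait.detect_events_fsr(trial.kinematics)
        ev_g, _ = gait.detect_events_goniometer(trial.kinematics)
        f_lhs = np.array([e.time_s for e in ev_f if e.label == "LHS"])
        g_lhs = np.array([e.time_s for e in ev_g if e.label == "LHS"])
        deltas = [np.min(np.abs(f_lhs - t)) for t in g_lhs]
        assert np.median(deltas) < 0.020


class TestBuildCycles:
    def test_single_cycle_definition(self):
        ev = [
            GaitEvent(0.00, "LHS"),
            GaitEvent(0.12, "RTO"),
            GaitEvent(0.62, "RHS"),
            GaitEvent(0.72, "LTO"),
            GaitEvent(1.10, "LHS"),
        ]
        cycles = gait.build_cycles(ev)
        assert len(cycles) == 1
        c = cycles[0]
        assert c.phase_interval("DS1") == (0.00, 0.12)
        assert c.phase_interval("CLS") == (0.12, 0.62)
        assert c.phase_interval("DS2") == (0.62, 0.72)
        assert c.phase_interval("ILS") == (0.72, 1.10)
        assert c.stride_time_s == pytest.approx(1.10)

    def test_missing_event_skips_only_that_cycle(self):
        ev = []
        t = 0.0
        for k in range(4):
            ev.append(GaitEvent(t, "LHS"))
            if k != 1:  # drop RTO of the second cycle
                ev.append(GaitEvent(t + 0.12, "RTO"))
            ev.append(GaitEvent(t + 0.60, "RHS"))
            ev.append(GaitEvent(t + 0.72, "LTO"))
            t += 1.1
        ev.append(GaitEvent(t, "LHS"))
        cycles = gait.build_cycles(ev)
        assert len(cycles) == 3
        assert not any(abs(c.lhs - 1.1) < 1e-9 for c in cycles)

    def test_phase_partition_on_detected_cycles(self, trial_gait):
        for c in trial_gait.cycles:
            d = c.phase_durations()
            assert sum(d.values()) == pytest.approx(c.stride_time_s, abs=1e-12)

    @given(
        lhs=st.floats(0, 10),
        d1=st.floats(0.01, 0.5),
        d2=st.floats(0.01, 0.5),
        d3=st.floats(0.01, 0.5),
        d4=st.floats(0.01, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_phase_partition_property(self, lhs, d1, d2, d3, d4):
        c = GaitCycle(lhs, lhs + d1, lhs + d1 + d2, lhs + d1 + d2 + d3,
                      lhs + d1 + d2 + d3 + d4)
        d = c.phase_durations()
        assert sum(d.values()) == pytest.approx(c.stride_time_s, abs=1e-9)
        # no overlap, no gap: phase ends meet the next phase's start
        ends = [c.phase_interval(p)[1] for p in PHASES]
        starts = [c.phase_interval(p)[0] for p in PHASES]
        assert starts[1:] == ends[:-1]


class TestExcludeTurns:
    def test_ground_truth_turns_flagged(self, trial, trial_gait):
        gt = trial.ground_truth
        turn_times = {gt.lhs[i] for i in gt.turn_cycle_indices}
        for c in trial_gait.cycles:
            truth = any(abs(c.lhs - t) < 0.05 for t in turn_times)
            assert c.is_turn == truth

    def test_straight_walk_has_no_flags(self):
        cycles = [GaitCycle(i * 1.1, i * 1.1 + 0.12, i * 1.1 + 0.6,
                            i * 1.1 + 0.72, (i + 1) * 1.1) for i in range(5)]
        heading = Signal(np.zeros(700), 100.0)
        kept = gait.exclude_turns(cycles, heading)
        assert len(kept) == 5 and not any(c.is_turn for c in cycles)

    def test_missing_heading_keeps_everything(self):
        cycles = [GaitCycle(0, 0.1, 0.6, 0.7, 1.1)]
        assert len(gait.exclude_turns(cycles, None)) == 1

    def test_alternating_turn_directions(self, trial):
        # turns alternate left/right; heading returns toward start
        h = trial.kinematics["heading_deg"].data
        assert h.max() > 170 and h.min() < 10

    def test_pure_filter_leaves_metrics_intact(self, trial, trial_gait):
        sm_all = gait.compute_stride_metrics(trial_gait.cycles, trial.kinematics)
        sm_kept = gait.compute_stride_metrics(
            trial_gait.walking_cycles, trial.kinematics
        )
        kept_by_time = {m.cycle.lhs: m for m in sm_all}
        for m in sm_kept:
            ref = kept_by_time[m.cycle.lhs]
            assert m.stride_velocity == ref.stride_velocity
            assert m.arm_swing_amplitude == ref.arm_swing_amplitude


class TestStrideMetrics:
    def _streams(self, n=500, rate=100.0):
        t = np.arange(n) / rate
        return t, {
            "pelvis_x": Signal(1.2 * t, rate),
            "pelvis_y": Signal(np.zeros(n), rate),
            "wrist_ap_l": Signal(0.2 * np.sin(2 * np.pi * t / 1.0), rate),
            "wrist_ap_r": Signal(-0.2 * np.sin(2 * np.pi * t / 1.0), rate),
        }

    def test_constant_velocity_pelvis(self):
        _, streams = self._streams()
        c = GaitCycle(1.0, 1.12, 1.5, 1.62, 2.0)
        (m,) = gait.compute_stride_metrics([c], streams)
        assert m.stride_velocity == pytest.approx(1.2, rel=1e-6)

    def test_sinusoidal_wrist_amplitude(self):
        _, streams = self._streams()
        c = GaitCycle(1.0, 1.12, 1.5, 1.62, 2.0)
        (m,) = gait.compute_stride_metrics([c], streams)
        assert m.arm_swing_amplitude == pytest.approx(0.4, abs=0.01)

    def test_generator_targets_recovered(self, trial, trial_gait):
        tm = trial_gait.trial_metrics
        tgt = trial.ground_truth.metric_targets
        assert tm.stride_velocity == pytest.approx(tgt["stride_velocity"], rel=0.10)
        assert tm.arm_swing_amplitude == pytest.approx(
            tgt["arm_swing_amplitude"], rel=0.10
        )
        assert tm.step_time_cv == pytest.approx(tgt["step_time_cv"], abs=0.03)
        assert tm.step_length_cv == pytest.approx(tgt["step_length_cv"], abs=0.04)


class TestAggregate:
    def _metric(self, step_times, step_lengths):
        c = GaitCycle(0, 0.12, 0.6, 0.72, 1.1)
        return gait.StrideMetrics(
            stride_index=0,
            cycle=c,
            stride_length=float(np.sum(step_lengths)),
            stride_velocity=1.0,
            step_times=np.asarray(step_times),
            step_lengths=np.asarray(step_lengths),
            arm_swing_amplitude=0.4,
        )

    def test_identical_strides_have_zero_cv(self):
        sm = [self._metric([0.5, 0.5], [0.6, 0.6]) for _ in range(6)]
        tm = gait.aggregate_trial_metrics(sm)
        assert tm.step_time_cv == pytest.approx(0.0, abs=1e-12)
        assert tm.step_length_cv == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_cv(self):
        # steps {0.5, 0.5, 0.6, 0.6}: mean 0.55, sample SD 0.057735
        sm = [
            self._metric([0.5, 0.5], [0.6, 0.6]),
            self._metric([0.6, 0.6], [0.6, 0.6]),
        ]
        tm = gait.aggregate_trial_metrics(sm, min_strides=2)
        assert tm.step_time_cv == pytest.approx(0.0577350269 / 0.55, rel=1e-6)

    def test_cv_scale_invariance(self):
        rng = np.random.default_rng(0)
        steps = rng.uniform(0.4, 0.8, size=(6, 2))
        sm1 = [self._metric([0.5, 0.5], s) for s in steps]
        sm2 = [self._metric([0.5, 0.5], 2 * s) for s in steps]
        a = gait.aggregate_trial_metrics(sm1)
        b = gait.aggregate_trial_metrics(sm2)
        assert a.step_length_cv == pytest.approx(b.step_length_cv, rel=1e-12)

    def test_below_minimum_marks_unusable(self):
        sm = [self._metric([0.5, 0.5], [0.6, 0.6])]
        tm = gait.aggregate_trial_metrics(sm, min_strides=5)
        assert not tm.usable


class TestStrideOrderConsistency:
    def _cycles(self, bout_lengths, stride_times):
        cycles, t, i = [], 0.0, 0
        for L in bout_lengths:
            for _ in range(L):
                st = stride_times[i]
                cycles.append(GaitCycle(t, t + 0.1 * st, t + 0.5 * st,
                                        t + 0.62 * st, t + st))
                t += st
                i += 1
            turn = GaitCycle(t, t + 0.11, t + 0.55, t + 0.68, t + 1.1)
            turn.is_turn = True
            cycles.append(turn)
            t += 1.1
        return cycles

    def test_single_bout_of_three_gives_no_test(self):
        res = gait.stride_order_consistency(self._cycles([3], [1.0, 1.1, 1.05]))
        assert res.p_value is None
        assert len(res.summary) == 3

    def test_type_i_error_controlled(self):
        rng = np.random.default_rng(1)
        rejections = 0
        n_seeds = 60
        for _ in range(n_seeds):
            times = 1.1 + 0.05 * rng.standard_normal(60)
            res = gait.stride_order_consistency(self._cycles([5] * 12, times))
            if res.p_value is not None and res.p_value < 0.05:
                rejections += 1
        assert rejections / n_seeds <= 0.12

    def test_detects_first_stride_slowing(self):
        rng = np.random.default_rng(2)
        detected = 0
        n_seeds = 30
        for _ in range(n_seeds):
            times = 1.1 + 0.05 * rng.standard_normal(100)
            times[::5] *= 1.30  # first stride of every 5-stride bout slowed
            res = gait.stride_order_consistency(self._cycles([5] * 20, times))
            if res.p_value is not None and res.p_value < 0.05:
                detected += 1
        assert detected / n_seeds >= 0.90
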