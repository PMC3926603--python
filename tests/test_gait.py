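"""Gait segmentation, event detection, steps, double support, summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_biomech_frame
from insolekit.biomechanics import BiomechSample
from insolekit.gait import (
    SW,
    ST1,
    ST2,
    DoubleSupportRecord,
    GaitEvent,
    classify_sample,
    detect_events,
    double_support,
    extract_steps,
    segment_stream,
    trial_summary,
)


def sample(vgrf, cop_y):
    nan = float("nan")
    if cop_y is None:
        return BiomechSample(t=0.0, vgrf=vgrf, cop_x=nan, cop_y=nan)
    return BiomechSample(t=0.0, vgrf=vgrf, cop_x=45.0, cop_y=cop_y)


class TestClassifySample:
    @pytest.mark.parametrize(
        "vgrf,cop_y,expected",
        [
            (0.0, None, SW),  # undefined CoP -> swing
            (-400.0, 200.0, ST1),  # loaded, CoP behind the 125 mm line
            (-400.0, 125.0, ST2),  # boundary: CoP_y <= 125 mm is ST2
            (-400.0, 60.0, ST2),
            (-20.0, 200.0, ST1),  # boundary: vGRF <= -20 N counts as loaded
        ],
    )
    def test_rule_table(self, vgrf, cop_y, expected):
        assert classify_sample(sample(vgrf, cop_y)) == expected

    def test_classification_total(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            vgrf = -rng.uniform(0, 800)
            cop_y = rng.uniform(0, 250) if rng.uniform() < 0.8 else None
            assert classify_sample(sample(vgrf, cop_y)) in (SW, ST1, ST2)


def random_biomech(rng, n=300):
    vgrf = -rng.uniform(0, 100, n)
    cop_y = rng.uniform(0, 250, n)
    undef = rng.uniform(size=n) < 0.3
    vgrf[undef] = 0.0
    cop_y[undef] = np.nan
    return make_biomech_frame(vgrf, cop_y)


class TestSegmentStream:
    def test_all_swing(self):
        df = make_biomech_frame(np.zeros(10), np.full(10, np.nan))
        assert (segment_stream(df)["phase"] == SW).all()

    def test_st1_to_st2_switch_at_crossing(self):
        # stance with CoP_y sweeping heel to toe: label flips where y <= 125
        n = 50
        cop_y = np.linspace(240, 20, n)
        df = make_biomech_frame(np.full(n, -400.0), cop_y)
        phases = segment_stream(df)["phase"].to_numpy()
        k = int(np.argmax(cop_y <= 125.0))
        assert (phases[:k] == ST1).all()
        assert (phases[k:] == ST2).all()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equivalence_with_naive_rule(self, seed):
        # oracle: per-sample application of the classification rule
        df = random_biomech(np.random.default_rng(seed))
        got = segment_stream(df)["phase"].tolist()
        want = [
            classify_sample(
                BiomechSample(t=r.time_s, vgrf=r.vgrf_N, cop_x=r.cop_x_mm, cop_y=r.cop_y_mm)
            )
            for r in df.itertuples()
        ]
        assert got == want

    def test_debounce_removes_short_runs(self):
        vgrf = np.full(40, -400.0)
        cop_y = np.full(40, 200.0)
        vgrf[20] = 0.0  # single-sample dropout
        cop_y[20] = np.nan
        df = make_biomech_frame(vgrf, cop_y)
        raw = segment_stream(df)["phase"].to_numpy()
        assert raw[20] == SW
        debounced = segment_stream(df, min_phase_s=0.03)["phase"].to_numpy()
        assert (debounced == ST1).all()


def phase_frame(labels, fs=100.0):
    return pd.DataFrame({"time_s": np.arange(len(labels)) / fs, "phase": labels})


class TestDetectEvents:
    def test_toy_stream(self):
        events = detect_events(phase_frame([SW, SW, ST1, ST1, ST2, SW]))
        assert [(e.kind, e.index) for e in events] == [("heel_strike", 2), ("toe_off", 5)]
        assert events[0].t == pytest.approx(0.02)

    def test_all_swing_no_events(self):
        assert detect_events(phase_frame([SW] * 10)) == []

    def test_stream_starting_mid_stance(self):
        events = detect_events(phase_frame([ST1, ST2, SW, SW, ST1, ST1, SW]))
        assert events[0].kind == "toe_off"
        # leading partial stance yields no step
        assert extract_steps(events, trim=0) == []

    def test_forefoot_first_contact_flagged_atypical(self):
        events = detect_events(phase_frame([SW, ST2, ST2, SW]))
        assert events[0].kind == "heel_strike" and events[0].atypical

    def test_alternation(self, short_result):
        for foot in (short_result.left, short_result.right):
            kinds = [e.kind for e in foot.events]
            for a, b in zip(kinds, kinds[1:]):
                assert a != b


def make_events(n_steps, stance=0.8, swing=0.45, t0=0.0):
    events = []
    for k in range(n_steps + 1):
        hs = t0 + k * (stance + swing)
        events.append(GaitEvent("heel_strike", hs, 0))
        if k < n_steps:
            events.append(GaitEvent("toe_off", hs + stance, 0))
    return events


class TestExtractSteps:
    def test_trim_arithmetic(self):
        steps = extract_steps(make_events(7), trim=2)
        assert len(steps) == 3

    def test_trim_zero_keeps_all(self):
        assert len(extract_steps(make_events(7), trim=0)) == 7

    def test_too_few_steps_empty_with_warning(self):
        with pytest.warns(UserWarning):
            assert extract_steps(make_events(4), trim=2) == []

    def test_step_durations_and_cadence(self):
        s = extract_steps(make_events(5, stance=0.80, swing=0.45), trim=0)[0]
        assert s.dt_stance == pytest.approx(0.80)
        assert s.dt_swing == pytest.approx(0.45)
        assert s.cadence_hz == pytest.approx(0.8)
        assert s.stance_pct == pytest.approx(64.0)
        assert s.stance_pct + s.swing_pct == pytest.approx(100.0)


class TestDoubleSupport:
    def test_interval_intersection(self):
        # left ST1 over [0, 0.20) s, right ST2 over [0.10, 0.25) s
        n = 30
        left = [ST1 if i < 20 else SW for i in range(n)]
        right = [ST2 if 10 <= i < 25 else SW for i in range(n)]
        recs = double_support(phase_frame(left), phase_frame(right))
        assert len(recs) == 1
        assert recs[0].kind == "DS_L"
        assert recs[0].dt == pytest.approx(0.10)
        assert recs[0].t_start == pytest.approx(0.10)

    def test_no_overlap_no_records(self):
        left = phase_frame([ST1] * 5 + [SW] * 5)
        right = phase_frame([SW] * 5 + [ST2] * 5)
        assert double_support(left, right) == []

    def test_left_right_swap_symmetry(self):
        rng = np.random.default_rng(9)
        labels = lambda: rng.choice([SW, ST1, ST2], size=100)
        l, r = phase_frame(labels()), phase_frame(labels())
        fwd = double_support(l, r)
        rev = double_support(r, l)
        flip = {"DS_L": "DS_R", "DS_R": "DS_L"}
        assert sorted((flip[x.kind], x.t_start, x.dt) for x in fwd) == sorted(
            (x.kind, x.t_start, x.dt) for x in rev
        )

    def test_misaligned_streams_rejected(self):
        with pytest.raises(ValueError):
            double_support(phase_frame([SW] * 5), phase_frame([SW] * 6))

    def test_ds_bounded_by_overlapping_stances(self, short_result):
        stance_max = max(
            s.dt_stance for s in short_result.left.steps + short_result.right.steps
        )
        for rec in short_result.ds_records:
            assert rec.dt <= stance_max + 1e-9


class TestTrialSummary:
    def test_identical_steps_zero_sd(self):
        steps = extract_steps(make_events(5), trim=0)
        out = trial_summary(steps, steps)
        assert out["left"]["dt_stance_s"]["sd"] == pytest.approx(0.0)

    def test_two_step_hand_arithmetic(self):
        e1 = extract_steps(make_events(1, stance=0.6, swing=0.6), trim=0)
        e2 = extract_steps(make_events(1, stance=0.8, swing=0.4, t0=10.0), trim=0)
        out = trial_summary(e1 + e2, [])
        assert out["left"]["dt_stance_s"]["mean"] == pytest.approx(0.7)
        assert out["left"]["dt_stance_s"]["sd"] == pytest.approx(0.1 * math.sqrt(2.0))

    def test_stance_swing_percent_complementary(self, short_result):
        for side in ("left", "right"):
            s = short_result.summary[side]
            assert s["stance_pct"]["mean"] + s["swing_pct"]["mean"] == pytest.approx(100.0)

    def test_empty_inputs_empty_summary(self):
        out = trial_summary([], [])
        assert out["left"].get("n_steps") is None
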