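"""Synthetic trial generator, stage segmentation and the oximetry pair."""

import numpy as np
import pytest
from scipy import stats as sps

from ergofatigue.kinematics import (
    ANGLE_CHANNELS,
    JointAngleTrace,
    SegmenterConfig,
    StageDurations,
    StageSegment,
    SynthTrialSpec,
    generate_oxi_pair,
    generate_trial,
    read_trace_csv,
    segment_stages,
    stage_durations,
    write_trace_csv,
)
from ergofatigue.oximetry import baseline_rso2, rso2_difference


def constant_trace(n=300, rate=60.0, **overrides):
    angles = {k: np.zeros(n) for k in ANGLE_CHANNELS}
    for k, v in overrides.items():
        angles[k] = np.full(n, float(v))
    return JointAngleTrace(
        times=np.arange(n) / rate,
        angles=angles,
        both_feet_on_ground=np.ones(n, bool),
        walking=np.zeros(n, bool),
    )


class TestGenerateTrial:
    def test_seeded_determinism(self):
        spec = SynthTrialSpec(seed=11, cycle_count=2)
        t1, s1 = generate_trial(spec)
        t2, s2 = generate_trial(spec)
        assert np.array_equal(t1.times, t2.times)
        for k in t1.angles:
            assert np.array_equal(t1.angles[k], t2.angles[k])
        assert s1 == s2

    def test_static_hold_and_carry_durations_honoured(self):
        spec = SynthTrialSpec(seed=2, cycle_count=3)
        _, gt = generate_trial(spec)
        statics = [s for s in gt if s.stage == "static"]
        carries = [s for s in gt if s.stage == "carrying"]
        assert len(statics) == len(carries) == 3
        tol = 1.0 / spec.sample_rate
        for s in statics:
            assert s.duration == pytest.approx(10.0, abs=tol)
        # 3 m at the default 1 m/s walking speed
        for c in carries:
            assert c.duration == pytest.approx(3.0, abs=tol)

    def test_lower_body_height_deepens_static_flexion(self):
        means = {}
        for h in (15, 45):
            spec = SynthTrialSpec(seed=4, body_height=h, cycle_count=2)
            trace, gt = generate_trial(spec)
            mask = np.zeros(len(trace), bool)
            for s in gt:
                if s.stage == "static":
                    mask |= (trace.times >= s.start) & (trace.times < s.end)
            means[h] = trace.angles["trunk_flexion"][mask].mean()
        assert means[15] > means[45]

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SynthTrialSpec(seed=0, cycle_count=0)
        with pytest.raises(ValueError):
            SynthTrialSpec(seed=0, sample_rate=0.0)

    def test_angles_bounded_and_finite(self):
        trace, _ = generate_trial(SynthTrialSpec(seed=9, cycle_count=2))
        for k, v in trace.angles.items():
            assert np.all(np.isfinite(v))
            assert np.all((v >= -90.0) & (v <= 180.0))


class TestSegmentStages:
    @pytest.mark.parametrize("seed,height,weight", [(0, 15, 8), (1, 45, 20), (2, 15, 14)])
    def test_recovers_ground_truth_boundaries(self, seed, height, weight):
        spec = SynthTrialSpec(
            seed=seed, body_height=height, seat_weight=weight, cycle_count=3
        )
        trace, gt = generate_trial(spec)
        segs = segment_stages(trace)
        assert [s.stage for s in segs] == [s.stage for s in gt]
        for g, s in zip(gt, segs):
            assert abs(g.start - s.start) <= 0.25
            assert abs(g.end - s.end) <= 0.25

    def test_segments_partition_the_trace(self):
        trace, _ = generate_trial(SynthTrialSpec(seed=7, cycle_count=3))
        segs = segment_stages(trace)
        assert segs[0].start == trace.times[0]
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start
        total = sum(s.duration for s in segs)
        assert total == pytest.approx(trace.duration, abs=1e-9)

    def test_constant_standing_posture_is_one_static_segment(self):
        segs = segment_stages(constant_trace())
        assert len(segs) == 1 and segs[0].stage == "static"

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            segment_stages([])

    def test_missing_flexion_channel_rejected(self):
        trace = constant_trace()
        del trace.angles["trunk_flexion"]
        with pytest.raises(KeyError, match="trunk_flexion"):
            segment_stages(trace)


class TestStageDurations:
    def test_direct_sums(self):
        segs = [
            StageSegment("lifting", 0, 5),
            StageSegment("carrying", 5, 8),
            StageSegment("static", 8, 18),
        ]
        d = stage_durations(segs)
        assert (d.lifting, d.carrying, d.static) == (5, 3, 10)
        assert d.total == 18

    def test_empty_list_is_zero(self):
        assert stage_durations([]).as_array().tolist() == [0, 0, 0]

    def test_two_equal_cycles_double_durations(self):
        one = [
            StageSegment("lifting", 0, 4),
            StageSegment("carrying", 4, 7),
            StageSegment("static", 7, 17),
        ]
        two = one + [
            StageSegment("lifting", 17, 21),
            StageSegment("carrying", 21, 24),
            StageSegment("static", 24, 34),
        ]
        assert np.array_equal(
            stage_durations(two).as_array(), 2 * stage_durations(one).as_array()
        )

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            StageDurations(lifting=-1.0)


class TestOxiPairGenerator:
    def test_null_fatigue_difference_inside_resting_band(self):
        pre, post = generate_oxi_pair(seed=3, fatigue_level=0.0)
        assert abs(rso2_difference(pre, post)) < 0.5

    def test_full_fatigue_recovers_slope(self):
        pre, post = generate_oxi_pair(seed=5, fatigue_level=1.0, slope=-15.0)
        assert rso2_difference(pre, post) == pytest.approx(-15.0, abs=0.5)

    def test_pre_trace_mean_stays_in_resting_band(self):
        for seed in range(10):
            pre, _ = generate_oxi_pair(seed=seed, fatigue_level=0.5, baseline=70.0)
            assert abs(pre.rso2.mean() - 70.0) <= 0.5

    def test_slope_recovered_by_regression_over_seeded_trials(self):
        slope = -15.0
        levels = np.linspace(0.0, 1.0, 50)
        diffs = [
            rso2_difference(*generate_oxi_pair(seed=100 + i, fatigue_level=lv, slope=slope))
            for i, lv in enumerate(levels)
        ]
        fit = sps.linregress(levels, diffs)
        ci = 1.96 * fit.stderr
        assert fit.slope - ci <= slope <= fit.slope + ci

    def test_invalid_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            generate_oxi_pair(seed=0, fatigue_level=0.5, baseline=0.0)


class TestTraceIO:
    def test_wide_csv_round_trip(self, tmp_path):
        trace, _ = generate_trial(SynthTrialSpec(seed=1, cycle_count=1))
        path = tmp_path / "trace.csv"
        write_trace_csv(trace, path)
        back = read_trace_csv(path)
        assert np.allclose(back.times, trace.times)
        for k in trace.angles:
            assert np.allclose(back.angles[k], trace.angles[k])
        assert np.array_equal(back.walking, trace.walking)

    def test_long_format_reader(self, tmp_path):
        import pandas as pd

        rows = []
        for t in (0.0, 0.1, 0.2):
            for ch in ANGLE_CHANNELS:
                rows.append({"time_s": t, "channel": ch, "value": 1.0})
        path = tmp_path / "long.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        trace = read_trace_csv(path)
        assert len(trace) == 3
        assert trace.angles["trunk_flexion"].tolist() == [1.0, 1.0, 1.0]
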