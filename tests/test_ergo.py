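"""NIOSH lifting equation, OWAS classification and RULA scoring."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_frame
from ergofatigue.ergo import (
    LiftTaskParams,
    RulaInputs,
    niosh_li,
    owas_action_category,
    owas_classify,
    owas_load_digit,
    rula_from_frame,
    rula_score,
    aggregate,
)


class TestNiosh:
    def test_reference_task_all_multipliers_unity(self):
        res = niosh_li(
            LiftTaskParams(load=23.0, horizontal=25, vertical=75, travel=25,
                           asymmetry=0, frequency=0.2)
        )
        assert all(v == 1.0 for v in res.multipliers.values())
        assert res.rwl == 23.0
        assert res.li == 1.0

    def test_li_linear_in_load(self):
        geo = dict(horizontal=25, vertical=75, travel=25)
        assert niosh_li(LiftTaskParams(load=11.5, **geo)).li == 0.5

    def test_hand_multiplied_table_cell(self):
        # multipliers transcribed independently from the published method:
        # H=40 -> 25/40; V=30 -> 1-0.003*45; D=60 -> 0.82+4.5/60;
        # A=30 -> 1-0.0032*30; F=3/min, <=1h, V<75 -> 0.88; fair, V<75 -> 0.95
        expected_rwl = 23.0 * (25 / 40) * (1 - 0.003 * 45) * (0.82 + 4.5 / 60) \
            * (1 - 0.0032 * 30) * 0.88 * 0.95
        res = niosh_li(
            LiftTaskParams(load=14.0, horizontal=40, vertical=30, travel=60,
                           asymmetry=30, frequency=3.0, coupling="fair")
        )
        assert res.rwl == pytest.approx(expected_rwl, rel=1e-12)
        assert res.li == pytest.approx(14.0 / expected_rwl, rel=1e-12)

    def test_out_of_reach_geometry_flags_maximal_risk(self):
        res = niosh_li(LiftTaskParams(load=10, horizontal=80, vertical=75, travel=25))
        assert res.rwl == 0.0 and res.li == float("inf")
        assert "HM" in res.note

    def test_invalid_horizontal_rejected(self):
        with pytest.raises(ValueError, match="horizontal"):
            LiftTaskParams(load=10, horizontal=0, vertical=75, travel=25)

    @settings(deadline=None, max_examples=200)
    @given(
        load=st.floats(0, 30),
        h=st.floats(10, 60),
        v=st.floats(0, 170),
        d=st.floats(0, 170),
        a=st.floats(0, 135),
        f=st.floats(0.1, 12),
        dur=st.sampled_from(["<=1h", "<=2h", "<=8h"]),
        cpl=st.sampled_from(["good", "fair", "poor"]),
    )
    def test_multipliers_bounded_and_rwl_capped(self, load, h, v, d, a, f, dur, cpl):
        res = niosh_li(
            LiftTaskParams(load=load, horizontal=h, vertical=v, travel=d,
                           asymmetry=a, frequency=f, work_duration_class=dur,
                           coupling=cpl)
        )
        for v_ in res.multipliers.values():
            assert 0.0 <= v_ <= 1.0
        assert 0.0 <= res.rwl <= 23.0
        if res.rwl > 0:
            assert res.li == pytest.approx(load / res.rwl)

    def test_li_monotone_in_load_and_geometry(self):
        geo = dict(vertical=75, travel=25, frequency=1.0)
        li = lambda load, h, a: niosh_li(
            LiftTaskParams(load=load, horizontal=h, asymmetry=a, **geo)
        ).li
        assert li(10, 30, 0) < li(12, 30, 0)  # strictly increasing in load
        assert li(10, 30, 0) <= li(10, 40, 0)  # non-decreasing in H
        assert li(10, 30, 0) <= li(10, 30, 45)  # non-decreasing in A


class TestOwas:
    def test_neutral_stance_light_load(self):
        code = owas_classify(make_frame(), load=8.0)
        assert (code.back, code.arms, code.legs, code.load_digit) == (1, 1, 2, 1)
        assert code.action_category == 1

    def test_load_digit_bands_for_protocol_weights(self):
        assert owas_load_digit(8) == 1
        assert owas_load_digit(14) == 2
        assert owas_load_digit(20) == 2
        assert owas_load_digit(20.5) == 3

    def test_category_defined_for_all_252_codes(self):
        cats = set()
        for back, arms, legs, load in itertools.product(
            range(1, 5), range(1, 4), range(1, 8), range(1, 4)
        ):
            cats.add(owas_action_category(back, arms, legs, load))
        assert cats == {1, 2, 3, 4}

    def test_bent_and_twisted_back_is_worst_back_digit(self):
        code = owas_classify(
            make_frame(trunk_flexion=50.0, trunk_twist=30.0), load=20.0
        )
        assert code.back == 4

    def test_walking_maps_to_legs_seven(self):
        code = owas_classify(
            make_frame(walking=True, both_feet=False, trunk_flexion=10.0), load=14.0
        )
        assert code.legs == 7

    def test_missing_channel_named_in_error(self):
        frame = make_frame()
        del frame.angles["trunk_twist"]
        with pytest.raises(KeyError, match="trunk_twist"):
            owas_classify(frame, load=8.0)


class TestRula:
    def test_minimal_posture_scores_one(self):
        assert rula_score(RulaInputs(1, 1, 1, 1, 1, 1, 1)).grand == 1

    def test_maximal_inputs_cap_at_seven(self):
        res = rula_score(
            RulaInputs(6, 3, 4, 2, 6, 6, 2, muscle_use_a=1, muscle_use_b=1,
                       force_load_a=3, force_load_b=3)
        )
        assert res.grand == 7

    def test_bent_trunk_static_assembly_in_observed_range(self):
        res = rula_score(
            RulaInputs(upper_arm=3, lower_arm=2, wrist=2, wrist_twist=1,
                       neck=2, trunk=4, legs=1, muscle_use_a=1, muscle_use_b=1,
                       force_load_a=3, force_load_b=3)
        )
        assert 3 <= res.grand <= 7

    def test_out_of_range_input_rejected(self):
        with pytest.raises(ValueError, match="upper_arm"):
            RulaInputs(7, 1, 1, 1, 1, 1, 1)

    def test_grand_bounded_over_full_posture_domain(self):
        grands = set()
        for ua, la, wr, tw, nk, tr, lg in itertools.product(
            range(1, 7), range(1, 4), range(1, 5), range(1, 3),
            range(1, 7), range(1, 7), range(1, 3)
        ):
            grands.add(rula_score(RulaInputs(ua, la, wr, tw, nk, tr, lg)).grand)
        assert grands <= set(range(1, 8))

    def test_neutral_frame_scores_minimum(self):
        frame = make_frame(lower_arm_flexion_left=80.0, lower_arm_flexion_right=80.0)
        res = rula_from_frame(frame, load=0.0, static_posture=False)
        assert res.grand == 1

    def test_grand_monotone_in_trunk_flexion(self):
        grands = []
        for flex in np.arange(10.0, 71.0, 5.0):
            frame = make_frame(
                trunk_flexion=flex,
                lower_arm_flexion_left=80.0,
                lower_arm_flexion_right=80.0,
            )
            grands.append(rula_from_frame(frame, load=0.0, static_posture=False).grand)
        assert all(b >= a for a, b in zip(grands, grands[1:]))
        assert grands[-1] > grands[0]

    def test_missing_neck_channel_rejected(self):
        frame = make_frame()
        del frame.angles["neck_flexion"]
        with pytest.raises(KeyError, match="neck_flexion"):
            rula_from_frame(frame)


class TestAggregate:
    def test_max_mean_mode(self):
        vals = [3, 3, 4, 5]
        assert aggregate(vals, "max") == 5
        assert aggregate(vals, "mean") == pytest.approx(3.75)
        assert aggregate(vals, "mode") == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])


def test_synthetic_task_sweep_spans_observed_li_range():
    """Across plausible task geometries the LI covers at least [0.42, 2.51]."""
    lis = []
    for load in (8, 14, 20):
        for h in (25, 40, 55):
            for v in (15, 75):
                for freq, asym, cpl in ((1.0, 0, "good"), (3.0, 30, "fair")):
                    res = niosh_li(
                        LiftTaskParams(load=load, horizontal=h, vertical=v,
                                       travel=60, asymmetry=asym, frequency=freq,
                                       coupling=cpl)
                    )
                    lis.append(res.li)
    assert min(lis) <= 0.42 and max(lis) >= 2.51
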