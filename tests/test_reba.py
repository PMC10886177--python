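"""Joint angles, REBA table walk, and risk levels."""

import numpy as np
import pytest

from ergoskel.reba import (
    ANGLE_NAMES,
    JointAngles,
    REBAConfig,
    angles_table,
    joint_angles,
    legs_bin,
    lower_arm_bin,
    neck_bin,
    reba_score,
    risk_level,
    score_from_bins,
    score_sequence,
    trunk_bin,
    upper_arm_bin,
)

from conftest import make_frame, neutral_pose_xy


class TestJointAngles:
    def test_vertical_trunk_is_zero(self, neutral_frame):
        a = joint_angles(neutral_frame)
        assert a.trunk == pytest.approx(0.0, abs=1e-9)
        assert a.neck == pytest.approx(0.0, abs=1e-9)

    def test_straight_limbs_zero_flexion(self, neutral_frame):
        a = joint_angles(neutral_frame)
        for name in ("leg_r", "leg_l", "lower_arm_r", "lower_arm_l"):
            assert getattr(a, name) == pytest.approx(0.0, abs=1e-6)

    def test_hanging_arms_zero(self, neutral_frame):
        a = joint_angles(neutral_frame)
        assert a.upper_arm_r == pytest.approx(0.0, abs=1e-9)
        assert a.upper_arm_l == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_forearm_is_ninety(self):
        xy = neutral_pose_xy()
        xy[4] = (300, 340)  # forearm horizontal, upper arm vertical
        a = joint_angles(make_frame(0, xy))
        assert a.lower_arm_r == pytest.approx(90.0, abs=1e-6)

    def test_no_wrist_angle_field(self):
        assert "wrist" not in ANGLE_NAMES
        assert not hasattr(JointAngles(*[0.0] * 8), "wrist")

    def test_translation_and_scale_invariance(self, neutral_frame):
        ref = joint_angles(neutral_frame).as_array()
        xy = neutral_frame.keypoints[:, :2]
        for moved in (xy + [123.0, -45.0], xy * 2.5, (xy - 200.0) * 0.5):
            got = joint_angles(make_frame(0, moved)).as_array()
            np.testing.assert_allclose(got, ref, atol=1e-9)

    def test_global_rotation_shifts_vertical_referenced_angles(
        self, neutral_frame
    ):
        theta = np.radians(30.0)
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        xy = neutral_frame.keypoints[:, :2]
        rot = (xy - xy.mean(0)) @ R.T + xy.mean(0)
        a = joint_angles(make_frame(0, rot))
        for name in ("trunk", "neck", "upper_arm_r", "upper_arm_l"):
            assert getattr(a, name) == pytest.approx(30.0, abs=1e-6)
        for name in ("leg_r", "leg_l", "lower_arm_r", "lower_arm_l"):
            assert getattr(a, name) == pytest.approx(0.0, abs=1e-6)

    def test_absent_keypoint_marks_unavailable(self, neutral_frame):
        neutral_frame.keypoints[10] = (0.0, 0.0, 0.0)  # right knee
        a = joint_angles(neutral_frame)
        assert np.isnan(a.leg_r)
        assert not np.isnan(a.leg_l)
        assert a.unavailable() == ["leg_r"]

    def test_degenerate_segment_unavailable(self, neutral_frame):
        neutral_frame.keypoints[0, :2] = neutral_frame.keypoints[1, :2]
        assert np.isnan(joint_angles(neutral_frame).neck)

    def test_eight_angles_per_frame(self, neutral_frame):
        assert len(ANGLE_NAMES) == 8
        assert joint_angles(neutral_frame).as_array().shape == (8,)


class TestBins:
    @pytest.mark.parametrize(
        "angle,expected",
        [(0, 1), (4.9, 1), (10, 2), (20, 2), (45, 3), (60, 3), (61, 4)],
    )
    def test_trunk(self, angle, expected):
        assert trunk_bin(angle, twist=False) == expected

    def test_trunk_twist_caps_at_five(self):
        assert trunk_bin(90, twist=True) == 5

    def test_neck(self):
        assert neck_bin(10, twist=False) == 1
        assert neck_bin(25, twist=False) == 2
        assert neck_bin(25, twist=True) == 3

    def test_legs(self):
        assert legs_bin(10, leg_raised=False) == 1
        assert legs_bin(45, leg_raised=False) == 2
        assert legs_bin(70, leg_raised=False) == 3
        assert legs_bin(70, leg_raised=True) == 4

    def test_upper_arm(self):
        assert upper_arm_bin(10, False, False, False) == 1
        assert upper_arm_bin(30, False, False, False) == 2
        assert upper_arm_bin(70, False, False, False) == 3
        assert upper_arm_bin(120, False, False, False) == 4
        assert upper_arm_bin(120, True, True, False) == 6
        assert upper_arm_bin(10, False, False, True) == 1  # clipped at 1

    def test_lower_arm(self):
        assert lower_arm_bin(80) == 1
        assert lower_arm_bin(30) == 2
        assert lower_arm_bin(120) == 2


class TestScoreFromBins:
    def test_neutral_minimum(self):
        # manual walk through the published tables: all bins at 1,
        # no load, good coupling, no activity -> A=1, B=1, C=1, final 1
        assert score_from_bins(1, 1, 1, 1, 1, 1) == (1, 1, 1, 1)

    def test_known_cell(self):
        # trunk 3, neck 2, legs 2 -> table A = 5; load 1 -> A = 6
        # upper arm 4, lower arm 2, wrist 1 -> table B = 5; coupling 2 -> 7
        # C[6-1][7-1] = 9; activity 1 -> 10
        assert score_from_bins(3, 2, 2, 4, 2, 1, 1, 2, 1) == (6, 7, 9, 10)

    def test_out_of_range_bins(self):
        with pytest.raises(ValueError):
            score_from_bins(0, 1, 1, 1, 1, 1)
        with pytest.raises(ValueError):
            score_from_bins(1, 1, 1, 7, 1, 1)
        with pytest.raises(ValueError):
            score_from_bins(1, 1, 1, 1, 1, 1, load=4)


class TestREBAScore:
    def test_neutral_posture_scores_one(self, neutral_frame):
        res = reba_score(joint_angles(neutral_frame), REBAConfig())
        assert res.final_score == 1
        assert res.risk_level == "Negligible"
        assert res.suggestion == "None necessary"

    def test_worse_arm_side_used(self, neutral_frame):
        xy = neutral_frame.keypoints[:, :2].copy()
        xy[6] = xy[5] + (0, -80)  # left arm raised far overhead
        res = reba_score(joint_angles(make_frame(0, xy)), REBAConfig())
        assert res.side_used == "left"
        assert res.upper_arm_score == 4

    def test_unavailable_angles_error_lists_them(self, neutral_frame):
        neutral_frame.keypoints[10] = (0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="leg_r"):
            reba_score(joint_angles(neutral_frame))

    def test_wrist_held_constant_but_configurable(self, neutral_frame):
        a = joint_angles(neutral_frame)
        assert reba_score(a, REBAConfig()).wrist_score == 1
        assert reba_score(a, REBAConfig(wrist_score=3)).wrist_score == 3

    def test_load_and_activity_raise_score(self, neutral_frame):
        a = joint_angles(neutral_frame)
        base = reba_score(a, REBAConfig()).final_score
        loaded = reba_score(
            a,
            REBAConfig(load_kg=12, shock=True, static=True, repeated=True,
                       rapid_change=True, coupling="poor"),
        ).final_score
        assert loaded > base


class TestRiskLevel:
    @pytest.mark.parametrize(
        "score,risk,suggestion",
        [
            (1, "Negligible", "None necessary"),
            (3, "Low", "Maybe necessary"),
            (12, "Very high", "Necessary now"),
        ],
    )
    def test_published_rows(self, score, risk, suggestion):
        r, s, _ = risk_level(score)
        assert (r, s) == (risk, suggestion)

    def test_full_mapping(self):
        expected = (
            [(1, "Negligible", 0)]
            + [(s, "Low", 1) for s in (2, 3)]
            + [(s, "Medium", 2) for s in range(4, 8)]
            + [(s, "High", 3) for s in range(8, 11)]
            + [(s, "Very high", 4) for s in range(11, 16)]
        )
        for score, risk, action in expected:
            r, _, a = risk_level(score)
            assert (r, a) == (risk, action)

    def test_out_of_range(self):
        for bad in (0, 16, -3):
            with pytest.raises(ValueError):
                risk_level(bad)


class TestScoreSequence:
    def test_one_row_per_frame_with_nan_passthrough(self, neutral_frame):
        good = neutral_frame.keypoints
        bad = good.copy()
        bad[10] = (0.0, 0.0, 0.0)
        table = score_sequence(angles_table(np.stack([good, bad])))
        assert len(table) == 2
        assert table.loc[0, "final_score"] == 1
        assert np.isnan(table.loc[1, "final_score"])
        assert table.loc[1, "risk_level"] == ""
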