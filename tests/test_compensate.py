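"""Missing-frame repair: anchors, interpolation, sequence compensation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ergoskel.compensate import (
    AnchorPair,
    CompensateParams,
    UncompensableError,
    compensate_sequence,
    find_anchors,
    interpolate_missing,
)
from ergoskel.discriminate import IntegrityReport, classify_sequence
from ergoskel.skeleton import SkeletonSequence
from ergoskel.topology import N_KEYPOINTS

from conftest import blank_frame, make_frame, static_sequence


def _reports(statuses):
    out = []
    for i, s in enumerate(statuses):
        ids = {0} if s == "missing" else set()
        out.append(IntegrityReport(i, s, missing_ids=ids))
    return out


class TestFindAnchors:
    def test_nearest_complete_pair(self):
        # complete at 3 and 8; 4, 5 missing; 6, 7 misidentified
        statuses = (
            ["complete"] * 4 + ["missing", "missing"]
            + ["misidentified", "misidentified"] + ["complete"] * 2
        )
        seq = static_sequence(len(statuses))
        pair = find_anchors(seq, 5, _reports(statuses))
        assert (pair.start_index, pair.end_index, pair.n_missing) == (3, 8, 2)

    def test_missing_run(self):
        statuses = ["complete"] * 4 + ["missing"] * 3 + ["complete"] * 3
        seq = static_sequence(len(statuses))
        pair = find_anchors(seq, 5, _reports(statuses))
        assert (pair.start_index, pair.end_index, pair.n_missing) == (3, 7, 3)

    def test_no_preceding_anchor_uncompensable(self):
        statuses = ["missing"] * 6 + ["complete"] * 6
        seq = static_sequence(len(statuses))
        with pytest.raises(UncompensableError):
            find_anchors(seq, 5, _reports(statuses))

    def test_span_bound(self):
        statuses = ["complete"] + ["missing"] * 21 + ["complete"]
        seq = static_sequence(len(statuses))
        with pytest.raises(UncompensableError):
            find_anchors(seq, 11, _reports(statuses), max_span=10)
        # frame 5 is within 10 of the left anchor but not the right one
        with pytest.raises(UncompensableError):
            find_anchors(seq, 5, _reports(statuses), max_span=10)

    def test_not_missing_raises(self):
        seq = static_sequence(3)
        with pytest.raises(ValueError):
            find_anchors(seq, 1, _reports(["complete"] * 3))

    def test_anchor_pair_invariant(self):
        with pytest.raises(ValueError):
            AnchorPair(5, 5, 0)


class TestInterpolateMissing:
    def test_midpoint(self):
        pts = interpolate_missing(np.array([0.0, 0.0]), np.array([10.0, 20.0]), 1)
        np.testing.assert_allclose(pts, [[5.0, 10.0]])

    def test_four_points(self):
        pts = interpolate_missing(np.array([0.0, 0.0]), np.array([10.0, 20.0]), 4)
        np.testing.assert_allclose(
            pts, [[2.0, 4.0], [4.0, 8.0], [6.0, 12.0], [8.0, 16.0]]
        )

    def test_degenerate_anchors(self):
        p = np.array([3.0, 4.0])
        for q in interpolate_missing(p, p.copy(), 5):
            np.testing.assert_allclose(q, p)

    def test_zero_is_noop(self):
        assert interpolate_missing(np.zeros(2), np.ones(2), 0) == []

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            interpolate_missing(np.zeros(2), np.ones(2), -1)


class TestCompensateSequence:
    def test_small_gap_fully_filled(self):
        seq = static_sequence(10)
        blank_frame(seq[4], range(25))
        blank_frame(seq[5], range(25))
        reports = classify_sequence(seq)
        res = compensate_sequence(seq, reports)
        assert res.n_compensated == 2 and res.n_uncompensable == 0
        assert all(r.status == "complete" for r in res.reports)
        assert all(v == 0.0 for v in res.residual_missing.values())

    def test_linear_motion_exact(self):
        base = np.random.default_rng(5).uniform(100, 400, size=(N_KEYPOINTS, 2))
        vel = np.array([1.5, -0.75])
        frames = [make_frame(t, base + t * vel) for t in range(20)]
        truth = SkeletonSequence(frames).stacked()
        seq = SkeletonSequence([make_frame(t, base + t * vel) for t in range(20)])
        for t in range(8, 13):
            blank_frame(seq[t], range(25))
        res = compensate_sequence(seq, classify_sequence(seq))
        np.testing.assert_allclose(
            res.sequence.stacked()[:, :, :2], truth[:, :, :2], atol=1e-9
        )

    def test_synthesized_confidence_sentinel(self):
        seq = static_sequence(7)
        blank_frame(seq[3], [4, 7])
        res = compensate_sequence(seq, classify_sequence(seq))
        assert res.sequence[3].keypoints[4, 2] == 0.5
        assert res.sequence[3].keypoints[7, 2] == 0.5
        # untouched keypoints keep their measured confidence
        assert res.sequence[3].keypoints[0, 2] == 0.9

    def test_oversized_gap_stays_missing(self):
        seq = static_sequence(40)
        for t in range(5, 30):  # 25-frame gap exceeds the traversal span
            blank_frame(seq[t], range(25))
        res = compensate_sequence(seq, classify_sequence(seq))
        still = [r for r in res.reports if r.status == "missing"]
        # both-sided anchors within 10 frames are unreachable everywhere
        assert len(still) == 25
        assert any(v > 0 for v in res.residual_missing.values())

    def test_complete_frames_untouched(self):
        seq = static_sequence(12)
        blank_frame(seq[6], [3])
        before = seq.stacked().copy()
        res = compensate_sequence(seq, classify_sequence(seq))
        after = res.sequence.stacked()
        complete = [t for t in range(12) if t != 6]
        np.testing.assert_array_equal(after[complete], before[complete])
        # input sequence not mutated either
        np.testing.assert_array_equal(seq.stacked(), before)

    def test_partial_frame_repair_uses_same_anchors(self):
        seq = static_sequence(9)
        blank_frame(seq[4], [11, 14])  # only ankles missing
        res = compensate_sequence(seq, classify_sequence(seq))
        assert res.reports[4].status == "complete"
        np.testing.assert_allclose(
            res.sequence[4].keypoints[11, :2], seq[3].keypoints[11, :2]
        )

    def test_missing_rate_never_increases(self):
        from ergoskel import synthetic

        fx = synthetic.default_fixture(seed=11, n_frames=600)
        reports = classify_sequence(fx["corrupted"], fx["weights"])
        pre = sum(1 for r in reports if r.status == "missing")
        res = compensate_sequence(fx["corrupted"], reports)
        post = sum(1 for r in res.reports if r.status == "missing")
        assert post <= pre

    def test_boundary_gap_hold_nearest_flag(self):
        seq = static_sequence(8)
        blank_frame(seq[0], range(25))
        reports = classify_sequence(seq)
        default = compensate_sequence(seq, reports)
        assert default.reports[0].status == "missing"
        held = compensate_sequence(
            seq, reports, CompensateParams(hold_boundary=True)
        )
        assert held.reports[0].status == "complete"

    def test_rms_error_monotone_in_gap_length(self):
        # smooth sinusoidal motion at 50 Hz: longer masked gaps cannot
        # reconstruct better than shorter ones
        from ergoskel import synthetic

        truth, _ = synthetic.generate_sequence([("bend", 80)], seed=9)
        errs = []
        for gap in (2, 4, 6, 8, 10):
            seq = truth.copy()
            for t in range(40 - gap // 2, 40 + (gap + 1) // 2):
                blank_frame(seq[t], range(25))
            res = compensate_sequence(seq, classify_sequence(seq))
            diff = res.sequence.stacked()[:, :, :2] - truth.stacked()[:, :, :2]
            errs.append(np.sqrt((diff**2).mean()))
        assert all(a <= b + 1e-12 for a, b in zip(errs, errs[1:]))


@settings(max_examples=40, deadline=None)
@given(
    st.integers(min_value=1, max_value=12),
    st.floats(min_value=-1e3, max_value=1e3),
    st.floats(min_value=-1e3, max_value=1e3),
    st.floats(min_value=-1e3, max_value=1e3),
    st.floats(min_value=-1e3, max_value=1e3),
)
def test_interpolation_endpoints_bound_property(n, xs, ys, xe, ye):
    pts = interpolate_missing(np.array([xs, ys]), np.array([xe, ye]), n)
    assert len(pts) == n
    for p in pts:
        assert min(xs, xe) - 1e-9 <= p[0] <= max(xs, xe) + 1e-9
        assert min(ys, ye) - 1e-9 <= p[1] <= max(ys, ye) + 1e-9
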