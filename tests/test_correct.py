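"""Misidentification correction and Kalman smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ergoskel.actions import ActionWeights
from ergoskel.correct import (
    CorrectParams,
    KalmanParams,
    UncorrectableError,
    correct_frame,
    correct_sequence,
    kalman_smooth,
    smooth_sequence,
)
from ergoskel.discriminate import DiscriminateParams, classify_sequence

from conftest import static_sequence


def _weights(labels):
    all_labels = sorted(set(labels))
    return [
        ActionWeights.one_hot(i, lab, all_labels) for i, lab in enumerate(labels)
    ]


def _oracle_kalman(y, A, B, C, Q, R, x0, P0):
    """Independent step-by-step coding of the filter recursion."""
    xs = []
    x, P = x0, P0
    for k in range(len(y)):
        x_prior = A * x + B * 0.0
        P_prior = A * P * A + Q
        K = P_prior * C / (C * P_prior * C + R)
        x = x_prior + K * (y[k] - C * x_prior)
        P = (1 - K * C) * P_prior
        xs.append(x)
    return np.array(xs)


class TestKalmanSmooth:
    def test_constant_series_is_identity(self):
        y = np.full(50, 3.25)
        out = kalman_smooth(y, KalmanParams(x0=3.25))
        np.testing.assert_allclose(out, y, atol=1e-12)

    def test_r_to_zero_limit_tracks_measurements(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=100)
        out = kalman_smooth(y, KalmanParams(Q=1e-3, R=1e-12))
        np.testing.assert_allclose(out, y, atol=1e-6)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(42)
        y = np.cumsum(rng.normal(size=200)) + rng.normal(scale=0.5, size=200)
        params = KalmanParams(Q=1e-3, R=1e-2, P0=1.0)
        out = kalman_smooth(y, params)
        ref = _oracle_kalman(y, 1.0, 0.0, 1.0, 1e-3, 1e-2, y[0], 1.0)
        np.testing.assert_allclose(out, ref, atol=1e-12)

    def test_invalid_r_raises(self):
        with pytest.raises(ValueError):
            KalmanParams(R=0.0)
        with pytest.raises(ValueError):
            KalmanParams(Q=-1.0)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            kalman_smooth(np.array([]))

    @settings(max_examples=30, deadline=None)
    @given(
        st.integers(min_value=0, max_value=2**32 - 1),
        st.floats(min_value=-100, max_value=100),
    )
    def test_shift_equivariance(self, seed, c):
        # A = C = 1, B = 0: smoothing(series + c) = smoothing(series) + c
        rng = np.random.default_rng(seed)
        y = rng.normal(scale=5, size=60)
        a = kalman_smooth(y + c)
        b = kalman_smooth(y) + c
        np.testing.assert_allclose(a, b, atol=1e-8)


class TestSmoothSequence:
    def test_absent_keypoints_untouched(self):
        seq = static_sequence(20)
        seq[5].keypoints[7] = (0.0, 0.0, 0.0)
        out = smooth_sequence(seq)
        assert tuple(out[5].keypoints[7]) == (0.0, 0.0, 0.0)

    def test_matches_scalar_smoother(self):
        rng = np.random.default_rng(1)
        seq = static_sequence(30)
        for f in seq.frames:
            f.keypoints[:, :2] += rng.normal(scale=0.5, size=(25, 2))
        out = smooth_sequence(seq)
        x_series = np.array([f.keypoints[3, 0] for f in seq.frames])
        np.testing.assert_allclose(
            [f.keypoints[3, 0] for f in out.frames],
            kalman_smooth(x_series),
            atol=1e-12,
        )


class TestCorrectFrame:
    def _swap_fixture(self, n=21, event=(10,), labels_flip=True):
        seq = static_sequence(n)
        truth = seq.stacked().copy()
        labels = ["A"] * n
        for t in event:
            seq[t].keypoints[4, :2] += (90.0, 50.0)
            if labels_flip:
                labels[t] = "B"
        return seq, truth, _weights(labels)

    def test_midpoint_repair(self):
        seq, truth, weights = self._swap_fixture()
        dparams = DiscriminateParams(persistence=1)
        reports = classify_sequence(seq, weights, dparams)
        assert reports[10].status == "misidentified"
        frame, w = correct_frame(seq, 10, reports, weights)
        # neighbors are identical, so the midpoint equals the true position
        np.testing.assert_allclose(frame.keypoints[4, :2], truth[10, 4, :2])
        assert w.argmax == "A"

    def test_no_dominant_uncorrectable(self):
        seq, _, _ = self._swap_fixture()
        labels = (["A", "B"] * 11)[:21]  # 11/10 split: no > 60% label
        weights = _weights(labels)
        dparams = DiscriminateParams(persistence=1, policy="or")
        reports = classify_sequence(seq, weights, dparams)
        if reports[10].status != "misidentified":
            pytest.skip("fixture did not flag the frame")
        with pytest.raises(UncorrectableError):
            correct_frame(seq, 10, reports, weights)

    def test_not_misidentified_raises(self):
        seq = static_sequence(5)
        weights = _weights(["A"] * 5)
        reports = classify_sequence(seq, weights)
        with pytest.raises(ValueError):
            correct_frame(seq, 2, reports, weights)

    def test_swap_fixture_bone_length_within_tolerance(self):
        from ergoskel import synthetic
        from ergoskel.skeleton import squared_link_lengths
        from ergoskel.topology import BODY25

        truth, labels = synthetic.generate_sequence(
            [("bend", 100)], noise_px=0.0, seed=4
        )
        cor, log = synthetic.inject_misidentification(
            truth, 0.03, magnitude=0.5, seed=1, labels=labels
        )
        weights = _weights(log.apply_label_flips(labels))
        reports = classify_sequence(cor, weights)
        res = correct_sequence(
            cor, reports, weights, CorrectParams(smooth=False)
        )
        sq_true = squared_link_lengths(truth.stacked()[:, :, :2], BODY25)
        sq_corr = squared_link_lengths(res.sequence.stacked()[:, :, :2], BODY25)
        for t in sorted(log.misid_frames()):
            ratio = np.sqrt(sq_corr[t] / sq_true[t])
            np.testing.assert_allclose(ratio, 1.0, atol=0.05)


class TestCorrectSequence:
    def test_zero_misid_only_smoothing(self):
        seq = static_sequence(25)
        weights = _weights(["A"] * 25)
        reports = classify_sequence(seq, weights)
        res = correct_sequence(seq, reports, weights)
        smoothed = smooth_sequence(seq)
        np.testing.assert_allclose(
            res.sequence.stacked(), smoothed.stacked(), atol=1e-12
        )
        assert res.n_corrected == 0

    def test_smoothing_disabled_passthrough(self):
        seq = static_sequence(25)
        weights = _weights(["A"] * 25)
        reports = classify_sequence(seq, weights)
        res = correct_sequence(
            seq, reports, weights, CorrectParams(smooth=False)
        )
        np.testing.assert_array_equal(res.sequence.stacked(), seq.stacked())

    def test_injected_misid_rate_strictly_drops(self):
        from ergoskel import synthetic

        seq, labels = synthetic.generate_sequence(
            [("bend", 250), ("lift", 250)], noise_px=0.2, seed=8
        )
        cor, log = synthetic.inject_misidentification(
            seq, 0.20, seed=2, labels=labels
        )
        weights = _weights(log.apply_label_flips(labels))
        reports = classify_sequence(cor, weights)
        before = sum(1 for r in reports if r.status == "misidentified") / len(
            reports
        )
        res = correct_sequence(cor, reports, weights)
        assert before > 0
        assert res.misid_rate_after < before

    def test_complete_frames_not_repositioned(self):
        seq, truth, weights = TestCorrectFrame()._swap_fixture(event=(10, 11))
        dparams = DiscriminateParams(persistence=2)
        reports = classify_sequence(seq, weights, dparams)
        res = correct_sequence(
            seq, reports, weights, CorrectParams(smooth=False), dparams
        )
        complete = [t for t, r in enumerate(reports) if r.status == "complete"]
        np.testing.assert_array_equal(
            res.sequence.stacked()[complete], seq.stacked()[complete]
        )
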