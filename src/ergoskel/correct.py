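"""Misidentified-skeleton correction and Kalman trajectory smoothing.

A misidentified frame is rectified by dominant-action-feature replacement:
its action label is rewritten to the dominant label of its +/-10-frame
window, and the keypoints implicated by the chain anomaly are re-synthesized
by linear interpolation between the nearest complete frames in the window
whose label matches the dominant one. Frames without a strictly dominant
label (> 60% of window votes), or without matching anchors on both sides,
are left untouched and recorded as uncorrectable.

After the repair pass, every keypoint trajectory is smoothed with a scalar
Kalman filter applied independently to each coordinate series (constant-
state model: A = C = 1, B = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .actions import ActionWeights
from .discriminate import (
    STATUS_COMPLETE,
    STATUS_MISIDENTIFIED,
    DiscriminateParams,
    IntegrityReport,
    action_heterogeneity,
    classify_sequence,
)
from .skeleton import SkeletonFrame, SkeletonSequence
from .topology import BODY25, SkeletonTopology


class UncorrectableError(ValueError):
    """No dominant action or no same-label anchors in the window."""


@dataclass
class KalmanParams:
    """Scalar per-coordinate Kalman filter parameters.

    The defaults encode a constant-state model with a high process-to-
    measurement noise ratio, i.e. mild smoothing: at 50 Hz, stronger
    smoothing introduces a lag bias larger than the pixel noise it removes.
    """

    A: float = 1.0
    B: float = 0.0
    C: float = 1.0
    Q: float = 0.1
    R: float = 0.01
    x0: float | None = None  # None: first measurement
    P0: float = 1.0

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.Q < 0 or self.P0 < 0:
            raise ValueError("Q and P0 must be non-negative")


@dataclass
class CorrectParams:
    window: int = 10
    dominance: float = 0.60
    smooth: bool = True
    kalman: KalmanParams | None = None

    def __post_init__(self) -> None:
        if self.kalman is None:
            self.kalman = KalmanParams()


def kalman_smooth(series: np.ndarray, params: KalmanParams | None = None) -> np.ndarray:
    """Run the scalar predict/update recursion over a measurement series.

    Per step: prior ``x = A x + B u`` (u = 0), ``P = A P A + Q``; gain
    ``K = P C / (C P C + R)``; posterior ``x += K (y - C x)``,
    ``P = (1 - K C) P``. Returns the posterior estimates.
    """
    params = params or KalmanParams()
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("series must be a non-empty 1-D array")
    out = np.empty_like(y)
    x = y[0] if params.x0 is None else params.x0
    P = params.P0
    A, C, Q, R = params.A, params.C, params.Q, params.R
    for k in range(y.size):
        x_prior = A * x
        P_prior = A * P * A + Q
        K = P_prior * C / (C * P_prior * C + R)
        x = x_prior + K * (y[k] - C * x_prior)
        P = (1.0 - K * C) * P_prior
        out[k] = x
    return out


def _kalman_smooth_block(block: np.ndarray, params: KalmanParams) -> np.ndarray:
    """Vectorized smoothing of a (T, N) block of independent series."""
    T = block.shape[0]
    out = np.empty_like(block)
    x = block[0].copy() if params.x0 is None else np.full(block.shape[1], params.x0)
    P = np.full(block.shape[1], params.P0, dtype=float)
    A, C, Q, R = params.A, params.C, params.Q, params.R
    for k in range(T):
        x_prior = A * x
        P_prior = A * P * A + Q
        K = P_prior * C / (C * P_prior * C + R)
        x = x_prior + K * (block[k] - C * x_prior)
        P = (1.0 - K * C) * P_prior
        out[k] = x
    return out


def smooth_sequence(
    seq: SkeletonSequence,
    params: KalmanParams | None = None,
    conf_threshold: float = 0.1,
) -> SkeletonSequence:
    """Kalman-smooth every present keypoint trajectory of a sequence.

    Each keypoint's x and y series are smoothed independently over maximal
    runs of frames where the keypoint is present; absent keypoints are
    left untouched (the filter restarts after each gap).
    """
    params = params or KalmanParams()
    out = seq.copy()
    data = out.stacked()
    conf = data[:, :, 2]
    present = (conf >= conf_threshold) & ~(
        (data[:, :, 0] == 0.0) & (data[:, :, 1] == 0.0)
    )
    T, V = present.shape
    for v in range(V):
        col = present[:, v]
        t = 0
        while t < T:
            if not col[t]:
                t += 1
                continue
            start = t
            while t < T and col[t]:
                t += 1
            block = data[start:t, v, :2]
            data[start:t, v, :2] = _kalman_smooth_block(block, params)
    for i, frame in enumerate(out.frames):
        frame.keypoints[:] = data[i]
    return out


def _dominant_and_anchors(
    seq: SkeletonSequence,
    t: int,
    reports: list[IntegrityReport],
    weights: list[ActionWeights],
    params: CorrectParams,
) -> tuple[str, int, int]:
    """Dominant label of the window and nearest matching complete anchors."""
    T = len(seq)
    lo, hi = max(0, t - params.window), min(T, t + params.window + 1)
    _, dominant, proportion = action_heterogeneity(
        weights[lo:hi], weights[t].argmax, params.dominance
    )
    if dominant is None:
        raise UncorrectableError(
            f"no dominant action in window of position {t} "
            f"(top proportion {proportion:.3f} <= {params.dominance})"
        )

    def matches(s: int) -> bool:
        return (
            reports[s].status == STATUS_COMPLETE and weights[s].argmax == dominant
        )

    before = next((s for s in range(t - 1, lo - 1, -1) if matches(s)), None)
    after = next((s for s in range(t + 1, hi) if matches(s)), None)
    if before is None or after is None:
        raise UncorrectableError(
            f"no complete '{dominant}'-labelled anchors on both sides of position {t}"
        )
    return dominant, before, after


def correct_frame(
    seq: SkeletonSequence,
    t: int,
    reports: list[IntegrityReport],
    weights: list[ActionWeights],
    params: CorrectParams | None = None,
) -> tuple[SkeletonFrame, ActionWeights]:
    """Rectify one misidentified frame; returns the new frame and weights.

    The implicated keypoints (from the report's chain-anomaly evidence)
    are re-synthesized by interpolation between the anchors; all other
    keypoints are untouched. The frame's action weights are replaced by a
    one-hot vector on the dominant label.
    """
    params = params or CorrectParams()
    if reports[t].status != STATUS_MISIDENTIFIED:
        raise ValueError(f"frame at position {t} is not flagged misidentified")
    dominant, s, e = _dominant_and_anchors(seq, t, reports, weights, params)
    frame = seq[t].copy()
    ids = sorted(reports[t].implicated_ids)
    if ids:
        frac = (t - s) / (e - s)
        frame.keypoints[ids, :2] = (
            (1.0 - frac) * seq[s].xy[ids] + frac * seq[e].xy[ids]
        )
    labels = sorted(weights[t].weights)
    return frame, ActionWeights.one_hot(weights[t].frame_index, dominant, labels)


@dataclass
class CorrectionResult:
    sequence: SkeletonSequence
    reports: list[IntegrityReport]
    weights: list[ActionWeights]
    misid_rate_after: float
    n_corrected: int = 0
    n_uncorrectable: int = 0


def correct_sequence(
    seq: SkeletonSequence,
    reports: list[IntegrityReport],
    weights: list[ActionWeights],
    params: CorrectParams | None = None,
    discriminate_params: DiscriminateParams | None = None,
    topology: SkeletonTopology = BODY25,
) -> CorrectionResult:
    """Correct all correctable misidentified frames, then smooth.

    Frames classified complete are never modified by the correction pass
    (smoothing aside). The post-hoc misidentification rate is recomputed
    by re-classifying the repaired, smoothed sequence.
    """
    params = params or CorrectParams()
    out = seq.copy()
    new_weights = list(weights)
    n_corr = n_unc = 0
    for t in range(len(out)):
        if reports[t].status != STATUS_MISIDENTIFIED:
            continue
        try:
            frame, w = correct_frame(seq, t, reports, weights, params)
        except UncorrectableError:
            n_unc += 1
            continue
        out.frames[t] = frame
        new_weights[t] = w
        n_corr += 1

    if params.smooth:
        out = smooth_sequence(out, params.kalman)

    new_reports = classify_sequence(out, new_weights, discriminate_params, topology)
    n_mis = sum(1 for r in new_reports if r.status == STATUS_MISIDENTIFIED)
    rate = n_mis / len(new_reports) if new_reports else 0.0
    return CorrectionResult(out, new_reports, new_weights, rate, n_corr, n_unc)
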