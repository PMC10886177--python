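"""Missing-skeleton repair by anchored linear interpolation.

For each frame flagged missing, the nearest complete frames before and
after it (within a bounded traversal span, 10 frames per side by default)
serve as anchors; absent keypoints are filled by linear interpolation
between the anchor coordinates. Only absent keypoints are synthesized —
per-keypoint repair generalizes whole-frame traversal and reduces to it
when the entire skeleton is gone. Frames with no anchor on one side stay
flagged (the residual-missing pathway); an optional hold-nearest
extrapolation for sequence-boundary gaps sits behind a config flag and is
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discriminate import (
    STATUS_COMPLETE,
    STATUS_MISSING,
    IntegrityReport,
    detect_missing,
)
from .skeleton import SYNTHESIZED_CONF, SkeletonSequence
from .topology import JOINT_GROUPS


class UncompensableError(ValueError):
    """No complete anchor exists on one side within the traversal span."""


@dataclass
class CompensateParams:
    max_span: int = 10
    #: fill one-sided boundary gaps by holding the nearest complete frame
    hold_boundary: bool = False
    synthesized_conf: float = SYNTHESIZED_CONF


@dataclass(frozen=True)
class AnchorPair:
    """Complete frames bracketing a missing frame, by sequence position."""

    start_index: int
    end_index: int
    n_missing: int

    def __post_init__(self) -> None:
        if not self.start_index < self.end_index:
            raise ValueError("start_index must precede end_index")


def find_anchors(
    seq: SkeletonSequence,
    t: int,
    reports: list[IntegrityReport],
    max_span: int = 10,
) -> AnchorPair:
    """Nearest complete frames at or before ``t-1`` / at or after ``t+1``.

    ``n_missing`` counts the frames strictly between the anchors that are
    themselves flagged missing.

    Raises
    ------
    UncompensableError
        When either side has no complete frame within ``max_span``.
    """
    if reports[t].status != STATUS_MISSING:
        raise ValueError(f"frame at position {t} is not flagged missing")
    start = next(
        (
            s
            for s in range(t - 1, max(t - max_span, 0) - 1, -1)
            if reports[s].status == STATUS_COMPLETE
        ),
        None,
    )
    end = next(
        (
            e
            for e in range(t + 1, min(t + max_span, len(seq) - 1) + 1)
            if reports[e].status == STATUS_COMPLETE
        ),
        None,
    )
    if start is None or end is None:
        side = "preceding" if start is None else "succeeding"
        raise UncompensableError(
            f"no complete {side} anchor within {max_span} frames of position {t}"
        )
    n = sum(
        1 for u in range(start + 1, end) if reports[u].status == STATUS_MISSING
    )
    return AnchorPair(start, end, n)


def interpolate_missing(
    Ps: np.ndarray, Pe: np.ndarray, n: int
) -> list[np.ndarray]:
    """``n`` evenly spaced points strictly between ``Ps`` and ``Pe``.

    Point ``i`` (1-based) is ``(1 - t) * Ps + t * Pe`` with
    ``t = i / (n + 1)``; applies componentwise, so callers may pass 2-d
    coordinates or whole keypoint blocks.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    Ps = np.asarray(Ps, dtype=float)
    Pe = np.asarray(Pe, dtype=float)
    out = []
    for i in range(1, n + 1):
        t = i / (n + 1)
        out.append((1.0 - t) * Ps + t * Pe)
    return out


@dataclass
class CompensationResult:
    sequence: SkeletonSequence
    reports: list[IntegrityReport]
    #: per joint group: fraction of frames still missing that group
    residual_missing: dict[str, float] = field(default_factory=dict)
    n_compensated: int = 0
    n_uncompensable: int = 0


def compensate_sequence(
    seq: SkeletonSequence,
    reports: list[IntegrityReport],
    params: CompensateParams | None = None,
) -> CompensationResult:
    """Fill every compensable missing frame; never touches complete frames.

    Returns a new sequence (the input is not mutated), updated reports
    (compensated frames re-detected, normally becoming complete), and
    residual per-joint-group missing rates for frames that stayed missing.
    """
    params = params or CompensateParams()
    out = seq.copy()
    T = len(out)
    n_comp = n_unc = 0
    for t in range(T):
        if reports[t].status != STATUS_MISSING:
            continue
        absent = sorted(reports[t].missing_ids)
        try:
            pair = find_anchors(seq, t, reports, params.max_span)
        except UncompensableError:
            if params.hold_boundary:
                near = _nearest_complete(t, reports, params.max_span)
                if near is not None:
                    _fill_from(out, t, seq[near].keypoints, absent, params)
                    n_comp += 1
                    continue
            n_unc += 1
            continue
        s, e = pair.start_index, pair.end_index
        frac = (t - s) / (e - s)
        xy = (1.0 - frac) * seq[s].xy[absent] + frac * seq[e].xy[absent]
        out[t].keypoints[absent, :2] = xy
        out[t].keypoints[absent, 2] = params.synthesized_conf
        n_comp += 1

    new_reports = _refresh_missing(out, reports)
    residual = {}
    for name, kps in JOINT_GROUPS.items():
        bad = sum(
            1
            for r in new_reports
            if r.status == STATUS_MISSING and r.missing_ids & set(kps)
        )
        residual[name] = bad / T if T else 0.0
    return CompensationResult(out, new_reports, residual, n_comp, n_unc)


def _nearest_complete(
    t: int, reports: list[IntegrityReport], max_span: int
) -> int | None:
    for d in range(1, max_span + 1):
        for s in (t - d, t + d):
            if 0 <= s < len(reports) and reports[s].status == STATUS_COMPLETE:
                return s
    return None


def _fill_from(out, t, anchor_keypoints, absent, params) -> None:
    out[t].keypoints[absent, :2] = anchor_keypoints[absent, :2]
    out[t].keypoints[absent, 2] = params.synthesized_conf


def _refresh_missing(
    seq: SkeletonSequence, reports: list[IntegrityReport]
) -> list[IntegrityReport]:
    """Re-detect absence after filling; other statuses pass through."""
    new_reports: list[IntegrityReport] = []
    for t, r in enumerate(reports):
        if r.status != STATUS_MISSING:
            new_reports.append(r)
            continue
        still = detect_missing(seq[t])
        if still:
            new_reports.append(
                IntegrityReport(r.frame_index, STATUS_MISSING, missing_ids=still)
            )
        else:
            new_reports.append(IntegrityReport(r.frame_index, STATUS_COMPLETE))
    return new_reports
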