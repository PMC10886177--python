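"""Per-frame skeleton integrity classification.

Each frame is classified as ``complete``, ``missing`` or ``misidentified``
by combining three evidence channels:

* keypoint presence (absence convention: low confidence or (0, 0));
* the temporal kinematic chain: relative changes in squared link lengths
  against the most recent trusted (unflagged, non-missing) frame;
* action-feature heterogeneity: the frame's action label disagreeing with
  the dominant label (> 60% of argmax votes) of its +/-10-frame window.

Missing takes precedence. The chain channel requires the anomaly to
persist for a configurable number of consecutive frames to suppress
single-frame jitter. The default verdict policy is disjunctive (chain
anomaly OR heterogeneity); both pieces of evidence are always recorded,
and a conjunctive policy is available via :class:`DiscriminateParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .actions import ActionWeights, argmax_labels
from .skeleton import ABSENCE_CONF_THRESHOLD, SkeletonFrame, SkeletonSequence, squared_link_lengths
from .topology import BODY25, SkeletonTopology

STATUS_COMPLETE = "complete"
STATUS_MISSING = "missing"
STATUS_MISIDENTIFIED = "misidentified"


class NotEvaluableError(ValueError):
    """Chain anomaly cannot be evaluated because a frame is missing."""


@dataclass
class DiscriminateParams:
    """Thresholds for the integrity classifier."""

    absence_conf: float = ABSENCE_CONF_THRESHOLD
    #: relative change in squared link length flagged as anomalous
    tau: float = 0.2
    #: consecutive chain flags required before a frame is marked misidentified
    persistence: int = 2
    #: half-width (frames) of the action-heterogeneity window
    window: int = 10
    #: strict dominance threshold on the windowed argmax-vote fraction
    dominance: float = 0.60
    #: "or" (default) or "and": how chain and heterogeneity evidence combine
    policy: str = "or"

    def __post_init__(self) -> None:
        if self.policy not in ("or", "and"):
            raise ValueError("policy must be 'or' or 'and'")
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")


@dataclass
class IntegrityReport:
    """Classification of one frame with the evidence behind it."""

    frame_index: int
    status: str
    missing_ids: set[int] = field(default_factory=set)
    #: max over links of |phi_jj| / psi_jj(baseline); 0 when not evaluated
    phi_diag_max_rel: float = 0.0
    heterogeneous: bool = False
    #: keypoints implicated by anomalous links (children + descendants)
    implicated_ids: set[int] = field(default_factory=set)
    #: frame index of the trusted baseline the chain was compared against
    baseline_index: int | None = None

    def __post_init__(self) -> None:
        if (self.status == STATUS_MISSING) != bool(self.missing_ids):
            raise ValueError("status 'missing' iff missing_ids is non-empty")
        if self.status == STATUS_MISIDENTIFIED and self.missing_ids:
            raise ValueError("misidentified frames must have no missing ids")


def detect_missing(
    frame: SkeletonFrame, conf_threshold: float = ABSENCE_CONF_THRESHOLD
) -> set[int]:
    """Return exactly the absent keypoint ids of the frame."""
    return frame.absent_ids(conf_threshold)


def phi_anomaly(
    seq: SkeletonSequence,
    t: int,
    i: int = 1,
    tau: float = 0.2,
    topology: SkeletonTopology = BODY25,
    conf_threshold: float = ABSENCE_CONF_THRESHOLD,
) -> tuple[bool, float]:
    """Chain anomaly between sequence positions ``t`` and ``t + i``.

    Returns ``(flag, magnitude)`` where ``magnitude`` is the max over links
    of ``|phi_jj| / psi_jj(t)`` and ``flag`` is ``magnitude > tau``.

    Raises
    ------
    NotEvaluableError
        If either frame has absent keypoints (route to compensation first).
    """
    for pos in (t, t + i):
        if detect_missing(seq[pos], conf_threshold) & topology.keypoint_ids:
            raise NotEvaluableError(
                f"frame at position {pos} has absent keypoints; not evaluable"
            )
    xy = np.stack([seq[t].xy, seq[t + i].xy])
    sq = squared_link_lengths(xy, topology)
    rel = np.abs(sq[1] - sq[0]) / sq[0]
    magnitude = float(rel.max())
    return magnitude > tau, magnitude


def action_heterogeneity(
    weights_window: list[ActionWeights],
    center_label: str,
    dominance: float = 0.60,
) -> tuple[bool, str | None, float]:
    """Dominant-label vote over a window of per-frame action weights.

    The dominant label is the modal argmax label iff its vote fraction
    strictly exceeds ``dominance``; the frame is heterogeneous when a
    dominant label exists and the center label differs from it.
    """
    if not weights_window:
        raise ValueError("weights window must be non-empty")
    votes = argmax_labels(weights_window)
    modal = max(sorted(set(votes)), key=votes.count)
    proportion = votes.count(modal) / len(votes)
    dominant = modal if proportion > dominance else None
    heterogeneous = dominant is not None and center_label != dominant
    return heterogeneous, dominant, proportion


def _chain_flags(
    seq: SkeletonSequence,
    missing: list[set[int]],
    params: DiscriminateParams,
    topology: SkeletonTopology,
) -> tuple[np.ndarray, np.ndarray, list[list[int]], list[int | None]]:
    """Raw per-frame chain anomaly flags against a running trusted baseline.

    The baseline advances only over unflagged, fully-present frames, so a
    multi-frame misidentification event keeps being compared against the
    last good frame instead of against itself.
    """
    T = len(seq)
    required = topology.keypoint_ids
    sq = squared_link_lengths(seq.stacked()[:, :, :2], topology)
    raw = np.zeros(T, dtype=bool)
    mag = np.zeros(T, dtype=float)
    bad_links: list[list[int]] = [[] for _ in range(T)]
    baseline_of: list[int | None] = [None] * T
    baseline: int | None = None
    for t in range(T):
        if missing[t] & required:
            continue
        if baseline is None:
            baseline = t
            continue
        rel = np.abs(sq[t] - sq[baseline]) / sq[baseline]
        mag[t] = float(rel.max())
        baseline_of[t] = seq[baseline].frame_index
        if mag[t] > params.tau:
            raw[t] = True
            bad_links[t] = np.flatnonzero(rel > params.tau).tolist()
            # cap the baseline's age at the traversal window: a baseline
            # that keeps flagging for longer than any plausible event is
            # itself suspect, so re-seat it to avoid unbounded flag runs
            if t - baseline > params.window:
                baseline = t
        else:
            baseline = t
    return raw, mag, bad_links, baseline_of


def _persistent(raw: np.ndarray, persistence: int) -> np.ndarray:
    """Keep only flags belonging to a run of >= ``persistence`` raw flags."""
    if persistence <= 1:
        return raw.copy()
    out = np.zeros_like(raw)
    t = 0
    T = raw.size
    while t < T:
        if raw[t]:
            start = t
            while t < T and raw[t]:
                t += 1
            if t - start >= persistence:
                out[start:t] = True
        else:
            t += 1
    return out


def classify_sequence(
    seq: SkeletonSequence,
    weights: list[ActionWeights] | None = None,
    params: DiscriminateParams | None = None,
    topology: SkeletonTopology = BODY25,
) -> list[IntegrityReport]:
    """Classify every frame of a sequence. Deterministic."""
    params = params or DiscriminateParams()
    T = len(seq)
    missing = [detect_missing(seq[t], params.absence_conf) for t in range(T)]
    raw, mag, bad_links, baseline_of = _chain_flags(seq, missing, params, topology)
    chain_flag = _persistent(raw, params.persistence)

    het = np.zeros(T, dtype=bool)
    if weights is not None:
        if len(weights) != T:
            raise ValueError("weights must align with the sequence, frame by frame")
        for t in range(T):
            lo, hi = max(0, t - params.window), min(T, t + params.window + 1)
            h, _, _ = action_heterogeneity(
                weights[lo:hi], weights[t].argmax, params.dominance
            )
            het[t] = h

    reports: list[IntegrityReport] = []
    for t in range(T):
        fi = seq[t].frame_index
        if missing[t]:
            reports.append(
                IntegrityReport(fi, STATUS_MISSING, missing_ids=missing[t])
            )
            continue
        if params.policy == "or":
            misid = bool(chain_flag[t] or het[t])
        else:
            misid = bool(chain_flag[t] and het[t])
        implicated: set[int] = set()
        if chain_flag[t]:
            for j in bad_links[t]:
                child = topology.links[j][1]
                implicated.add(child)
                implicated |= topology.descendants(child)
        reports.append(
            IntegrityReport(
                fi,
                STATUS_MISIDENTIFIED if misid else STATUS_COMPLETE,
                phi_diag_max_rel=float(mag[t]),
                heterogeneous=bool(het[t]),
                implicated_ids=implicated,
                baseline_index=baseline_of[t],
            )
        )
    return reports


def classify_frame(
    seq: SkeletonSequence,
    t: int,
    weights: list[ActionWeights] | None = None,
    params: DiscriminateParams | None = None,
    topology: SkeletonTopology = BODY25,
) -> IntegrityReport:
    """Classify the frame at sequence position ``t`` in sequence context."""
    if not 0 <= t < len(seq):
        raise IndexError(f"position {t} outside sequence of length {len(seq)}")
    return classify_sequence(seq, weights, params, topology)[t]
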