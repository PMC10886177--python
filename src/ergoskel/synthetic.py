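"""Synthetic 25-keypoint motion with ground truth and injected corruption.

A 2D articulated figure with fixed bone lengths is animated by smooth
per-label joint-angle trajectories and rendered by forward kinematics over
the BODY_25 tree, so the constant-bone-length premise behind the temporal
kinematic chain holds by construction. Gaussian pixel noise is applied in
image space after forward kinematics. Corruption is injected on top with
the original values retained in a :class:`CorruptionLog`, so every repair
stage can be evaluated against exact truth without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .skeleton import SkeletonSequence
from .topology import BODY25, JOINT_GROUPS

ROOT_XY = np.array([400.0, 420.0])

#: limb targets for misidentification events: displaced keypoint and the
#: descendants translated along with it (so only the proximal link's
#: length is violated, like a limb latching onto the wrong person)
LIMB_TARGETS: dict[str, tuple[int, tuple[int, ...]]] = {
    "trunk": (8, (9, 10, 11, 12, 13, 14, 19, 20, 21, 22, 23, 24)),
    "neck": (0, (15, 16, 17, 18)),
    "upper_arm_r": (3, (4,)),
    "lower_arm_r": (4, ()),
    "upper_arm_l": (6, (7,)),
    "lower_arm_l": (7, ()),
    "leg_r": (10, (11, 22, 23, 24)),
    "leg_l": (13, (14, 19, 20, 21)),
}

#: parent keypoint of each displaceable keypoint (defines the violated link)
_PARENT = {c: p for p, c in BODY25.links}


def _dir(deg: np.ndarray) -> np.ndarray:
    """Unit vector at ``deg`` degrees from image 'up' (y grows downward)."""
    rad = np.radians(deg)
    return np.stack([np.sin(rad), -np.cos(rad)], axis=-1)


# --- per-label pose parameter trajectories ---------------------------------
# Each script maps a phase array u in [0, 1) to the ten pose parameters
# (degrees): trunk, neck, sh_r, sh_l, el_r, el_l, hip_r, hip_l, kn_r, kn_l.

def _osc(u: np.ndarray, lo: float, hi: float, cycles: float = 1.0) -> np.ndarray:
    return lo + (hi - lo) * 0.5 * (1.0 - np.cos(2.0 * math.pi * cycles * u))


def _script_stand(u: np.ndarray) -> np.ndarray:
    z = np.zeros_like(u)
    return np.stack(
        [z + 3, z + 2, z + 8, z + 8, z + 12, z + 12, z + 4, z + 4, z + 5, z + 5],
        axis=1,
    )


def _script_bend(u: np.ndarray) -> np.ndarray:
    trunk = _osc(u, 8, 48)
    neck = _osc(u, 2, 14)
    hip = _osc(u, 5, 30)
    knee = _osc(u, 6, 35)
    z = np.zeros_like(u)
    return np.stack(
        [trunk, neck, z + 12, z + 12, z + 18, z + 18, hip, hip, knee, knee],
        axis=1,
    )


def _script_lift(u: np.ndarray) -> np.ndarray:
    sh = _osc(u, 12, 70)
    el = _osc(u, 20, 85)
    z = np.zeros_like(u)
    return np.stack(
        [z + 12, z + 6, sh, sh, el, el, z + 8, z + 8, z + 12, z + 12], axis=1
    )


ACTION_SCRIPTS = {
    "stand": _script_stand,
    "bend": _script_bend,
    "lift": _script_lift,
}


def _forward_kinematics(params: np.ndarray) -> np.ndarray:
    """Pose parameters (T, 10) -> keypoint coordinates (T, 25, 2)."""
    T = params.shape[0]
    trunk, neck, sh_r, sh_l, el_r, el_l, hip_r, hip_l, kn_r, kn_l = params.T
    xy = np.zeros((T, 25, 2))
    p8 = np.broadcast_to(ROOT_XY, (T, 2))
    xy[:, 8] = p8
    xy[:, 1] = p8 + 120.0 * _dir(trunk)
    head = trunk + neck
    xy[:, 0] = xy[:, 1] + 32.0 * _dir(head)
    xy[:, 15] = xy[:, 0] + 16.0 * _dir(head + 50)
    xy[:, 17] = xy[:, 15] + 18.0 * _dir(head + 85)
    xy[:, 16] = xy[:, 0] + 16.0 * _dir(head - 50)
    xy[:, 18] = xy[:, 16] + 18.0 * _dir(head - 85)
    xy[:, 2] = xy[:, 1] + 40.0 * _dir(trunk + 95)
    xy[:, 5] = xy[:, 1] + 40.0 * _dir(trunk - 95)
    ua_r = trunk + 180.0 - sh_r
    ua_l = trunk + 180.0 - sh_l
    xy[:, 3] = xy[:, 2] + 60.0 * _dir(ua_r)
    xy[:, 4] = xy[:, 3] + 55.0 * _dir(ua_r - el_r)
    xy[:, 6] = xy[:, 5] + 60.0 * _dir(ua_l)
    xy[:, 7] = xy[:, 6] + 55.0 * _dir(ua_l - el_l)
    xy[:, 9] = p8 + np.array([28.0, 0.0])
    xy[:, 12] = p8 + np.array([-28.0, 0.0])
    th_r = 180.0 + hip_r
    th_l = 180.0 + hip_l
    xy[:, 10] = xy[:, 9] + 95.0 * _dir(th_r)
    xy[:, 13] = xy[:, 12] + 95.0 * _dir(th_l)
    sk_r = th_r + kn_r
    sk_l = th_l + kn_l
    xy[:, 11] = xy[:, 10] + 90.0 * _dir(sk_r)
    xy[:, 14] = xy[:, 13] + 90.0 * _dir(sk_l)
    xy[:, 22] = xy[:, 11] + 32.0 * _dir(sk_r - 105)
    xy[:, 23] = xy[:, 22] + 16.0 * _dir(sk_r - 95)
    xy[:, 24] = xy[:, 11] + 16.0 * _dir(sk_r + 120)
    xy[:, 19] = xy[:, 14] + 32.0 * _dir(sk_l - 105)
    xy[:, 20] = xy[:, 19] + 16.0 * _dir(sk_l - 95)
    xy[:, 21] = xy[:, 14] + 16.0 * _dir(sk_l + 120)
    return xy


def _smooth_transitions(params: np.ndarray, width: int = 15) -> np.ndarray:
    """Triangular smoothing of the pose-parameter trajectories.

    Keeps motion continuous across action-segment boundaries (a human
    cannot teleport between poses); within-segment trajectories are
    already smooth and are only mildly attenuated.
    """
    if params.shape[0] <= width:
        return params
    kernel = np.concatenate([np.arange(1, width // 2 + 2),
                             np.arange(width // 2, 0, -1)]).astype(float)
    kernel /= kernel.sum()
    pad = len(kernel) // 2
    padded = np.pad(params, ((pad, pad), (0, 0)), mode="edge")
    out = np.empty_like(params)
    for j in range(params.shape[1]):
        out[:, j] = np.convolve(padded[:, j], kernel, mode="valid")
    return out


def generate_sequence(
    action_script: list[tuple[str, int]],
    fps: float = 50.0,
    noise_px: float = 0.0,
    seed: int = 0,
    cycle_frames: int = 150,
) -> tuple[SkeletonSequence, list[str]]:
    """Animate the figure through labelled segments; fully seeded.

    Parameters
    ----------
    action_script
        ``(label, duration_frames)`` segments; labels must be registered
        in :data:`ACTION_SCRIPTS`.
    noise_px
        Standard deviation of additive Gaussian coordinate noise.
    cycle_frames
        Frames per oscillation cycle of the parameter trajectories.

    Returns
    -------
    (sequence, labels)
        The sequence and the per-frame true label list.
    """
    if not action_script:
        raise ValueError("action_script must be non-empty")
    params_parts = []
    labels: list[str] = []
    for label, duration in action_script:
        if duration <= 0:
            raise ValueError(f"duration must be positive, got {duration}")
        if label not in ACTION_SCRIPTS:
            raise ValueError(
                f"unknown label {label!r}; known: {sorted(ACTION_SCRIPTS)}"
            )
        u = (np.arange(duration) % cycle_frames) / cycle_frames
        params_parts.append(ACTION_SCRIPTS[label](u))
        labels.extend([label] * duration)
    params = np.concatenate(params_parts)
    params = _smooth_transitions(params)
    xy = _forward_kinematics(params)
    if noise_px > 0:
        rng = np.random.default_rng(seed)
        xy = xy + rng.normal(scale=noise_px, size=xy.shape)
    data = np.concatenate([xy, np.full((*xy.shape[:2], 1), 0.9)], axis=2)
    return SkeletonSequence.from_array(data, fps=fps), labels


# ---------------------------------------------------------------------------
# corruption injection


@dataclass
class CorruptionLog:
    """Exact record of injected corruption; supports full restoration."""

    #: (frame position, keypoint id) -> true (x, y, conf)
    truth: dict[tuple[int, int], tuple[float, float, float]] = field(
        default_factory=dict
    )
    #: missing bursts: (group, start, length)
    missing_bursts: list[tuple[str, int, int]] = field(default_factory=list)
    #: misidentification events: (limb, start, length, magnitude, mode)
    misid_events: list[tuple[str, int, int, float, str]] = field(
        default_factory=list
    )
    #: frame positions whose true action label was flipped, with the flip
    label_flips: dict[int, tuple[str, str]] = field(default_factory=dict)

    def record(self, seq: SkeletonSequence, t: int, kp: int) -> None:
        if (t, kp) not in self.truth:
            self.truth[(t, kp)] = tuple(seq[t].keypoints[kp])

    def missing_frames(self) -> set[int]:
        out: set[int] = set()
        for _, start, length in self.missing_bursts:
            out.update(range(start, start + length))
        return out

    def misid_frames(self) -> set[int]:
        out: set[int] = set()
        for _, start, length, _, _ in self.misid_events:
            out.update(range(start, start + length))
        return out

    def restore(self, seq: SkeletonSequence) -> SkeletonSequence:
        """Undo the logged corruption, returning the original sequence."""
        out = seq.copy()
        for (t, kp), vals in self.truth.items():
            out[t].keypoints[kp] = vals
        return out

    def restore_labels(self, labels: list[str]) -> list[str]:
        out = list(labels)
        for t, (original, _) in self.label_flips.items():
            out[t] = original
        return out

    def apply_label_flips(self, labels: list[str]) -> list[str]:
        """Corrupted label list implied by the logged flips."""
        out = list(labels)
        for t, (_, flipped) in self.label_flips.items():
            out[t] = flipped
        return out


def inject_missing(
    seq: SkeletonSequence,
    target_rate: float,
    burst_len: int = 5,
    seed: int = 0,
    log: CorruptionLog | None = None,
    avoid_frames: set[int] | None = None,
) -> tuple[SkeletonSequence, CorruptionLog]:
    """Blank out keypoint groups in seeded bursts.

    Per joint group, bursts of ``burst_len`` frames are scheduled so the
    group's realized missing-frame rate matches ``target_rate`` up to
    burst rounding (within +/-10% relative on sequences of >= 1000
    frames). Groups share keypoints (e.g. the neck keypoint belongs to
    both trunk and neck), so scheduling is adaptive: frames a group
    already lost through a shared keypoint count toward its target.
    Absent keypoints get confidence 0 and coordinates (0, 0). Frames in
    ``avoid_frames`` are never blanked (used to keep occlusion bursts
    apart from misidentification events in fixtures).
    """
    if not 0.0 <= target_rate < 1.0:
        raise ValueError("target_rate must lie in [0, 1)")
    T = len(seq)
    if burst_len > T:
        raise ValueError(f"burst_len {burst_len} exceeds sequence length {T}")
    out = seq.copy()
    log = log or CorruptionLog()
    if target_rate == 0.0:
        return out, log
    rng = np.random.default_rng(seed)
    avoid = avoid_frames or set()
    blanked: dict[int, set[int]] = {}  # keypoint id -> frames blanked
    target_frames = int(round(target_rate * T))
    for group, kps in JOINT_GROUPS.items():
        existing: set[int] = set()
        for kp in kps:
            existing |= blanked.get(kp, set())
        need = target_frames - len(existing)
        n_bursts = int(round(need / burst_len)) if need > 0 else 0
        if n_bursts == 0:
            continue
        taken = set(existing)
        placed = 0
        for s in rng.permutation(T - burst_len + 1):
            span = set(range(int(s), int(s) + burst_len))
            if span & taken or span & avoid:
                continue
            taken |= span
            placed += 1
            log.missing_bursts.append((group, int(s), burst_len))
            for t in span:
                for kp in kps:
                    log.record(seq, t, kp)
                    out[t].keypoints[kp] = (0.0, 0.0, 0.0)
                    blanked.setdefault(kp, set()).add(t)
            if placed == n_bursts:
                break
    return out, log


def inject_misidentification(
    seq: SkeletonSequence,
    event_rate: float,
    mode: str = "limb_displace",
    magnitude: float = 0.6,
    seed: int = 0,
    duration: int = 5,
    rotation_deg: float = 55.0,
    labels: list[str] | None = None,
    flip_labels: bool = True,
    log: CorruptionLog | None = None,
    margin: int = 12,
) -> tuple[SkeletonSequence, CorruptionLog]:
    """Displace limbs in seeded events so link lengths are violated.

    Events cycle round-robin over the eight limb targets so each joint
    group receives comparable corruption. During an event the target
    keypoint is displaced by scaling its parent link by ``1 + magnitude``
    and rotating it by ``rotation_deg``; descendants are translated along
    (``limb_displace``) or swapped onto a mirrored phantom-figure limb
    (``second_figure_swap``). If ``labels`` is given and ``flip_labels``
    is set, the true label of event frames is flipped to a different
    label, emulating the action-feature disruption that accompanies
    misidentification; flips are recorded in the log.
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    if mode not in ("limb_displace", "second_figure_swap"):
        raise ValueError(f"unknown mode {mode!r}")
    if not 0.0 <= event_rate < 1.0:
        raise ValueError("event_rate must lie in [0, 1)")
    T = len(seq)
    out = seq.copy()
    log = log or CorruptionLog()
    if event_rate == 0.0:
        return out, log
    rng = np.random.default_rng(seed)
    n_events = max(1, int(round(event_rate * T / duration)))
    lo, hi = margin, T - margin - duration
    if hi <= lo:
        raise ValueError("sequence too short for the requested events")
    starts: list[int] = []
    for s in rng.permutation(np.arange(lo, hi + 1)):
        if all(abs(s - o) >= duration + 4 for o in starts):
            starts.append(int(s))
            if len(starts) == n_events:
                break
    starts.sort()
    theta = math.radians(rotation_deg)
    rot = np.array(
        [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
    )
    limb_names = list(LIMB_TARGETS)
    all_labels = sorted(set(labels)) if labels else []
    for k, start in enumerate(starts):
        limb = limb_names[k % len(limb_names)]
        kp, tail = LIMB_TARGETS[limb]
        parent = _PARENT[kp]
        log.misid_events.append((limb, start, duration, magnitude, mode))
        for t in range(start, start + duration):
            for j in (kp, *tail):
                log.record(seq, t, j)
            bone = seq[t].xy[kp] - seq[t].xy[parent]
            if mode == "limb_displace":
                new_bone = (1.0 + magnitude) * (rot @ bone)
            else:  # phantom second figure: mirrored limb, violated length
                new_bone = (1.0 + magnitude) * (rot @ (bone * np.array([-1.0, 1.0])))
            delta = (seq[t].xy[parent] + new_bone) - seq[t].xy[kp]
            out[t].keypoints[kp, :2] = seq[t].xy[kp] + delta
            for j in tail:
                out[t].keypoints[j, :2] = seq[t].xy[j] + delta
            if labels is not None and flip_labels and len(all_labels) > 1:
                if t not in log.label_flips:
                    original = labels[t]
                    others = [x for x in all_labels if x != original]
                    flipped = others[int(rng.integers(len(others)))]
                    log.label_flips[t] = (original, flipped)
    return out, log


def default_fixture(
    seed: int = 0,
    n_frames: int = 1000,
    noise_px: float = 0.2,
    missing_rate: float = 0.10,
    misid_rate: float = 0.05,
    confusion: float = 0.0,
) -> dict:
    """The standard two-label test fixture with retained ground truth.

    Returns a dict with the noise-free truth sequence, the observed
    (noisy) sequence, the corrupted sequence, true and corrupted labels,
    and the corruption log. Sized so the full pipeline runs in seconds.
    """
    from .actions import mock_classify

    half = n_frames // 2
    script = [("bend", half), ("lift", n_frames - half)]
    truth_seq, labels = generate_sequence(script, noise_px=0.0, seed=seed)
    observed, _ = generate_sequence(script, noise_px=noise_px, seed=seed)
    log = CorruptionLog()
    corrupted, log = inject_misidentification(
        observed, misid_rate, seed=seed + 1, labels=labels, log=log
    )
    corrupted_labels = log.apply_label_flips(labels)
    avoid = {
        t
        for f in log.misid_frames()
        for t in range(f - 2, f + 3)  # keep anchors around events clean
    }
    corrupted, log = inject_missing(
        corrupted, missing_rate, seed=seed + 2, log=log, avoid_frames=avoid
    )
    weights = mock_classify(corrupted_labels, confusion=confusion, seed=seed + 3)
    return {
        "truth": truth_seq,
        "observed": observed,
        "corrupted": corrupted,
        "labels": labels,
        "corrupted_labels": corrupted_labels,
        "weights": weights,
        "log": log,
    }
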