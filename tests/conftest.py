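"""Shared fixtures: toy topologies, hand-built frames, small sequences."""

from __future__ import annotations

import numpy as np
import pytest

from ergoskel.skeleton import SkeletonFrame, SkeletonSequence
from ergoskel.topology import N_KEYPOINTS, SkeletonTopology


def make_frame(index: int = 0, xy: np.ndarray | None = None, conf: float = 0.9):
    """A full 25-keypoint frame; defaults to a spread-out generic pose."""
    if xy is None:
        rng = np.random.default_rng(123)
        xy = rng.uniform(50, 500, size=(N_KEYPOINTS, 2))
    data = np.column_stack([xy, np.full(N_KEYPOINTS, conf)])
    return SkeletonFrame(index, data)


def neutral_pose_xy() -> np.ndarray:
    """An upright figure: vertical trunk/neck, hanging straight arms/legs."""
    xy = np.zeros((N_KEYPOINTS, 2))
    xy[8] = (400, 400)   # mid hip
    xy[1] = (400, 280)   # neck, straight above
    xy[0] = (400, 250)   # nose above neck
    xy[15], xy[16] = (390, 240), (410, 240)  # eyes
    xy[17], xy[18] = (382, 248), (418, 248)  # ears
    xy[2], xy[5] = (360, 280), (440, 280)    # shoulders
    xy[3], xy[6] = (360, 340), (440, 340)    # elbows straight below
    xy[4], xy[7] = (360, 395), (440, 395)    # wrists straight below
    xy[9], xy[12] = (372, 400), (428, 400)   # hips
    xy[10], xy[13] = (372, 495), (428, 495)  # knees straight below
    xy[11], xy[14] = (372, 585), (428, 585)  # ankles straight below
    xy[22], xy[23], xy[24] = (352, 595), (342, 597), (380, 595)  # right foot
    xy[19], xy[20], xy[21] = (448, 595), (458, 597), (420, 595)  # left foot
    return xy


@pytest.fixture
def neutral_frame() -> SkeletonFrame:
    return make_frame(0, neutral_pose_xy())


@pytest.fixture
def toy_topology() -> SkeletonTopology:
    """Two links sharing keypoint 0: (0->1), (0->2)."""
    return SkeletonTopology(links=((0, 1), (0, 2)))


def static_sequence(n: int, xy: np.ndarray | None = None, fps: float = 50.0):
    """n identical frames of a generic pose."""
    if xy is None:
        rng = np.random.default_rng(7)
        xy = rng.uniform(50, 500, size=(N_KEYPOINTS, 2))
    return SkeletonSequence([make_frame(i, xy.copy()) for i in range(n)], fps=fps)


def blank_frame(frame: SkeletonFrame, keypoint_ids) -> None:
    """Mark keypoints absent in place (coords (0,0), confidence 0)."""
    for k in keypoint_ids:
        frame.keypoints[k] = (0.0, 0.0, 0.0)
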