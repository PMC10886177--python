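"""Skeleton data model and kinematic-chain matrices.

A skeleton frame holds 25 image-space keypoints ``(x, y, confidence)``;
coordinates are pixels with y increasing downward, frame indices 0-based.
The kinematic chain of a frame is the 2xL matrix ``K`` of link (bone)
vectors; its Gram matrix ``psi = K.T @ K`` carries squared link lengths on
the diagonal and pairwise link dot products off it, and is invariant to
rigid motion of the figure. The temporal chain ``phi`` is the difference
of two Gram matrices across a frame interval: zero under rigid motion,
non-zero exactly when link lengths or inter-link geometry change — the
signal used to flag misidentified skeletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import N_KEYPOINTS, SkeletonTopology

#: Keypoints with confidence below this, or at exactly (0, 0), are "absent"
#: (the OpenPose convention for undetected points).
ABSENCE_CONF_THRESHOLD = 0.1

#: Confidence assigned to keypoints synthesized by interpolation, so
#: downstream consumers can tell measured from inferred points.
SYNTHESIZED_CONF = 0.5


class IncompleteFrameError(ValueError):
    """A required keypoint is absent from the frame."""

    def __init__(self, frame_index: int, missing_ids: set[int]):
        self.frame_index = frame_index
        self.missing_ids = set(missing_ids)
        super().__init__(
            f"frame {frame_index}: absent keypoints {sorted(self.missing_ids)}"
        )


@dataclass
class SkeletonFrame:
    """One time step: 25 keypoints as a (25, 3) float array of (x, y, conf)."""

    frame_index: int
    keypoints: np.ndarray

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        if self.keypoints.shape != (N_KEYPOINTS, 3):
            raise ValueError(
                f"keypoints must have shape ({N_KEYPOINTS}, 3), "
                f"got {self.keypoints.shape}"
            )
        conf = self.keypoints[:, 2]
        if np.any((conf < 0) | (conf > 1)):
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def xy(self) -> np.ndarray:
        return self.keypoints[:, :2]

    def absent_ids(self, conf_threshold: float = ABSENCE_CONF_THRESHOLD) -> set[int]:
        """Ids of absent keypoints per the absence convention."""
        conf = self.keypoints[:, 2]
        at_origin = (self.keypoints[:, 0] == 0.0) & (self.keypoints[:, 1] == 0.0)
        return set(np.flatnonzero((conf < conf_threshold) | at_origin).tolist())

    def copy(self) -> "SkeletonFrame":
        return SkeletonFrame(self.frame_index, self.keypoints.copy())


@dataclass
class SkeletonSequence:
    """Time-ordered skeleton frames sampled at ``fps`` frames per second."""

    frames: list[SkeletonFrame]
    fps: float = 50.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> SkeletonFrame:
        return self.frames[i]

    def stacked(self) -> np.ndarray:
        """All keypoints as a (T, 25, 3) array."""
        return np.stack([f.keypoints for f in self.frames])

    def frame_indices(self) -> np.ndarray:
        return np.array([f.frame_index for f in self.frames], dtype=np.intp)

    def copy(self) -> "SkeletonSequence":
        return SkeletonSequence([f.copy() for f in self.frames], fps=self.fps)

    @classmethod
    def from_array(
        cls, data: np.ndarray, fps: float = 50.0, start_index: int = 0
    ) -> "SkeletonSequence":
        """Build a sequence from a (T, 25, 3) array with consecutive indices."""
        data = np.asarray(data, dtype=float)
        return cls(
            [SkeletonFrame(start_index + t, data[t]) for t in range(data.shape[0])],
            fps=fps,
        )


@dataclass(frozen=True)
class ChainMatrices:
    """Link matrix K (2xL), Gram psi = K.T K (LxL) and temporal chain phi.

    ``interval`` is the frame interval the temporal chain was computed
    over; ``phi`` is None for a single-frame chain.
    """

    K: np.ndarray
    psi: np.ndarray
    phi: np.ndarray | None = None
    interval: int = 0

    link_lengths_sq: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "link_lengths_sq", np.diag(self.psi).copy())


def build_link_matrix(
    frame: SkeletonFrame,
    topology: SkeletonTopology,
    conf_threshold: float = ABSENCE_CONF_THRESHOLD,
) -> np.ndarray:
    """Stack link (child - parent) vectors into a 2xL matrix, in link order.

    Raises
    ------
    IncompleteFrameError
        If any keypoint referenced by the topology is absent; the error
        carries the offending keypoint ids.
    """
    required = topology.keypoint_ids
    absent = frame.absent_ids(conf_threshold) & required
    if absent:
        raise IncompleteFrameError(frame.frame_index, absent)
    xy = frame.xy
    return (xy[topology.children] - xy[topology.parents]).T.copy()


def gram(K: np.ndarray) -> np.ndarray:
    """Gram matrix ``K.T @ K`` of a 2xL link matrix.

    Diagonal entries are squared link lengths; off-diagonals are pairwise
    link dot products. Invariant to any 2D rotation of ``K``.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != 2:
        raise ValueError(f"K must be a 2xL matrix, got shape {K.shape}")
    psi = K.T @ K
    # enforce exact symmetry against floating-point drift
    return (psi + psi.T) / 2.0


def temporal_chain(K_t: np.ndarray, K_t_plus_i: np.ndarray, i: int = 1) -> ChainMatrices:
    """Temporal kinematic chain between two frames at interval ``i``.

    ``phi = gram(K_{t+i}) - gram(K_t)``; its diagonal is the change in
    squared link lengths, zero whenever the two frames are related by a
    rigid transform.
    """
    K_t = np.asarray(K_t, dtype=float)
    K_t_plus_i = np.asarray(K_t_plus_i, dtype=float)
    if K_t.shape != K_t_plus_i.shape:
        raise ValueError(
            f"link matrices must share shape, got {K_t.shape} vs {K_t_plus_i.shape}"
        )
    psi_t = gram(K_t)
    phi = gram(K_t_plus_i) - psi_t
    return ChainMatrices(K=K_t, psi=psi_t, phi=phi, interval=int(i))


def squared_link_lengths(
    data_xy: np.ndarray, topology: SkeletonTopology
) -> np.ndarray:
    """Vectorized squared link lengths for a (T, 25, 2) coordinate stack."""
    bones = data_xy[:, topology.children, :] - data_xy[:, topology.parents, :]
    return np.einsum("tlc,tlc->tl", bones, bones)
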