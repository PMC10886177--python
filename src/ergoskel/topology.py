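"""BODY_25 skeleton topology: keypoint names, link table, joint groups.

The 25-keypoint layout follows the OpenPose BODY_25 numbering (ids 0-24).
The link list is a fixed, versioned tree over those keypoints; its order
defines the column order of every kinematic-chain matrix in the package,
so it is shipped as a data file and must not be reordered between releases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources

import numpy as np

N_KEYPOINTS = 25

#: Joint groups used for per-joint reporting (missing rates, angle MAE).
#: Keys follow the conventional trunk / neck / per-side arm & leg breakdown.
JOINT_GROUPS: dict[str, tuple[int, ...]] = {
    "trunk": (1, 8),
    "neck": (0, 1),
    "upper_arm_r": (2, 3),
    "lower_arm_r": (3, 4),
    "upper_arm_l": (5, 6),
    "lower_arm_l": (6, 7),
    "leg_r": (9, 10, 11),
    "leg_l": (12, 13, 14),
}


@dataclass(frozen=True)
class SkeletonTopology:
    """An ordered, acyclic set of links (parent, child) over keypoint ids.

    Parameters
    ----------
    links
        Ordered (parent, child) keypoint-id pairs. Column ``j`` of every
        link matrix built from this topology corresponds to ``links[j]``.
    keypoint_names
        Optional display names, indexed by keypoint id.
    version
        Data-file version; bumped whenever the link order changes.
    """

    links: tuple[tuple[int, int], ...]
    keypoint_names: tuple[str, ...] = field(default=())
    version: int = 1

    def __post_init__(self) -> None:
        ids = {i for link in self.links for i in link}
        if any(i < 0 for i in ids):
            raise ValueError("keypoint ids must be non-negative")
        # acyclic + connected over the spanned keypoints: a tree has
        # exactly len(ids) - 1 edges and every child appears once.
        children = [c for _, c in self.links]
        if len(self.links) != len(ids) - 1 or len(set(children)) != len(children):
            raise ValueError("link list must form a tree (acyclic, connected)")

    @property
    def n_links(self) -> int:
        return len(self.links)

    @cached_property
    def parents(self) -> np.ndarray:
        """Parent keypoint id per link, in link order."""
        return np.array([p for p, _ in self.links], dtype=np.intp)

    @cached_property
    def children(self) -> np.ndarray:
        """Child keypoint id per link, in link order."""
        return np.array([c for _, c in self.links], dtype=np.intp)

    @cached_property
    def keypoint_ids(self) -> frozenset[int]:
        return frozenset(i for link in self.links for i in link)

    @cached_property
    def _child_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for p, c in self.links:
            out.setdefault(p, []).append(c)
        return out

    def descendants(self, keypoint_id: int) -> set[int]:
        """All keypoints strictly below ``keypoint_id`` in the tree."""
        out: set[int] = set()
        stack = list(self._child_map.get(keypoint_id, []))
        while stack:
            k = stack.pop()
            out.add(k)
            stack.extend(self._child_map.get(k, []))
        return out

    def links_touching(self, keypoint_ids: set[int]) -> list[int]:
        """Indices of links with at least one endpoint in ``keypoint_ids``."""
        return [
            j
            for j, (p, c) in enumerate(self.links)
            if p in keypoint_ids or c in keypoint_ids
        ]


def load_body25() -> SkeletonTopology:
    """Load the shipped BODY_25 topology (24 links over 25 keypoints)."""
    raw = json.loads(
        resources.files("ergoskel.data").joinpath("body25_topology.json").read_text()
    )
    return SkeletonTopology(
        links=tuple((int(p), int(c)) for p, c in raw["links"]),
        keypoint_names=tuple(raw["keypoint_names"]),
        version=int(raw["version"]),
    )


BODY25: SkeletonTopology = load_body25()
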