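"""Evaluation metrics: angle MAE, REBA accuracy, corruption rates.

Paired series are frame-aligned; entries unavailable in either series
(NaN) are excluded pairwise and the exclusion count is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discriminate import STATUS_MISIDENTIFIED, STATUS_MISSING, IntegrityReport
from .topology import JOINT_GROUPS


def _paired(a, b) -> tuple[np.ndarray, np.ndarray, int]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and aligned")
    if a.size == 0:
        raise ValueError("series must be non-empty")
    keep = ~(np.isnan(a) | np.isnan(b))
    if not keep.any():
        raise ValueError("no valid pairs after exclusion")
    return a[keep], b[keep], int((~keep).sum())


def mae(a, b) -> float:
    """Mean absolute difference between two aligned series (degrees)."""
    av, bv, _ = _paired(a, b)
    return float(np.abs(av - bv).mean())


def mae_with_exclusions(a, b) -> tuple[float, int]:
    """MAE plus the count of pairwise-excluded entries."""
    av, bv, excluded = _paired(a, b)
    return float(np.abs(av - bv).mean()), excluded


def reba_accuracy(scores, truth) -> float:
    """Percent of frames whose final REBA score matches the truth series."""
    sv, tv, _ = _paired(scores, truth)
    return float(100.0 * np.mean(sv == tv))


@dataclass
class CorruptionRates:
    """Per-joint-group missing rates plus one overall misidentification rate."""

    missing: dict[str, float]
    misidentification: float
    n_frames: int


def corruption_rates(
    reports: list[IntegrityReport],
    joint_groups: dict[str, tuple[int, ...]] | None = None,
) -> CorruptionRates:
    """Rates from integrity reports covering every frame.

    A joint group counts as missing in a frame when any of its keypoints
    is absent there. Misidentification is a single overall figure: flagged
    frames over total frames.
    """
    if not reports:
        raise ValueError("reports must be non-empty")
    joint_groups = joint_groups or JOINT_GROUPS
    T = len(reports)
    missing = {}
    for name, kps in joint_groups.items():
        kpset = set(kps)
        n = sum(
            1
            for r in reports
            if r.status == STATUS_MISSING and r.missing_ids & kpset
        )
        missing[name] = n / T
    n_mis = sum(1 for r in reports if r.status == STATUS_MISIDENTIFIED)
    return CorruptionRates(missing=missing, misidentification=n_mis / T, n_frames=T)
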