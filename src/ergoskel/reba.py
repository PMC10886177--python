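"""Joint angles from 2D keypoints and REBA scoring.

Eight joint angles are computed per frame: trunk, neck and upper-arm
angles measure deviation from the vertical through a synthetic reference
point anchored at the proximal joint (trunk/neck against the upward
vertical, upper arms against the downward vertical, matching the usual
flexion-from-vertical convention); leg and lower-arm angles are flexion,
i.e. 180 degrees minus the interior angle at the middle joint, so a
straight limb reads 0.

Scoring walks the published REBA tables (A: trunk/neck/legs + load,
B: arms/wrist + coupling, C + activity additions), shipped as a
checksummed data file. Twist/abduction/support modifiers cannot be read
from a 2D skeleton and are supplied manually through :class:`REBAConfig`.
The wrist angle is not computed; its score is held constant (1 by
default) and is configurable.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .skeleton import ABSENCE_CONF_THRESHOLD, SkeletonFrame

_TABLES_SHA256 = "88cdbcbb51e874e1507e45d4b04d8cf6f40afb6331c09251934dc2d15aa8d03a"

#: Canonical angle order used by arrays, CSVs and metrics.
ANGLE_NAMES: tuple[str, ...] = (
    "trunk",
    "neck",
    "leg_r",
    "leg_l",
    "upper_arm_r",
    "upper_arm_l",
    "lower_arm_r",
    "lower_arm_l",
)

RISK_LEVELS: tuple[tuple[int, int, int, str, str], ...] = (
    # (lo, hi, action_level, risk, suggestion)
    (1, 1, 0, "Negligible", "None necessary"),
    (2, 3, 1, "Low", "Maybe necessary"),
    (4, 7, 2, "Medium", "Necessary"),
    (8, 10, 3, "High", "Necessary soon"),
    (11, 15, 4, "Very high", "Necessary now"),
)


def _load_tables() -> dict:
    blob = resources.files("ergoskel.data").joinpath("reba_tables.json").read_bytes()
    digest = hashlib.sha256(blob).hexdigest()
    if digest != _TABLES_SHA256:
        raise RuntimeError(
            f"REBA tables checksum mismatch: {digest} != {_TABLES_SHA256}"
        )
    return json.loads(blob)


_tables = _load_tables()
TABLE_A = np.array(_tables["table_a"])  # [neck-1][trunk-1][legs-1]
TABLE_B = np.array(_tables["table_b"])  # [lower-1][upper-1][wrist-1]
TABLE_C = np.array(_tables["table_c"])  # [score_a-1][score_b-1]


class Coupling(str, Enum):
    good = "good"
    fair = "fair"
    poor = "poor"
    unacceptable = "unacceptable"


COUPLING_SCORE = {
    Coupling.good: 0,
    Coupling.fair: 1,
    Coupling.poor: 2,
    Coupling.unacceptable: 3,
}


class REBAConfig(BaseModel):
    """Manual REBA modifiers: load, coupling, activity, per-joint flags."""

    load_kg: float = Field(default=0.0, ge=0.0)
    shock: bool = False  # sudden/shock force buildup (+1 to load)
    coupling: Coupling = Coupling.good
    static: bool = False  # held > 1 min
    repeated: bool = False  # > 4x per minute
    rapid_change: bool = False  # large, rapid or unstable changes
    trunk_twist: bool = False  # twist or side-bend
    neck_twist: bool = False
    shoulder_raised: bool = False
    arm_abducted: bool = False
    arm_supported: bool = False  # leaning / gravity-assisted (-1)
    leg_raised: bool = False  # unilateral / unstable support
    wrist_score: int = Field(default=1, ge=1, le=3)
    #: angles below this (degrees) count as neutral for trunk binning
    neutral_tol: float = Field(default=5.0, ge=0.0)


@dataclass
class JointAngles:
    """The eight per-frame joint angles, degrees; NaN marks unavailable."""

    trunk: float
    neck: float
    leg_r: float
    leg_l: float
    upper_arm_r: float
    upper_arm_l: float
    lower_arm_r: float
    lower_arm_l: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in ANGLE_NAMES], dtype=float)

    def unavailable(self) -> list[str]:
        return [n for n in ANGLE_NAMES if math.isnan(getattr(self, n))]


@dataclass
class REBAResult:
    angles: JointAngles
    trunk_score: int
    neck_score: int
    legs_score: int
    upper_arm_score: int
    lower_arm_score: int
    wrist_score: int
    score_a: int
    score_b: int
    score_c: int
    final_score: int
    risk_level: str
    action_level: int
    suggestion: str
    side_used: str  # arm side feeding score B: "left" or "right"


def _vec_angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angle in degrees between stacked 2-vectors; NaN for zero vectors."""
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.einsum("...c,...c->...", u, v) / (nu * nv)
        cos = np.where((nu == 0) | (nv == 0), np.nan, cos)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def angles_table(
    data: np.ndarray, conf_threshold: float = ABSENCE_CONF_THRESHOLD
) -> np.ndarray:
    """All eight joint angles for a (T, 25, 3) stack -> (T, 8), NaN-marked.

    Image coordinates have y increasing downward; "up" is (0, -1).
    """
    data = np.asarray(data, dtype=float)
    squeeze = data.ndim == 2
    if squeeze:
        data = data[None]
    xy = data[:, :, :2]
    absent = (data[:, :, 2] < conf_threshold) | (
        (data[:, :, 0] == 0.0) & (data[:, :, 1] == 0.0)
    )
    T = data.shape[0]
    up = np.broadcast_to(np.array([0.0, -1.0]), (T, 2))
    down = -up

    def seg(a: int, b: int) -> np.ndarray:
        return xy[:, b] - xy[:, a]

    def need(*kps: int) -> np.ndarray:
        return ~np.any(absent[:, list(kps)], axis=1)

    out = np.full((T, len(ANGLE_NAMES)), np.nan)
    # vertical-referenced angles
    out[:, 0] = np.where(need(1, 8), _vec_angle_deg(seg(8, 1), up), np.nan)
    out[:, 1] = np.where(need(0, 1), _vec_angle_deg(seg(1, 0), up), np.nan)
    out[:, 4] = np.where(need(2, 3), _vec_angle_deg(seg(2, 3), down), np.nan)
    out[:, 5] = np.where(need(5, 6), _vec_angle_deg(seg(5, 6), down), np.nan)
    # flexion angles: 180 - interior angle at the middle joint
    out[:, 2] = np.where(
        need(9, 10, 11), 180.0 - _vec_angle_deg(seg(10, 9), seg(10, 11)), np.nan
    )
    out[:, 3] = np.where(
        need(12, 13, 14), 180.0 - _vec_angle_deg(seg(13, 12), seg(13, 14)), np.nan
    )
    out[:, 6] = np.where(
        need(2, 3, 4), 180.0 - _vec_angle_deg(seg(3, 2), seg(3, 4)), np.nan
    )
    out[:, 7] = np.where(
        need(5, 6, 7), 180.0 - _vec_angle_deg(seg(6, 5), seg(6, 7)), np.nan
    )
    return out[0] if squeeze else out


def joint_angles(
    frame: SkeletonFrame, conf_threshold: float = ABSENCE_CONF_THRESHOLD
) -> JointAngles:
    """The eight joint angles of one frame (NaN marks unavailable)."""
    vals = angles_table(frame.keypoints, conf_threshold)
    return JointAngles(*(float(v) for v in vals))


# ---------------------------------------------------------------------------
# angle binning

def trunk_bin(angle: float, twist: bool, neutral_tol: float = 5.0) -> int:
    if angle <= neutral_tol:
        b = 1
    elif angle <= 20:
        b = 2
    elif angle <= 60:
        b = 3
    else:
        b = 4
    return min(b + int(twist), 5)


def neck_bin(angle: float, twist: bool) -> int:
    b = 1 if angle <= 20 else 2
    return min(b + int(twist), 3)


def legs_bin(knee_flexion: float, leg_raised: bool) -> int:
    b = 2 if leg_raised else 1
    if 30 <= knee_flexion < 60:
        b += 1
    elif knee_flexion >= 60:
        b += 2
    return min(b, 4)


def upper_arm_bin(
    angle: float, raised: bool, abducted: bool, supported: bool
) -> int:
    if angle <= 20:
        b = 1
    elif angle <= 45:
        b = 2
    elif angle <= 90:
        b = 3
    else:
        b = 4
    b += int(raised) + int(abducted) - int(supported)
    return int(np.clip(b, 1, 6))


def lower_arm_bin(angle: float) -> int:
    return 1 if 60 <= angle <= 100 else 2


def load_score(load_kg: float, shock: bool) -> int:
    if load_kg < 5:
        s = 0
    elif load_kg <= 10:
        s = 1
    else:
        s = 2
    return min(s + int(shock), 3)


# ---------------------------------------------------------------------------
# table walk

def score_from_bins(
    trunk: int,
    neck: int,
    legs: int,
    upper_arm: int,
    lower_arm: int,
    wrist: int,
    load: int = 0,
    coupling: int = 0,
    activity: int = 0,
) -> tuple[int, int, int, int]:
    """Deterministic lookup through tables A, B and C.

    Returns ``(score_a, score_b, score_c, final)`` where final is
    ``score_c`` plus the activity additions.
    """
    if not (1 <= trunk <= 5 and 1 <= neck <= 3 and 1 <= legs <= 4):
        raise ValueError("trunk/neck/legs bin out of range")
    if not (1 <= upper_arm <= 6 and 1 <= lower_arm <= 2 and 1 <= wrist <= 3):
        raise ValueError("arm/wrist bin out of range")
    if not (0 <= load <= 3 and 0 <= coupling <= 3 and 0 <= activity <= 3):
        raise ValueError("load/coupling/activity score out of range")
    score_a = int(TABLE_A[neck - 1, trunk - 1, legs - 1]) + load
    score_b = int(TABLE_B[lower_arm - 1, upper_arm - 1, wrist - 1]) + coupling
    score_c = int(TABLE_C[min(score_a, 12) - 1, min(score_b, 12) - 1])
    return score_a, score_b, score_c, score_c + activity


def risk_level(score: int) -> tuple[str, str, int]:
    """Risk category, correction suggestion and action level for a score."""
    if not 1 <= score <= 15:
        raise ValueError(f"REBA score must lie in [1, 15], got {score}")
    for lo, hi, action, risk, suggestion in RISK_LEVELS:
        if lo <= score <= hi:
            return risk, suggestion, action
    raise AssertionError("unreachable")  # bins cover [1, 15]


def reba_score(angles: JointAngles, config: REBAConfig | None = None) -> REBAResult:
    """Score one frame's angles through the REBA tables.

    Both arms are binned; score B is computed per side and the worse side
    is used (per-side scores are derivable from the returned bins and
    ``side_used``).
    """
    config = config or REBAConfig()
    missing = angles.unavailable()
    if missing:
        raise ValueError(f"angles unavailable: {missing}")

    t_bin = trunk_bin(angles.trunk, config.trunk_twist, config.neutral_tol)
    n_bin = neck_bin(angles.neck, config.neck_twist)
    l_bin = legs_bin(max(angles.leg_r, angles.leg_l), config.leg_raised)
    load = load_score(config.load_kg, config.shock)
    coup = COUPLING_SCORE[config.coupling]
    activity = int(config.static) + int(config.repeated) + int(config.rapid_change)

    sides = {}
    for side, ua, la in (
        ("right", angles.upper_arm_r, angles.lower_arm_r),
        ("left", angles.upper_arm_l, angles.lower_arm_l),
    ):
        ua_bin = upper_arm_bin(
            ua, config.shoulder_raised, config.arm_abducted, config.arm_supported
        )
        la_bin = lower_arm_bin(la)
        b = int(TABLE_B[la_bin - 1, ua_bin - 1, config.wrist_score - 1]) + coup
        sides[side] = (ua_bin, la_bin, b)
    # worse side feeds score B; ties resolved toward the higher bins, then right
    side_used = max(
        sides, key=lambda s: (sides[s][2], sides[s][0] + sides[s][1], s == "right")
    )
    ua_bin, la_bin, score_b = sides[side_used]

    score_a, _, score_c, final = score_from_bins(
        t_bin, n_bin, l_bin, ua_bin, la_bin, config.wrist_score,
        load=load, coupling=coup, activity=activity,
    )
    risk, suggestion, action = risk_level(final)
    return REBAResult(
        angles=angles,
        trunk_score=t_bin,
        neck_score=n_bin,
        legs_score=l_bin,
        upper_arm_score=ua_bin,
        lower_arm_score=la_bin,
        wrist_score=config.wrist_score,
        score_a=score_a,
        score_b=score_b,
        score_c=score_c,
        final_score=final,
        risk_level=risk,
        action_level=action,
        suggestion=suggestion,
        side_used=side_used,
    )


_SCORE_COLUMNS = (
    "trunk_score",
    "neck_score",
    "legs_score",
    "upper_arm_score",
    "lower_arm_score",
    "wrist_score",
    "score_a",
    "score_b",
    "score_c",
    "final_score",
)


def score_sequence(
    angles: np.ndarray,
    config: REBAConfig | None = None,
    frame_indices: np.ndarray | None = None,
) -> pd.DataFrame:
    """Score a (T, 8) angle table frame by frame into a tidy table.

    Frames with any unavailable angle get NaN scores and an empty risk
    label rather than raising, so partially-repaired sequences can still
    be tabulated.
    """
    config = config or REBAConfig()
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    T = angles.shape[0]
    if frame_indices is None:
        frame_indices = np.arange(T)
    rows = []
    for t in range(T):
        row: dict = {"frame": int(frame_indices[t])}
        row.update({f"angle_{n}": angles[t, j] for j, n in enumerate(ANGLE_NAMES)})
        if np.isnan(angles[t]).any():
            row.update({c: np.nan for c in _SCORE_COLUMNS})
            row["risk_level"] = ""
        else:
            res = reba_score(JointAngles(*angles[t]), config)
            row.update({c: getattr(res, c) for c in _SCORE_COLUMNS})
            row["risk_level"] = res.risk_level
        rows.append(row)
    return pd.DataFrame(rows)
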