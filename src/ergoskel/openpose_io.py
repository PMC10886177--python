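"""Readers and writers for the OpenPose BODY_25 per-frame JSON dialect.

The on-disk shape mirrors OpenPose output: each frame is an object with a
``people`` array whose entries carry a flat 75-value
``pose_keypoints_2d`` list (x, y, confidence for each of 25 keypoints).
A file may hold a single frame object, a list of frame objects, or an
object with a ``frames`` key. Multi-person frames are resolved by a
configured person index (association is out of scope). Coordinates are
serialized with fixed 3-decimal precision so write -> read round-trips
are bit-stable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .actions import ActionWeights
from .discriminate import IntegrityReport
from .skeleton import SkeletonFrame, SkeletonSequence
from .topology import N_KEYPOINTS


class OpenPoseParseError(ValueError):
    """Malformed OpenPose-dialect JSON; message names the frame."""


def _frame_from_record(record: dict, index: int, person_index: int) -> SkeletonFrame:
    people = record.get("people", [])
    frame_index = int(record.get("frame_index", index))
    if not people:
        # OpenPose emits an empty people array when nobody is detected
        return SkeletonFrame(frame_index, np.zeros((N_KEYPOINTS, 3)))
    if person_index >= len(people):
        raise OpenPoseParseError(
            f"frame {frame_index}: person index {person_index} out of range "
            f"({len(people)} people)"
        )
    flat = people[person_index].get("pose_keypoints_2d")
    if flat is None or len(flat) != N_KEYPOINTS * 3:
        n = "missing" if flat is None else len(flat)
        raise OpenPoseParseError(
            f"frame {frame_index}: pose_keypoints_2d must have "
            f"{N_KEYPOINTS * 3} values, got {n}"
        )
    return SkeletonFrame(frame_index, np.array(flat, dtype=float).reshape(-1, 3))


def read_openpose_json(
    path: str | Path, person_index: int = 0, fps: float = 50.0
) -> SkeletonSequence:
    """Parse an OpenPose-dialect JSON file into a skeleton sequence."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise OpenPoseParseError(f"{path}: malformed JSON: {exc}") from exc
    if isinstance(payload, dict) and "frames" in payload:
        fps = float(payload.get("fps", fps))
        records = payload["frames"]
    elif isinstance(payload, dict):
        records = [payload]
    elif isinstance(payload, list):
        records = payload
    else:
        raise OpenPoseParseError(f"{path}: unrecognized top-level JSON type")
    frames = [
        _frame_from_record(rec, i, person_index) for i, rec in enumerate(records)
    ]
    return SkeletonSequence(frames, fps=fps)


def write_openpose_json(seq: SkeletonSequence, path: str | Path) -> None:
    """Write a sequence in the same dialect, 3-decimal fixed precision."""
    records = []
    for frame in seq.frames:
        flat = [round(float(v), 3) for v in frame.keypoints.ravel()]
        records.append(
            {
                "frame_index": frame.frame_index,
                "people": [{"person_id": [-1], "pose_keypoints_2d": flat}],
            }
        )
    Path(path).write_text(
        json.dumps({"fps": seq.fps, "frames": records}, separators=(",", ":"))
    )


# --- sidecar formats -------------------------------------------------------


def write_actions_json(weights: list[ActionWeights], path: str | Path) -> None:
    labels = sorted(weights[0].weights) if weights else []
    payload = {
        "labels": labels,
        "frames": [
            {"frame_index": w.frame_index, "weights": w.weights} for w in weights
        ],
    }
    Path(path).write_text(json.dumps(payload, separators=(",", ":")))


def read_actions_json(path: str | Path) -> list[ActionWeights]:
    payload = json.loads(Path(path).read_text())
    return [
        ActionWeights(int(rec["frame_index"]), dict(rec["weights"]))
        for rec in payload["frames"]
    ]


def reports_to_frame(reports: list[IntegrityReport]) -> pd.DataFrame:
    """Integrity reports as a one-row-per-frame table."""
    return pd.DataFrame(
        {
            "frame": [r.frame_index for r in reports],
            "status": [r.status for r in reports],
            "missing_ids": [
                ";".join(map(str, sorted(r.missing_ids))) for r in reports
            ],
            "phi_diag_max_rel": [r.phi_diag_max_rel for r in reports],
            "heterogeneous": [r.heterogeneous for r in reports],
            "implicated_ids": [
                ";".join(map(str, sorted(r.implicated_ids))) for r in reports
            ],
        }
    )


def write_reports_csv(reports: list[IntegrityReport], path: str | Path) -> None:
    reports_to_frame(reports).to_csv(path, index=False)


def write_reports_jsonl(reports: list[IntegrityReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reports:
            fh.write(
                json.dumps(
                    {
                        "frame": r.frame_index,
                        "status": r.status,
                        "missing_ids": sorted(r.missing_ids),
                        "phi_diag_max_rel": r.phi_diag_max_rel,
                        "heterogeneous": r.heterogeneous,
                        "implicated_ids": sorted(r.implicated_ids),
                    }
                )
                + "\n"
            )
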