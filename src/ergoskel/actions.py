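"""Per-frame action-label weights and the deterministic mock classifier.

The repair pipeline only needs normalized per-frame weight vectors over
action labels; where they come from (a trained classifier, an external
file, or the mock below) is deliberately behind this small interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

WEIGHT_SUM_TOL = 1e-6


@dataclass
class ActionWeights:
    """Normalized weight vector over action labels for one frame."""

    frame_index: int
    weights: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()), dtype=float)
        if vals.size == 0:
            raise ValueError("weights must be non-empty")
        if np.any(vals < -WEIGHT_SUM_TOL):
            raise ValueError("weights must be non-negative")
        if abs(vals.sum() - 1.0) > WEIGHT_SUM_TOL:
            raise ValueError(f"weights must sum to 1, got {vals.sum()!r}")

    @property
    def argmax(self) -> str:
        """Highest-weighted label; ties broken by label sort order."""
        return max(sorted(self.weights), key=lambda k: self.weights[k])

    @staticmethod
    def one_hot(frame_index: int, label: str, labels: list[str]) -> "ActionWeights":
        return ActionWeights(
            frame_index, {lab: 1.0 if lab == label else 0.0 for lab in labels}
        )


def mock_classify(
    script: list[str],
    confusion: float = 0.0,
    seed: int = 0,
    labels: list[str] | None = None,
) -> list[ActionWeights]:
    """One-hot weights on the scripted label, with seeded label-flip noise.

    Each frame's true label is kept with probability ``1 - confusion`` and
    otherwise flipped to a uniformly random other label. Reproducible
    under ``seed``.
    """
    if not script:
        raise ValueError("script must be non-empty")
    if not 0.0 <= confusion < 1.0:
        raise ValueError("confusion must lie in [0, 1)")
    if labels is None:
        labels = sorted(set(script))
    unknown = set(script) - set(labels)
    if unknown:
        raise ValueError(f"unknown labels in script: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    out: list[ActionWeights] = []
    for t, true_label in enumerate(script):
        label = true_label
        if confusion > 0 and len(labels) > 1 and rng.random() < confusion:
            others = [lab for lab in labels if lab != true_label]
            label = others[rng.integers(len(others))]
        out.append(ActionWeights.one_hot(t, label, labels))
    return out


def argmax_labels(weights: list[ActionWeights]) -> list[str]:
    return [w.argmax for w in weights]
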