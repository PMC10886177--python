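"""Pipeline configuration and the end-to-end orchestration.

Stage order: discriminate -> compensate -> re-discriminate -> correct
(+ Kalman smoothing) -> joint angles -> REBA scores -> metrics. No stage
mutates its input; every stage's output is independently serializable so
a run can be resumed from any checkpoint.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .actions import ActionWeights
from .compensate import CompensateParams, CompensationResult, compensate_sequence
from .correct import CorrectionResult, CorrectParams, KalmanParams, correct_sequence
from .discriminate import DiscriminateParams, IntegrityReport, classify_sequence
from .metrics import CorruptionRates, corruption_rates
from .reba import REBAConfig, angles_table, score_sequence
from .skeleton import SkeletonSequence


class KalmanConfig(BaseModel):
    A: float = 1.0
    B: float = 0.0
    C: float = 1.0
    Q: float = Field(default=0.1, ge=0.0)
    R: float = Field(default=0.01, gt=0.0)
    P0: float = Field(default=1.0, ge=0.0)

    def to_params(self) -> KalmanParams:
        return KalmanParams(A=self.A, B=self.B, C=self.C, Q=self.Q, R=self.R, P0=self.P0)


class PipelineConfig(BaseModel):
    """All thresholds, spans and modifiers of one pipeline run."""

    absence_conf: float = 0.1
    tau: float = 0.2
    persistence: int = 2
    window: int = 10
    dominance: float = 0.60
    policy: str = "or"
    max_span: int = 10
    hold_boundary: bool = False
    smooth: bool = True
    kalman: KalmanConfig = Field(default_factory=KalmanConfig)
    reba: REBAConfig = Field(default_factory=REBAConfig)
    fps: float = 50.0
    seed: int = 0

    def discriminate_params(self) -> DiscriminateParams:
        return DiscriminateParams(
            absence_conf=self.absence_conf,
            tau=self.tau,
            persistence=self.persistence,
            window=self.window,
            dominance=self.dominance,
            policy=self.policy,
        )

    def compensate_params(self) -> CompensateParams:
        return CompensateParams(
            max_span=self.max_span, hold_boundary=self.hold_boundary
        )

    def correct_params(self) -> CorrectParams:
        return CorrectParams(
            window=self.window,
            dominance=self.dominance,
            smooth=self.smooth,
            kalman=self.kalman.to_params(),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix == ".toml":
            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        return cls.model_validate(data)


@dataclass
class PipelineResult:
    sequence: SkeletonSequence
    reports_initial: list[IntegrityReport]
    compensation: CompensationResult
    reports_compensated: list[IntegrityReport]
    correction: CorrectionResult
    weights: list[ActionWeights]
    angles: np.ndarray
    scores: pd.DataFrame
    rates_before: CorruptionRates
    rates_after: CorruptionRates
    summary: dict


def run_pipeline(
    seq: SkeletonSequence,
    weights: list[ActionWeights] | None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute the full repair-and-score pipeline on one sequence."""
    config = config or PipelineConfig()
    dparams = config.discriminate_params()

    reports0 = classify_sequence(seq, weights, dparams)
    rates_before = corruption_rates(reports0)

    comp = compensate_sequence(seq, reports0, config.compensate_params())

    reports1 = classify_sequence(comp.sequence, weights, dparams)

    if weights is None:
        # correction needs action weights; without them only smoothing runs
        from .correct import smooth_sequence

        smoothed = (
            smooth_sequence(comp.sequence, config.kalman.to_params())
            if config.smooth
            else comp.sequence
        )
        reports2 = classify_sequence(smoothed, None, dparams)
        corr = CorrectionResult(
            sequence=smoothed,
            reports=reports2,
            weights=[],
            misid_rate_after=corruption_rates(reports2).misidentification,
        )
    else:
        corr = correct_sequence(
            comp.sequence, reports1, weights, config.correct_params(), dparams
        )

    final_seq = corr.sequence
    rates_after = corruption_rates(corr.reports)
    angles = angles_table(final_seq.stacked(), config.absence_conf)
    scores = score_sequence(angles, config.reba, final_seq.frame_indices())

    summary = {
        "n_frames": len(seq),
        "missing_before": sum(1 for r in reports0 if r.status == "missing"),
        "misidentified_before": sum(
            1 for r in reports0 if r.status == "misidentified"
        ),
        "n_compensated": comp.n_compensated,
        "n_uncompensable": comp.n_uncompensable,
        "n_corrected": corr.n_corrected,
        "n_uncorrectable": corr.n_uncorrectable,
        "missing_after": sum(1 for r in corr.reports if r.status == "missing"),
        "misidentified_after": sum(
            1 for r in corr.reports if r.status == "misidentified"
        ),
        "misid_rate_before": rates_before.misidentification,
        "misid_rate_after": rates_after.misidentification,
        "mean_final_score": float(np.nanmean(scores["final_score"].to_numpy()))
        if len(scores)
        else float("nan"),
    }
    return PipelineResult(
        sequence=final_seq,
        reports_initial=reports0,
        compensation=comp,
        reports_compensated=reports1,
        correction=corr,
        weights=corr.weights if weights is not None else [],
        angles=angles,
        scores=scores,
        rates_before=rates_before,
        rates_after=rates_after,
        summary=summary,
    )


def write_run_manifest(config: PipelineConfig, path: str | Path) -> None:
    """Echo the full configuration (thresholds, seed) next to the outputs."""
    Path(path).write_text(config.model_dump_json(indent=2))
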