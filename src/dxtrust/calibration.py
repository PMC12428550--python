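"""Cost-sensitive calibration of per-transparency acceptance thresholds.

The acceptance thresholds were tuned on a development cohort so that
necessary overrides (of incorrect AI suggestions) were preserved without
unduly rejecting correct suggestions, with false acceptances penalized more
heavily than unnecessary overrides.  This module formalizes that tuning as
an exhaustive, deterministic grid search: for each transparency level
independently, every candidate threshold on a fixed grid is evaluated under
the asymmetric loss

    loss = c_FA * #(accepted & incorrect) + c_OV * #(overridden & correct)

and the minimizer is returned, with ties broken toward the higher (more
conservative) threshold.  Default costs are 2:1 — the direction of the
asymmetry is a clinical-risk statement; the magnitude is a package default.

Score components and gates do not depend on the threshold, so each case's
composite score is computed once and the whole loss curve follows by
vectorized comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .decision import (
    CaseRecord,
    Reason,
    TransparencyLevel,
    TransparencyProfile,
    decide,
    default_profiles,
)
from .similarity import diagnosis_similarity

__all__ = [
    "CalibrationConfig",
    "LabeledCase",
    "CalibrationResult",
    "decision_loss",
    "calibrate_thresholds",
    "similarity_correctness_rule",
]


@dataclass(frozen=True)
class CalibrationConfig:
    """Grid and costs for the threshold search.

    The default grid spans [0.30, 0.95] in steps of 0.01 — wide enough to
    bracket every deployed threshold.  ``cost_false_accept`` must be at
    least ``cost_unnecessary_override``; both must be positive.
    """

    grid_start: float = 0.30
    grid_stop: float = 0.95
    grid_step: float = 0.01
    cost_false_accept: float = 2.0
    cost_unnecessary_override: float = 1.0
    gate_mode: str = "hard"
    conf_norm: str = "affine"

    def __post_init__(self) -> None:
        if not (0.0 < self.grid_start <= self.grid_stop < 1.0):
            raise ValueError("threshold grid must lie within (0, 1)")
        if self.grid_step <= 0:
            raise ValueError("grid step must be positive")
        if self.cost_unnecessary_override <= 0:
            raise ValueError("costs must be positive")
        if self.cost_false_accept < self.cost_unnecessary_override:
            raise ValueError(
                "false acceptances must cost at least as much as "
                "unnecessary overrides"
            )

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return np.round(
            self.grid_start + self.grid_step * np.arange(n), decimals=10
        )


@dataclass(frozen=True)
class LabeledCase:
    """A case record together with its correctness label (1 = AI correct).

    ``correct`` may be None for unlabeled data; such cases can be scored
    but not used for calibration until a correctness rule labels them.
    """

    case: CaseRecord
    correct: Optional[int]

    def __post_init__(self) -> None:
        if self.correct not in (0, 1, None):
            raise ValueError("correctness label must be 0, 1 or None")


def similarity_correctness_rule(
    case: CaseRecord,
    threshold: float = 0.5,
    backend: str = "token-cosine",
) -> int:
    """Default correctness rule for unlabeled data.

    An AI diagnosis is deemed correct when its similarity to the reference
    (exact-match short-circuit included) reaches ``threshold``.  Synthetic
    cohorts carry a latent label instead and never need this rule.
    """
    sim = case.similarity_override
    if sim is None:
        sim = diagnosis_similarity(case.ai_dx, case.human_dx, backend)
    return int(sim >= threshold)


def decision_loss(
    decisions: Sequence,
    labels: Sequence[int],
    config: Optional[CalibrationConfig] = None,
) -> float:
    """Asymmetric cost of a batch of decisions against correctness labels.

    loss = c_FA * #(accepted & incorrect) + c_OV * #(overridden & correct).
    Zero iff every incorrect case was overridden and every correct case
    accepted.
    """
    config = config or CalibrationConfig()
    if len(decisions) != len(labels):
        raise ValueError(
            f"{len(decisions)} decisions vs {len(labels)} labels"
        )
    fa = sum(
        1 for d, y in zip(decisions, labels) if d.override == 0 and y == 0
    )
    ov = sum(
        1 for d, y in zip(decisions, labels) if d.override == 1 and y == 1
    )
    return config.cost_false_accept * fa + config.cost_unnecessary_override * ov


@dataclass(frozen=True)
class CalibrationResult:
    """Per-level calibrated thresholds with the full loss curves for audit."""

    thresholds: Dict[TransparencyLevel, float]
    curves: Dict[TransparencyLevel, pd.DataFrame]  # threshold, fa, ov, loss

    def report(self) -> pd.DataFrame:
        frames = []
        for level, curve in self.curves.items():
            frame = curve.copy()
            frame.insert(0, "level", level.name)
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)


def calibrate_thresholds(
    cases: Sequence[LabeledCase],
    profiles: Optional[Mapping[TransparencyLevel, TransparencyProfile]] = None,
    config: Optional[CalibrationConfig] = None,
) -> CalibrationResult:
    """Grid-search the loss-minimizing threshold per transparency level.

    Each level is calibrated independently on its own cases.  Cases whose
    gates fire are overridden at every threshold and contribute a constant
    to the curve.  Ties are broken toward the higher threshold.  Levels
    with no cases are omitted with a warning.
    """
    profiles = default_profiles() if profiles is None else profiles
    config = config or CalibrationConfig()
    grid = config.grid()

    by_level: Dict[TransparencyLevel, List[Tuple[float, bool, int]]] = {}
    for lc in cases:
        if lc.correct is None:
            raise ValueError(
                f"case {lc.case.case_id} has no correctness label; apply a "
                "correctness rule before calibrating"
            )
        d = decide(
            lc.case,
            profiles=profiles,
            gate_mode=config.gate_mode,
            conf_norm=config.conf_norm,
        )
        gated = d.reason in (
            Reason.LOW_CONFIDENCE_GATE,
            Reason.LOW_SIMILARITY_GATE,
        )
        by_level.setdefault(lc.case.transparency, []).append(
            (d.breakdown.s_final, gated, lc.correct)
        )

    thresholds: Dict[TransparencyLevel, float] = {}
    curves: Dict[TransparencyLevel, pd.DataFrame] = {}
    for level in profiles:
        entries = by_level.get(level)
        if not entries:
            warnings.warn(
                f"no cases at transparency level {level.name}; omitted",
                stacklevel=2,
            )
            continue
        scores = np.array([e[0] for e in entries])
        gated = np.array([e[1] for e in entries])
        correct = np.array([e[2] for e in entries], dtype=bool)

        # accepted at threshold t  <=>  not gated and score >= t; the small
        # tolerance keeps scores that are analytically equal to a grid
        # threshold from flipping on floating-point rounding
        accepted = (~gated)[None, :] & (
            scores[None, :] >= grid[:, None] - 1e-9
        )
        fa = (accepted & ~correct[None, :]).sum(axis=1)
        ov = (~accepted & correct[None, :]).sum(axis=1)
        loss = (
            config.cost_false_accept * fa
            + config.cost_unnecessary_override * ov
        )
        # ties toward the higher (more conservative) threshold
        best = len(loss) - 1 - int(np.argmin(loss[::-1]))
        thresholds[level] = float(grid[best])
        curves[level] = pd.DataFrame(
            {
                "threshold": grid,
                "false_accepts": fa,
                "unnecessary_overrides": ov,
                "loss": loss.astype(float),
            }
        )
    if not thresholds:
        raise ValueError("no transparency level had any cases to calibrate on")
    return CalibrationResult(thresholds=thresholds, curves=curves)
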