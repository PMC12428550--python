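"""Composite trust score and override decision rule.

An AI-generated diagnosis is accepted or overridden based on a composite
trust score

    S_final = wc * S_conf + ws * S_sim + wl * S_len

where S_conf is the model's stated confidence normalized into [0.5, 1.0],
S_sim is the diagnosis-similarity score in [0, 1], and S_len is a binary
length prior (1.0 for diagnoses of 30-100 characters, 0.7 otherwise).  The
weights (wc, ws, wl) and the acceptance threshold are conditioned on the
model's self-rated transparency level; weaker explanations tighten the bar.
The decision rule is

    override = 1  if S_final < threshold,   0 otherwise,

so a score exactly at the threshold is accepted.  Two gates dominate the
score: confidence below 70% always forces an override (transparency never
acts as an independent factor), and, in the default "hard" gate mode, a
similarity below the 0.10 cut-point forces an override as a text-quality
constraint.  The alternative "clamp" mode instead floors S_sim at 0.10 and
lets the weighted sum decide.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .similarity import SimilarityBackend, diagnosis_similarity

__all__ = [
    "TransparencyLevel",
    "TransparencyProfile",
    "CaseRecord",
    "ScoreBreakdown",
    "OverrideDecision",
    "Gate",
    "Reason",
    "default_profiles",
    "normalize_confidence",
    "length_score",
    "final_score",
    "decide",
    "batch_decide",
    "with_thresholds",
    "BatchError",
    "CONFIDENCE_FLOOR",
    "CONFIDENCE_CEIL",
    "SIMILARITY_CUT",
]

# Admissible stated-confidence band: below 70% the output is auto-overridden
# as unreliable; the generation protocol caps stated confidence at 99%.
CONFIDENCE_FLOOR = 70.0
CONFIDENCE_CEIL = 99.0

# Minimum similarity cut-point below which a diagnosis is treated as
# untrustworthy regardless of the other factors (hard gate mode).
SIMILARITY_CUT = 0.10


class TransparencyLevel(enum.Enum):
    """Model-self-rated explainability on a three-point ordinal scale."""

    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"

    @classmethod
    def from_label(cls, label: "str | TransparencyLevel") -> "TransparencyLevel":
        """Map a free-text transparency label onto the ordinal scale.

        Accepts the labels seen in model output: "Minimal" -> LOW,
        "Moderate" -> MODERATE, and "High" / "High Confidence" /
        "High Explainability + High Confidence" -> HIGH (case-insensitive).
        """
        if isinstance(label, cls):
            return label
        key = str(label).strip().lower()
        mapping = {
            "low": cls.LOW,
            "minimal": cls.LOW,
            "moderate": cls.MODERATE,
            "high": cls.HIGH,
            "high confidence": cls.HIGH,
            "high explainability": cls.HIGH,
            "high explainability + high confidence": cls.HIGH,
        }
        try:
            return mapping[key]
        except KeyError:
            raise ValueError(f"unrecognized transparency label {label!r}") from None


class Gate(enum.Flag):
    """Hard constraints that dominate the weighted score."""

    NONE = 0
    LOW_CONFIDENCE = enum.auto()
    LOW_SIMILARITY = enum.auto()


class Reason(enum.Enum):
    ACCEPTED = "accepted"
    BELOW_THRESHOLD = "below_threshold"
    LOW_CONFIDENCE_GATE = "low_confidence_gate"
    LOW_SIMILARITY_GATE = "low_similarity_gate"


@dataclass(frozen=True)
class TransparencyProfile:
    """Weights and acceptance threshold used at one transparency level."""

    level: TransparencyLevel
    wc: float
    ws: float
    wl: float
    threshold: float

    def __post_init__(self) -> None:
        if min(self.wc, self.ws, self.wl) < 0:
            raise ValueError("weights must be nonnegative")
        if abs(self.wc + self.ws + self.wl - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly in (0, 1)")


def default_profiles() -> Mapping[TransparencyLevel, TransparencyProfile]:
    """The deployed weight/threshold sets, one per transparency level.

    Confidence carries the largest weight everywhere; lower transparency
    raises the acceptance threshold (0.70 > 0.65 > 0.55) so weaker
    explanations demand a stronger composite score.
    """
    return {
        TransparencyLevel.HIGH: TransparencyProfile(
            TransparencyLevel.HIGH, wc=0.50, ws=0.30, wl=0.20, threshold=0.55
        ),
        TransparencyLevel.MODERATE: TransparencyProfile(
            TransparencyLevel.MODERATE, wc=0.60, ws=0.30, wl=0.10, threshold=0.65
        ),
        TransparencyLevel.LOW: TransparencyProfile(
            TransparencyLevel.LOW, wc=0.40, ws=0.50, wl=0.10, threshold=0.70
        ),
    }


@dataclass(frozen=True)
class CaseRecord:
    """One AI/human diagnosis pair with stated confidence and transparency."""

    case_id: str
    ai_dx: str
    human_dx: str
    confidence_pct: float
    transparency: TransparencyLevel
    similarity_override: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_pct <= 100.0:
            raise ValueError(
                f"case {self.case_id}: confidence {self.confidence_pct} "
                "outside [0, 100]"
            )
        if self.similarity_override is not None and not (
            0.0 <= self.similarity_override <= 1.0
        ):
            raise ValueError(
                f"case {self.case_id}: similarity {self.similarity_override} "
                "outside [0, 1]"
            )
        if not self.ai_dx.strip():
            raise ValueError(f"case {self.case_id}: AI diagnosis is empty")
        if not self.human_dx.strip() and self.similarity_override is None:
            raise ValueError(
                f"case {self.case_id}: reference diagnosis empty and no "
                "precomputed similarity supplied"
            )


@dataclass(frozen=True)
class ScoreBreakdown:
    """The components of one composite trust score."""

    s_conf: float
    s_sim: float
    s_len: float
    s_final: float
    profile: TransparencyProfile
    gates: Gate = Gate.NONE


@dataclass(frozen=True)
class OverrideDecision:
    case_id: str
    override: int
    reason: Reason
    breakdown: ScoreBreakdown
    case: Optional[CaseRecord] = None


# ---------------------------------------------------------------------------
# Score components
# ---------------------------------------------------------------------------

def normalize_confidence(confidence_pct: float, mode: str = "affine") -> float:
    """Map a stated confidence percentage onto the S_conf scale [0.5, 1.0].

    The default "affine" mode maps the admissible band [70, 99] linearly
    onto [0.5, 1.0], realizing both stated endpoints; the "fraction" mode
    (confidence/100 clamped into [0.5, 1.0]) is provided for sensitivity
    analysis.
    """
    c = float(confidence_pct)
    if mode == "affine":
        if not CONFIDENCE_FLOOR <= c <= CONFIDENCE_CEIL:
            raise ValueError(
                f"confidence {c} outside [{CONFIDENCE_FLOOR:g}, "
                f"{CONFIDENCE_CEIL:g}]; sub-70 confidences are handled by "
                "the override gate, not normalized"
            )
        return 0.5 + 0.5 * (c - CONFIDENCE_FLOOR) / (
            CONFIDENCE_CEIL - CONFIDENCE_FLOOR
        )
    if mode == "fraction":
        return min(1.0, max(0.5, c / 100.0))
    raise ValueError(f"unknown confidence normalization mode {mode!r}")


def length_score(ai_dx: str) -> float:
    """Length prior: 1.0 for 30-100 characters (inclusive), else 0.7.

    Measured on the trimmed, whitespace-collapsed surface string — the
    band describes the text a clinician reads, not the stemmed tokens.
    """
    collapsed = " ".join(ai_dx.split())
    if not collapsed:
        raise ValueError("cannot score the length of an empty diagnosis")
    return 1.0 if 30 <= len(collapsed) <= 100 else 0.7


def final_score(
    s_conf: float, s_sim: float, s_len: float, profile: TransparencyProfile
) -> float:
    """Weighted composite S_final = wc*S_conf + ws*S_sim + wl*S_len."""
    if not 0.5 <= s_conf <= 1.0:
        raise ValueError(f"s_conf {s_conf} outside [0.5, 1.0]")
    if not 0.0 <= s_sim <= 1.0:
        raise ValueError(f"s_sim {s_sim} outside [0, 1]")
    if s_len not in (0.7, 1.0):
        raise ValueError(f"s_len {s_len} not in {{0.7, 1.0}}")
    return profile.wc * s_conf + profile.ws * s_sim + profile.wl * s_len


# ---------------------------------------------------------------------------
# Decision rule
# ---------------------------------------------------------------------------

def decide(
    case: CaseRecord,
    profiles: Optional[Mapping[TransparencyLevel, TransparencyProfile]] = None,
    similarity: Optional[float] = None,
    backend: "SimilarityBackend | str | None" = None,
    gate_mode: str = "hard",
    conf_norm: str = "affine",
) -> OverrideDecision:
    """Score one case and return the override decision with full breakdown.

    Precedence: (a) confidence below 70% overrides immediately
    (LOW_CONFIDENCE_GATE) — no amount of similarity, length or transparency
    can rescue it; (b) in "hard" gate mode a similarity strictly below 0.10
    overrides (LOW_SIMILARITY_GATE); (c) otherwise the composite score is
    compared against the profile threshold, with equality accepting.

    ``similarity`` may be passed explicitly, carried on the case record, or
    computed from the diagnosis texts via ``backend``.
    """
    if gate_mode not in ("hard", "clamp"):
        raise ValueError(f"unknown gate mode {gate_mode!r}")
    profiles = default_profiles() if profiles is None else profiles
    try:
        profile = profiles[case.transparency]
    except KeyError:
        raise KeyError(
            f"no profile configured for transparency level {case.transparency}"
        ) from None

    if similarity is None:
        similarity = case.similarity_override
    if similarity is None:
        if backend is None:
            raise ValueError(
                f"case {case.case_id}: no similarity value and no backend to "
                "compute one"
            )
        similarity = diagnosis_similarity(case.ai_dx, case.human_dx, backend)
    if not 0.0 <= similarity <= 1.0:
        raise ValueError(f"similarity {similarity} outside [0, 1]")

    confidence = case.confidence_pct
    if confidence > CONFIDENCE_CEIL:
        warnings.warn(
            f"case {case.case_id}: confidence {confidence} above "
            f"{CONFIDENCE_CEIL:g}%, clamped",
            stacklevel=2,
        )
        confidence = CONFIDENCE_CEIL

    gates = Gate.NONE
    if case.confidence_pct < CONFIDENCE_FLOOR:
        gates |= Gate.LOW_CONFIDENCE
    if gate_mode == "hard" and similarity < SIMILARITY_CUT:
        gates |= Gate.LOW_SIMILARITY

    s_sim = similarity
    if gate_mode == "clamp":
        s_sim = max(similarity, SIMILARITY_CUT)

    # Breakdown is always populated, gated or not; a sub-70 confidence is
    # clamped to the band floor for the informational S_conf component.
    s_conf = normalize_confidence(max(confidence, CONFIDENCE_FLOOR), conf_norm)
    s_len = length_score(case.ai_dx)
    s_final = final_score(s_conf, s_sim, s_len, profile)
    breakdown = ScoreBreakdown(
        s_conf=s_conf,
        s_sim=s_sim,
        s_len=s_len,
        s_final=s_final,
        profile=profile,
        gates=gates,
    )

    if gates & Gate.LOW_CONFIDENCE:
        reason = Reason.LOW_CONFIDENCE_GATE
    elif gates & Gate.LOW_SIMILARITY:
        reason = Reason.LOW_SIMILARITY_GATE
    elif s_final < profile.threshold:
        reason = Reason.BELOW_THRESHOLD
    else:
        reason = Reason.ACCEPTED

    return OverrideDecision(
        case_id=case.case_id,
        override=0 if reason is Reason.ACCEPTED else 1,
        reason=reason,
        breakdown=breakdown,
        case=case,
    )


class BatchError(ValueError):
    """Raised in strict mode when one or more cases fail to score."""

    def __init__(self, failures: Sequence) -> None:
        self.failures = list(failures)
        ids = ", ".join(str(cid) for cid, _ in self.failures[:5])
        super().__init__(
            f"{len(self.failures)} case(s) failed to score (first: {ids})"
        )


def batch_decide(
    cases: Iterable[CaseRecord],
    profiles: Optional[Mapping[TransparencyLevel, TransparencyProfile]] = None,
    backend: "SimilarityBackend | str | None" = None,
    gate_mode: str = "hard",
    conf_norm: str = "affine",
    strict: bool = True,
    audit: Optional[Callable[[OverrideDecision], None]] = None,
) -> list:
    """Decide a sequence of cases, order-preserving.

    Equivalent to mapping :func:`decide` over the cases.  In strict mode
    (default) any invalid case aborts the batch with a :class:`BatchError`
    naming the failing case ids; in fail-soft mode failing cases are skipped
    and reported via warning, leaving the remainder unaffected.  ``audit``,
    when given, is invoked once per decision in order.
    """
    decisions: list = []
    failures: list = []
    for case in cases:
        try:
            d = decide(
                case,
                profiles=profiles,
                backend=backend,
                gate_mode=gate_mode,
                conf_norm=conf_norm,
            )
        except (ValueError, KeyError) as exc:
            failures.append((case.case_id, exc))
            continue
        decisions.append(d)
        if audit is not None:
            audit(d)
    if failures:
        if strict:
            raise BatchError(failures)
        for cid, exc in failures:
            warnings.warn(f"case {cid} skipped: {exc}", stacklevel=2)
    return decisions


def with_thresholds(
    profiles: Mapping[TransparencyLevel, TransparencyProfile],
    thresholds: Mapping[TransparencyLevel, float],
) -> Mapping[TransparencyLevel, TransparencyProfile]:
    """Return a profile mapping with thresholds replaced where given."""
    return {
        level: (
            replace(profile, threshold=thresholds[level])
            if level in thresholds
            else profile
        )
        for level, profile in profiles.items()
    }
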