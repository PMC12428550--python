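"""Synthetic cohorts and embedded reference tables.

The framework was evaluated on 6689 cardiovascular admissions whose clinical
notes cannot be redistributed, so two substitutes make every other module
testable offline:

* :func:`reference_tables` embeds the reference evaluation's stratum counts verbatim —
  the transparency contingency table, the per-confidence-range counts and
  the transparency x confidence interaction cells — as exact integer
  fixtures for the statistics layer.

* :func:`generate_cohort` draws a labeled synthetic cohort with the same
  stratified structure: fixed stratum sizes (transparency level x stated
  confidence range), a latent correctness indicator per case, similarity
  drawn from a Beta mixture in which correct cases stochastically dominate
  incorrect ones (Beta(8, 2) vs Beta(2, 6) by default), confidence sampled
  uniformly within the stratum's band, and diagnosis text pairs drawn from
  a cardiovascular vocabulary.  Correct cases pair the reference text with
  a lightly perturbed copy; incorrect cases pair it with a different
  condition.  Similarity is *generated*, not computed, so the cohort has a
  known ground truth; the emitted text pairs let the similarity module be
  exercised on the very same cases.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .calibration import LabeledCase
from .decision import CaseRecord, TransparencyLevel
from .stats import ContingencyTable, CONFIDENCE_RANGES

__all__ = [
    "SyntheticCohortConfig",
    "StratumSpec",
    "ReferenceTables",
    "generate_cohort",
    "reference_tables",
    "fixture_decisions",
    "FixtureDecision",
    "cvd_vocabulary",
    "default_config",
    "TABLE_STRATA",
]


# ---------------------------------------------------------------------------
# Cardiovascular vocabulary
# ---------------------------------------------------------------------------

# Condition families of the study cohort (ICD-9 chapters 390-459) plus the
# specific subtypes used to build the case list.
_CONDITIONS: Tuple[str, ...] = (
    "ischemic heart disease",
    "hypertension",
    "cerebrovascular disease",
    "valvular heart diseases",
    "other heart diseases",
    "heart failure",
    "arrhythmias",
    "cardiomyopathies",
    "hypertensive heart disease",
    "acute myocardial infarction",
    "atrial fibrillation",
    "aortic stenosis",
    "mitral regurgitation",
    "unstable angina",
    "dilated cardiomyopathy",
    "chronic systolic heart failure",
    "paroxysmal ventricular tachycardia",
)

# Qualifier templates chosen so the combined diagnosis lands in the
# 30-100-character band rewarded by the length prior.
_TEMPLATES: Tuple[str, ...] = (
    "acute exacerbation of {c} with secondary complications",
    "chronic {c} with preserved ejection fraction",
    "decompensated {c} requiring inpatient management",
    "newly diagnosed {c} confirmed on imaging",
    "{c} with associated volume overload",
    "recurrent {c} refractory to medical therapy",
)


def cvd_vocabulary(templated: bool = False) -> List[str]:
    """Cardiovascular diagnosis strings used by the generator.

    With ``templated=True``, each condition is expanded through qualifier
    templates so the resulting diagnoses fall within the 30-100-character
    length band; the bare condition names are always included first.
    """
    vocab = list(_CONDITIONS)
    if templated:
        vocab += [
            t.format(c=c) for c, t in itertools.product(_CONDITIONS, _TEMPLATES)
        ]
    return vocab


# ---------------------------------------------------------------------------
# Embedded reference tables (exact integer fixtures)
# ---------------------------------------------------------------------------

# Transparency contingency rows: (not overridden, overridden).
_TRANSPARENCY_ROWS: Tuple[Tuple[str, int, int], ...] = (
    ("Minimal", 41, 116),
    ("Moderate", 1676, 1631),
    ("High Confidence", 2745, 480),
)

# Per-confidence-range (overridden k, stratum n).  The high-confidence k is
# 40, the value consistent with the overall overridden total of 2227
# (147 + 2040 + 40) and the reported 1.7% rate.
_CONFIDENCE_COUNTS: Tuple[Tuple[str, int, int], ...] = (
    ("70-79", 147, 148),
    ("80-89", 2040, 4243),
    ("90-99", 40, 2298),
)

# Interaction cells: (level label, range, reported rate %, n, reported CI %).
# Overridden counts are those stated in the text where given (31/56,
# 1591/3182, 448/1059) and otherwise the integer matching the reported rate.
_INTERACTION_CELLS: Tuple[Tuple[str, str, float, int, int, Tuple[float, float]], ...] = (
    ("Minimal", "70-79", 100.0, 85, 85, (95.6, 100.0)),
    ("Minimal", "80-89", 55.4, 31, 56, (42.4, 67.6)),
    ("Minimal", "90-99", 0.0, 0, 16, (0.0, 19.4)),
    ("Moderate", "70-79", 98.4, 61, 62, (94.1, 100.0)),
    ("Moderate", "80-89", 49.9, 1591, 3182, (48.1, 51.6)),
    ("Moderate", "90-99", 7.7, 4, 51, (5.1, 15.4)),
    ("High Explainability + High Confidence", "70-79", 100.0, 1, 1, (20.6, 100.0)),
    ("High Explainability + High Confidence", "80-89", 42.3, 448, 1059, (39.4, 45.3)),
    ("High Explainability + High Confidence", "90-99", 1.4, 30, 2165, (1.0, 2.0)),
)


@dataclass(frozen=True)
class ReferenceTables:
    """Stratum counts of the reference cardiovascular evaluation.

    ``table3_observed`` is the transparency-level contingency table
    (total 6689, column totals 4462 / 2227); ``table4_counts`` maps each
    confidence range to its (overridden, total) pair; ``table5_cells`` maps
    (transparency label, range) to (reported rate %, overridden, n,
    reported CI %).  The interaction cells as reported total 6677, twelve
    short of the cohort — an internal inconsistency of the source tables
    that is preserved verbatim rather than repaired.
    """

    table3_observed: ContingencyTable
    table4_counts: Dict[str, Tuple[int, int]]
    table5_cells: Dict[Tuple[str, str], Tuple[float, int, int, Tuple[float, float]]]

    @property
    def total_cases(self) -> int:
        return self.table3_observed.total

    @property
    def total_overridden(self) -> int:
        return int(self.table3_observed.column_totals[1])


def reference_tables() -> ReferenceTables:
    """Return the embedded reference stratum counts."""
    table3 = ContingencyTable(
        row_labels=tuple(r[0] for r in _TRANSPARENCY_ROWS),
        counts=np.array([[r[1], r[2]] for r in _TRANSPARENCY_ROWS], dtype=np.int64),
    )
    table4 = {label: (k, n) for label, k, n in _CONFIDENCE_COUNTS}
    table5 = {
        (level, rng): (rate, k, n, ci)
        for level, rng, rate, k, n, ci in _INTERACTION_CELLS
    }
    return ReferenceTables(
        table3_observed=table3, table4_counts=table4, table5_cells=table5
    )


def fixture_decisions() -> List["FixtureDecision"]:
    """Expand the interaction cells into per-case binary override records.

    Each cell of the interaction grid becomes k overridden and n - k
    accepted pseudo-decisions labeled with its transparency level and
    confidence range — enough structure for contingency tabulation and
    post hoc comparisons on exactly the reference counts.
    """
    out: List[FixtureDecision] = []
    for level, rng, _rate, k, n, _ci in _INTERACTION_CELLS:
        out += [FixtureDecision(level, rng, 1)] * k
        out += [FixtureDecision(level, rng, 0)] * (n - k)
    return out


@dataclass(frozen=True)
class FixtureDecision:
    """Minimal decision record carrying only stratum labels and the outcome."""

    transparency_label: str
    confidence_range: str
    override: int


# ---------------------------------------------------------------------------
# Synthetic cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StratumSpec:
    """Size and latent-correctness probability of one cohort stratum."""

    level: TransparencyLevel
    confidence_range: str  # one of "70-79", "80-89", "90-99"
    n: int
    correct_prob: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("stratum size must be nonnegative")
        if not 0.0 <= self.correct_prob <= 1.0:
            raise ValueError("correctness probability outside [0, 1]")
        if self.confidence_range not in {r[0] for r in CONFIDENCE_RANGES}:
            raise ValueError(
                f"unknown confidence range {self.confidence_range!r}"
            )


# Default strata: the reference interaction-cell sizes, with the twelve
# cases unaccounted for by those cells assigned to the largest (moderate
# transparency, 80-89) cell so the transparency margins (157 / 3307 / 3225)
# and the cohort total of 6689 are honored.  Correctness probability is the
# complement of each cell's reference override propensity.
TABLE_STRATA: Tuple[StratumSpec, ...] = (
    StratumSpec(TransparencyLevel.LOW, "70-79", 85, 0.000),
    StratumSpec(TransparencyLevel.LOW, "80-89", 56, 0.446),
    StratumSpec(TransparencyLevel.LOW, "90-99", 16, 1.000),
    StratumSpec(TransparencyLevel.MODERATE, "70-79", 62, 0.016),
    StratumSpec(TransparencyLevel.MODERATE, "80-89", 3194, 0.501),
    StratumSpec(TransparencyLevel.MODERATE, "90-99", 51, 0.923),
    StratumSpec(TransparencyLevel.HIGH, "70-79", 1, 0.000),
    StratumSpec(TransparencyLevel.HIGH, "80-89", 1059, 0.577),
    StratumSpec(TransparencyLevel.HIGH, "90-99", 2165, 0.986),
)

_RANGE_BOUNDS: Dict[str, Tuple[int, int]] = {
    "70-79": (70, 79),
    "80-89": (80, 89),
    "90-99": (90, 99),
}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Conditions under which a synthetic cohort is drawn.

    ``strata`` fixes the exact per-stratum case counts (sizes are never
    sampled).  Similarity for correct cases is drawn from
    ``Beta(*beta_correct)`` and for incorrect cases from
    ``Beta(*beta_incorrect)``; the correct-case distribution must
    stochastically dominate the incorrect-case one (checked on the means
    a/(a+b)).  Confidence is a uniform integer within the stratum's band.
    """

    strata: Tuple[StratumSpec, ...] = TABLE_STRATA
    beta_correct: Tuple[float, float] = (8.0, 2.0)
    beta_incorrect: Tuple[float, float] = (2.0, 6.0)
    vocabulary: Tuple[str, ...] = field(
        default_factory=lambda: tuple(cvd_vocabulary(templated=True))
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for params in (self.beta_correct, self.beta_incorrect):
            if min(params) <= 0:
                raise ValueError("Beta parameters must be positive")
        mean_c = self.beta_correct[0] / sum(self.beta_correct)
        mean_i = self.beta_incorrect[0] / sum(self.beta_incorrect)
        if mean_c <= mean_i:
            raise ValueError(
                "correct-case similarity distribution must dominate the "
                "incorrect-case distribution"
            )
        if sum(s.n for s in self.strata) > 0 and not self.vocabulary:
            raise ValueError("empty vocabulary with nonzero stratum counts")

    @property
    def total(self) -> int:
        return sum(s.n for s in self.strata)


def default_config(seed: int = 0) -> SyntheticCohortConfig:
    """The study-structured default: reference stratum sizes and propensities."""
    return SyntheticCohortConfig(seed=seed)


def _perturb(text: str, rng: np.random.Generator) -> str:
    """Light token perturbation of a correct AI diagnosis.

    Either returns the text unchanged, prepends a hedging qualifier, or
    drops one non-leading token — the kinds of surface variation an
    LLM-paraphrased but correct diagnosis shows.
    """
    choice = rng.integers(0, 3)
    words = text.split()
    if choice == 1:
        return "probable " + text
    if choice == 2 and len(words) > 2:
        drop = int(rng.integers(1, len(words)))
        return " ".join(w for i, w in enumerate(words) if i != drop)
    return text


def generate_cohort(config: SyntheticCohortConfig) -> List[LabeledCase]:
    """Draw one labeled synthetic cohort.

    Produces exactly ``config.strata`` sizes per stratum, in stratum order;
    each case carries its latent correctness label, a generated similarity
    (stored on the record as the precomputed similarity), and a diagnosis
    text pair from the vocabulary.  Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    vocab = list(config.vocabulary)
    cases: List[LabeledCase] = []
    counter = 0
    for stratum in config.strata:
        lo, hi = _RANGE_BOUNDS[stratum.confidence_range]
        for _ in range(stratum.n):
            correct = bool(rng.random() < stratum.correct_prob)
            a, b = config.beta_correct if correct else config.beta_incorrect
            similarity = float(np.clip(rng.beta(a, b), 0.0, 1.0))
            confidence = int(rng.integers(lo, hi + 1))
            h_idx = int(rng.integers(0, len(vocab)))
            human_dx = vocab[h_idx]
            if correct:
                ai_dx = _perturb(human_dx, rng)
            else:
                offset = int(rng.integers(1, len(vocab))) if len(vocab) > 1 else 0
                ai_dx = vocab[(h_idx + offset) % len(vocab)]
            counter += 1
            record = CaseRecord(
                case_id=f"SYN-{counter:05d}",
                ai_dx=ai_dx,
                human_dx=human_dx,
                confidence_pct=float(confidence),
                transparency=stratum.level,
                similarity_override=similarity,
            )
            cases.append(LabeledCase(case=record, correct=int(correct)))
    return cases
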