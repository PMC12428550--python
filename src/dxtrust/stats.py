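"""Stratified override-rate statistics.

The primary acceptance measure for the decision framework is the override
rate — the fraction of AI diagnoses rejected — reported overall and within
strata defined by transparency level and stated-confidence range (70-79,
80-89, 90-99).  This module provides:

* per-stratum rates with Wilson score 95% confidence intervals,
* contingency tables of overridden vs. accepted counts per stratum,
* Pearson's chi-square test of independence (no continuity correction)
  with Cramer's V as the effect size,
* the transparency x confidence interaction grid, and
* pairwise post hoc comparisons between strata, by Tukey's HSD on the
  binary override indicator or by two-proportion z-tests with Holm
  adjustment.

Wilson intervals are used throughout: unlike the Wald interval they stay
inside [0, 1] and behave sensibly for the extreme cells (0% and 100%
override) that occur in the low- and high-confidence strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import (
    proportion_confint,
    proportions_ztest,
)

from .decision import OverrideDecision

__all__ = [
    "ContingencyTable",
    "RateEstimate",
    "Chi2Result",
    "PosthocComparison",
    "override_rate",
    "wilson_interval",
    "contingency_from_decisions",
    "chi2_independence",
    "cramers_v",
    "interaction_table",
    "pairwise_posthoc",
    "groups_from_decisions",
    "EvaluationReport",
    "evaluate_decision_frame",
    "confidence_range",
    "CONFIDENCE_RANGES",
    "transparency_stratifier",
    "confidence_stratifier",
]

NOT_OVERRIDDEN = "Not Overridden"
OVERRIDDEN = "Overridden"

#: The reporting bands for stated confidence, closed on both ends.
CONFIDENCE_RANGES: Tuple[Tuple[str, float, float], ...] = (
    ("70-79", 70.0, 80.0),
    ("80-89", 80.0, 90.0),
    ("90-99", 90.0, 100.0),
)


def confidence_range(confidence_pct: float) -> Optional[str]:
    """Band label for a stated confidence, or None outside [70, 100)."""
    for label, lo, hi in CONFIDENCE_RANGES:
        if lo <= confidence_pct < hi:
            return label
    return None


def transparency_stratifier(decision: OverrideDecision) -> str:
    if decision.case is None:
        raise ValueError(
            f"decision {decision.case_id} carries no case record to stratify"
        )
    return decision.case.transparency.name


def confidence_stratifier(decision: OverrideDecision) -> Optional[str]:
    if decision.case is None:
        raise ValueError(
            f"decision {decision.case_id} carries no case record to stratify"
        )
    return confidence_range(decision.case.confidence_pct)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateEstimate:
    """A stratum override proportion, optionally with a confidence interval."""

    k: int
    n: int
    rate: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    method: str = "point"

    @property
    def percent(self) -> float:
        return 100.0 * self.rate

    def render(self) -> str:
        """Render as a percent at one decimal with its CI at one decimal."""
        s = f"{self.percent:.1f}% ({self.k}/{self.n})"
        if self.ci_low is not None:
            s += f"; 95% CI: {100 * self.ci_low:.1f}-{100 * self.ci_high:.1f}%"
        return s


@dataclass(frozen=True)
class ContingencyTable:
    """Strata x (not overridden, overridden) counts with derived margins."""

    row_labels: Tuple[str, ...]
    counts: np.ndarray  # shape (rows, 2), nonnegative integers
    column_labels: Tuple[str, str] = (NOT_OVERRIDDEN, OVERRIDDEN)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.row_labels), 2):
            raise ValueError("counts must be a (rows, 2) array")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integral")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if counts.sum() == 0:
            raise ValueError("contingency table is empty")
        object.__setattr__(self, "counts", counts)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row(self, label: str) -> Tuple[int, int]:
        i = self.row_labels.index(label)
        return tuple(int(v) for v in self.counts[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.column_labels)
        )


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    cramers_v: float


@dataclass(frozen=True)
class PosthocComparison:
    group_a: str
    group_b: str
    mean_difference: float
    p_adjusted: float
    significant: bool
    method: str = "tukey-hsd"


# ---------------------------------------------------------------------------
# Rates and intervals
# ---------------------------------------------------------------------------

def override_rate(k: int, n: int) -> RateEstimate:
    """Point estimate k/n of the override proportion."""
    if n <= 0:
        raise ValueError("stratum size must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"override count {k} outside [0, {n}]")
    return RateEstimate(k=int(k), n=int(n), rate=k / n)


def wilson_interval(k: int, n: int, level: float = 0.95) -> RateEstimate:
    """Override proportion with its Wilson score confidence interval.

    The Wilson interval inverts the score test: with z the normal quantile
    for the requested coverage, the bounds are

        (p + z^2/2n +/- z*sqrt(p(1-p)/n + z^2/4n^2)) / (1 + z^2/n),

    clamped into [0, 1].  It always contains k/n.
    """
    base = override_rate(k, n)
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    # the analytic bounds at k = 0 and k = n are exactly 0 and 1
    if k == 0:
        lo = 0.0
    if k == n:
        hi = 1.0
    return RateEstimate(
        k=base.k,
        n=base.n,
        rate=base.rate,
        ci_low=float(np.clip(lo, 0.0, 1.0)),
        ci_high=float(np.clip(hi, 0.0, 1.0)),
        method="wilson",
    )


# ---------------------------------------------------------------------------
# Contingency tables and association
# ---------------------------------------------------------------------------

def contingency_from_decisions(
    decisions: Sequence[OverrideDecision],
    stratifier: Callable[[OverrideDecision], Optional[str]],
) -> ContingencyTable:
    """Tabulate overridden / not-overridden counts per stratum.

    Rows appear in order of first appearance; decisions for which the
    stratifier returns None (e.g. out-of-band confidence) are excluded.
    """
    if not decisions:
        raise ValueError("no decisions to tabulate")
    counts: Dict[str, List[int]] = {}
    for d in decisions:
        label = stratifier(d)
        if label is None:
            continue
        row = counts.setdefault(str(label), [0, 0])
        row[d.override] += 1
    if not counts:
        raise ValueError("no decisions fell into any stratum")
    labels = tuple(counts)
    return ContingencyTable(
        row_labels=labels,
        counts=np.array([counts[lbl] for lbl in labels], dtype=np.int64),
    )


def cramers_v(statistic: float, table: ContingencyTable) -> float:
    """Effect size sqrt(chi2 / (N * (min(rows, cols) - 1)))."""
    if statistic < 0:
        raise ValueError("chi-square statistic must be nonnegative")
    r, c = table.counts.shape
    return float(np.sqrt(statistic / (table.total * (min(r, c) - 1))))


def chi2_independence(table: ContingencyTable) -> Chi2Result:
    """Pearson chi-square test of independence, no continuity correction.

    Expected counts are E = row_total * col_total / N; their margins equal
    the observed margins exactly.  All expected counts must be positive.
    """
    if (table.row_totals == 0).any() or (table.column_totals == 0).any():
        raise ValueError("zero margin: chi-square test undefined")
    statistic, p_value, df, expected = sps.chi2_contingency(
        table.counts, correction=False
    )
    return Chi2Result(
        statistic=float(statistic),
        df=int(df),
        p_value=float(p_value),
        expected=np.asarray(expected),
        cramers_v=cramers_v(float(statistic), table),
    )


# ---------------------------------------------------------------------------
# Interaction grid
# ---------------------------------------------------------------------------

def interaction_table(
    decisions: Sequence[OverrideDecision],
    level: float = 0.95,
) -> Tuple[Dict[Tuple[str, str], RateEstimate], List[OverrideDecision]]:
    """Override rates per (transparency level, confidence range) cell.

    Returns the grid of Wilson-interval rate estimates plus the list of
    decisions whose confidence fell outside every reporting band (these are
    reported separately, never silently dropped).
    """
    cells: Dict[Tuple[str, str], List[int]] = {}
    out_of_band: List[OverrideDecision] = []
    for d in decisions:
        trans = transparency_stratifier(d)
        conf = confidence_stratifier(d)
        if conf is None:
            out_of_band.append(d)
            continue
        cell = cells.setdefault((trans, conf), [0, 0])
        cell[d.override] += 1
    grid = {
        key: wilson_interval(k=cell[1], n=cell[0] + cell[1], level=level)
        for key, cell in cells.items()
    }
    return grid, out_of_band


# ---------------------------------------------------------------------------
# Post hoc comparisons
# ---------------------------------------------------------------------------

def _holm_adjust(pvalues: Sequence[float]) -> List[float]:
    order = np.argsort(pvalues)
    m = len(pvalues)
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        adj = min(1.0, (m - rank) * pvalues[idx])
        running_max = max(running_max, adj)
        adjusted[idx] = running_max
    return adjusted.tolist()


def pairwise_posthoc(
    groups: Mapping[str, Sequence[int]],
    alpha: float = 0.05,
    method: str = "tukey-hsd",
) -> List[PosthocComparison]:
    """All pairwise comparisons of per-stratum override indicators.

    ``groups`` maps a stratum label to its binary override indicators
    (group mean = override proportion).  The default method is Tukey's
    honestly-significant-difference test at family-wise level ``alpha``;
    applying it to a binary response is unusual (variances are p(1-p), not
    homogeneous), so a two-proportion z-test with Holm adjustment is
    available as ``method="ztest"``.  Groups of size < 2 are excluded with
    a warning.  Mean differences are proportion differences (group A minus
    group B, in label order).
    """
    usable: Dict[str, np.ndarray] = {}
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            warnings.warn(
                f"group {label!r} has fewer than 2 observations; excluded",
                stacklevel=2,
            )
            continue
        usable[label] = arr
    if len(usable) < 2:
        raise ValueError("need at least two groups of size >= 2")
    labels = list(usable)

    results: List[PosthocComparison] = []
    if method == "tukey-hsd":
        res = sps.tukey_hsd(*[usable[lbl] for lbl in labels])
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                p = float(res.pvalue[i, j])
                results.append(
                    PosthocComparison(
                        group_a=labels[i],
                        group_b=labels[j],
                        mean_difference=float(
                            usable[labels[i]].mean() - usable[labels[j]].mean()
                        ),
                        p_adjusted=p,
                        significant=p < alpha,
                        method="tukey-hsd",
                    )
                )
        return results

    if method == "ztest":
        pairs = [
            (i, j)
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
        raw = []
        for i, j in pairs:
            a, b = usable[labels[i]], usable[labels[j]]
            count = np.array([a.sum(), b.sum()])
            nobs = np.array([a.size, b.size])
            if count.sum() in (0, nobs.sum()):
                raw.append(1.0)  # identical degenerate proportions
                continue
            _, p = proportions_ztest(count, nobs)
            raw.append(float(p))
        adjusted = _holm_adjust(raw)
        for (i, j), p in zip(pairs, adjusted):
            results.append(
                PosthocComparison(
                    group_a=labels[i],
                    group_b=labels[j],
                    mean_difference=float(
                        usable[labels[i]].mean() - usable[labels[j]].mean()
                    ),
                    p_adjusted=p,
                    significant=p < alpha,
                    method="ztest-holm",
                )
            )
        return results

    raise ValueError(f"unknown post hoc method {method!r}")


@dataclass(frozen=True)
class EvaluationReport:
    """Full stratified evaluation of a batch of override decisions."""

    overall: RateEstimate
    by_transparency: Dict[str, RateEstimate]
    by_confidence: Dict[str, RateEstimate]
    contingency: ContingencyTable
    chi2: Optional[Chi2Result]
    interaction: Dict[Tuple[str, str], RateEstimate]
    posthoc: List[PosthocComparison]
    notes: Tuple[str, ...] = ()


def evaluate_decision_frame(
    frame: pd.DataFrame,
    ci_level: float = 0.95,
    posthoc_method: str = "tukey-hsd",
) -> EvaluationReport:
    """Run the full stratified evaluation on a decisions table.

    ``frame`` needs columns ``override`` (0/1), ``transparency`` and,
    for the confidence analyses, ``confidence_range``.  Association tests
    are skipped (with a note) when only one transparency stratum is
    present.
    """
    if frame.empty:
        raise ValueError("no decisions to evaluate")
    for col in ("override", "transparency"):
        if col not in frame.columns:
            raise ValueError(f"decisions lack required column {col!r}")
    notes: List[str] = []
    overrides = frame["override"].astype(int)
    overall = wilson_interval(int(overrides.sum()), len(frame), ci_level)

    def _strata(by: str) -> Dict[str, RateEstimate]:
        out: Dict[str, RateEstimate] = {}
        for label, group in frame.groupby(by, sort=False):
            if str(label) == "":
                continue
            k = int(group["override"].astype(int).sum())
            out[str(label)] = wilson_interval(k, len(group), ci_level)
        return out

    by_transparency = _strata("transparency")
    has_ranges = "confidence_range" in frame.columns
    by_confidence = _strata("confidence_range") if has_ranges else {}
    if not has_ranges:
        notes.append("no confidence_range column; confidence analyses skipped")

    rows = [
        (label, est.n - est.k, est.k) for label, est in by_transparency.items()
    ]
    contingency = ContingencyTable(
        row_labels=tuple(r[0] for r in rows),
        counts=np.array([[r[1], r[2]] for r in rows], dtype=np.int64),
    )

    chi2: Optional[Chi2Result] = None
    posthoc: List[PosthocComparison] = []
    if len(by_transparency) >= 2:
        try:
            chi2 = chi2_independence(contingency)
        except ValueError as exc:
            notes.append(f"association test skipped: {exc}")
        groups = {
            label: frame.loc[
                frame["transparency"] == label, "override"
            ].astype(int).to_list()
            for label in by_transparency
        }
        usable = {k: v for k, v in groups.items() if len(v) >= 2}
        if len(usable) >= 2:
            posthoc = pairwise_posthoc(usable, method=posthoc_method)
    else:
        notes.append("single transparency stratum; association tests skipped")

    interaction: Dict[Tuple[str, str], RateEstimate] = {}
    if has_ranges:
        grouped = frame[frame["confidence_range"].astype(str) != ""].groupby(
            ["transparency", "confidence_range"], sort=False
        )
        for (trans, rng), group in grouped:
            k = int(group["override"].astype(int).sum())
            interaction[(str(trans), str(rng))] = wilson_interval(
                k, len(group), ci_level
            )

    return EvaluationReport(
        overall=overall,
        by_transparency=by_transparency,
        by_confidence=by_confidence,
        contingency=contingency,
        chi2=chi2,
        interaction=interaction,
        posthoc=posthoc,
        notes=tuple(notes),
    )


def groups_from_decisions(
    decisions: Sequence[OverrideDecision],
    stratifier: Callable[[OverrideDecision], Optional[str]],
) -> Dict[str, List[int]]:
    """Collect binary override indicators per stratum for post hoc tests."""
    groups: Dict[str, List[int]] = {}
    for d in decisions:
        label = stratifier(d)
        if label is None:
            continue
        groups.setdefault(str(label), []).append(d.override)
    return groups
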