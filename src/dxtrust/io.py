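"""Record file I/O, run configuration and audit logging.

Interchange format: UTF-8 delimited text (comma or tab) with a header row.
Case files carry ``case_id, ai_dx, human_dx, confidence_pct, transparency``
plus optional ``similarity`` and, for labeled cohorts, ``correct`` columns.
Decision files add ``override, reason, s_final`` (and the stratum labels)
so an evaluation can be rerun without rescoring.

Every scored case appends one line-delimited JSON audit record capturing
the model's confidence, transparency, similarity score, the applied
threshold, the composite score, any gates and the final decision, plus a
fingerprint of the effective configuration — the log a deployment would
keep for drift audits.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, IO, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .calibration import CalibrationConfig, LabeledCase
from .decision import (
    CaseRecord,
    Gate,
    OverrideDecision,
    TransparencyLevel,
    TransparencyProfile,
    default_profiles,
)
from .stats import confidence_range

__all__ = [
    "RunConfig",
    "AuditLog",
    "read_cases",
    "write_cases",
    "write_decisions",
    "read_decisions",
    "config_fingerprint",
]

CASE_COLUMNS = ["case_id", "ai_dx", "human_dx", "confidence_pct", "transparency"]
OPTIONAL_CASE_COLUMNS = ["similarity", "correct"]


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "profiles",
    "conf_norm",
    "gate_mode",
    "similarity_cut",
    "backend",
    "ci_level",
    "cost_false_accept",
    "cost_unnecessary_override",
    "seed",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated effective configuration for one run.

    Defaults mirror the deployed framework: the default per-transparency
    weights and thresholds, affine confidence normalization, the hard 0.10
    similarity gate, token-cosine similarity, 95% intervals and 2:1 costs.
    """

    profiles: Mapping[TransparencyLevel, TransparencyProfile] = field(
        default_factory=default_profiles
    )
    conf_norm: str = "affine"
    gate_mode: str = "hard"
    similarity_cut: float = 0.10
    backend: str = "token-cosine"
    ci_level: float = 0.95
    cost_false_accept: float = 2.0
    cost_unnecessary_override: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conf_norm not in ("affine", "fraction"):
            raise ValueError(f"unknown conf_norm {self.conf_norm!r}")
        if self.gate_mode not in ("hard", "clamp"):
            raise ValueError(f"unknown gate_mode {self.gate_mode!r}")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")

    def calibration_config(self) -> CalibrationConfig:
        return CalibrationConfig(
            cost_false_accept=self.cost_false_accept,
            cost_unnecessary_override=self.cost_unnecessary_override,
            gate_mode=self.gate_mode,
            conf_norm=self.conf_norm,
        )

    def to_dict(self) -> Dict:
        return {
            "profiles": {
                level.name: {
                    "wc": p.wc,
                    "ws": p.ws,
                    "wl": p.wl,
                    "threshold": p.threshold,
                }
                for level, p in sorted(
                    self.profiles.items(), key=lambda kv: kv[0].name
                )
            },
            "conf_norm": self.conf_norm,
            "gate_mode": self.gate_mode,
            "similarity_cut": self.similarity_cut,
            "backend": self.backend,
            "ci_level": self.ci_level,
            "cost_false_accept": self.cost_false_accept,
            "cost_unnecessary_override": self.cost_unnecessary_override,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "profiles" in kwargs:
            profiles = {}
            for name, spec in kwargs["profiles"].items():
                level = TransparencyLevel.from_label(name)
                profiles[level] = TransparencyProfile(
                    level=level,
                    wc=float(spec["wc"]),
                    ws=float(spec["ws"]),
                    wl=float(spec["wl"]),
                    threshold=float(spec["threshold"]),
                )
            kwargs["profiles"] = profiles
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)


def config_fingerprint(config: RunConfig) -> str:
    """Stable short hash of the effective configuration."""
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Case files
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_cases(path: "str | Path") -> List[LabeledCase]:
    """Read a delimited case file into labeled case records.

    Rows failing validation raise a ValueError naming the offending row
    number (1-based, excluding the header).  A missing or empty
    ``correct`` column is surfaced as None (unlabeled).
    """
    path = Path(path)
    frame = pd.read_csv(
        path, sep=_sep_for(path), dtype=str, keep_default_na=False, comment="#"
    )
    missing = [c for c in CASE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out: List[LabeledCase] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        data = row._asdict()
        try:
            similarity = None
            if data.get("similarity", "") != "":
                similarity = float(data["similarity"])
            case = CaseRecord(
                case_id=data["case_id"],
                ai_dx=data["ai_dx"],
                human_dx=data["human_dx"],
                confidence_pct=float(data["confidence_pct"]),
                transparency=TransparencyLevel.from_label(data["transparency"]),
                similarity_override=similarity,
            )
            correct = (
                int(data["correct"]) if data.get("correct", "") != "" else None
            )
            if correct not in (None, 0, 1):
                raise ValueError(f"correct label {correct} not binary")
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
        out.append(LabeledCase(case=case, correct=correct))
    return out


def write_cases(
    cases: Sequence, path: "str | Path", seed: Optional[int] = None
) -> None:
    """Write labeled or unlabeled cases in the standard schema."""
    path = Path(path)
    rows = []
    for lc in cases:
        case = lc.case
        rows.append(
            {
                "case_id": case.case_id,
                "ai_dx": case.ai_dx,
                "human_dx": case.human_dx,
                "confidence_pct": case.confidence_pct,
                "transparency": case.transparency.name,
                "similarity": (
                    "" if case.similarity_override is None
                    else case.similarity_override
                ),
                "correct": "" if lc.correct is None else int(lc.correct),
            }
        )
    frame = pd.DataFrame(
        rows, columns=CASE_COLUMNS[:5] + OPTIONAL_CASE_COLUMNS
    ) if rows else pd.DataFrame(columns=CASE_COLUMNS + OPTIONAL_CASE_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        frame.to_csv(fh, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Decision files
# ---------------------------------------------------------------------------

DECISION_COLUMNS = [
    "case_id",
    "override",
    "reason",
    "s_conf",
    "s_sim",
    "s_len",
    "s_final",
    "threshold",
    "gates",
    "transparency",
    "confidence_pct",
    "confidence_range",
]


def write_decisions(
    decisions: Sequence[OverrideDecision], path: "str | Path"
) -> None:
    path = Path(path)
    rows = []
    for d in decisions:
        b = d.breakdown
        rows.append(
            {
                "case_id": d.case_id,
                "override": d.override,
                "reason": d.reason.value,
                "s_conf": b.s_conf,
                "s_sim": b.s_sim,
                "s_len": b.s_len,
                "s_final": b.s_final,
                "threshold": b.profile.threshold,
                "gates": _gates_repr(b.gates),
                "transparency": b.profile.level.name,
                "confidence_pct": (
                    d.case.confidence_pct if d.case is not None else ""
                ),
                "confidence_range": (
                    confidence_range(d.case.confidence_pct) or ""
                    if d.case is not None
                    else ""
                ),
            }
        )
    frame = pd.DataFrame(rows, columns=DECISION_COLUMNS)
    frame.to_csv(path, sep=_sep_for(path), index=False)


def read_decisions(path: "str | Path") -> pd.DataFrame:
    """Read a decision file back as a DataFrame for evaluation."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), keep_default_na=False)
    missing = [c for c in ("override", "transparency") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return frame


def _gates_repr(gates: Gate) -> str:
    names = [g.name for g in Gate if g != Gate.NONE and g in gates]
    return "|".join(names)


# ---------------------------------------------------------------------------
# Audit log
# ---------------------------------------------------------------------------

class AuditLog:
    """Append-only line-delimited JSON log of override decisions."""

    def __init__(
        self,
        stream: IO[str],
        config: RunConfig,
        clock=None,
    ) -> None:
        self._stream = stream
        self._fingerprint = config_fingerprint(config)
        self._clock = clock or (lambda: datetime.now(timezone.utc).isoformat())

    def record(self, decision: OverrideDecision) -> None:
        b = decision.breakdown
        entry = {
            "timestamp": self._clock(),
            "case_id": decision.case_id,
            "confidence": (
                decision.case.confidence_pct if decision.case is not None else None
            ),
            "transparency": b.profile.level.name,
            "similarity": b.s_sim,
            "applied_threshold": b.profile.threshold,
            "s_final": b.s_final,
            "gates": _gates_repr(b.gates),
            "decision": "override" if decision.override else "accept",
            "reason": decision.reason.value,
            "config_fingerprint": self._fingerprint,
        }
        self._stream.write(json.dumps(entry, sort_keys=True) + "\n")
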