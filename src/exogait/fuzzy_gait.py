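"""Rule-based fuzzy gait-phase estimation from plantar FSR readings.

Six force-sensitive resistors — heel, first and fifth metatarsal of each
foot (LH, L1M, L5M, RH, R1M, R5M) — drive an eight-phase gait segmentation.
Raw readings are normalized by the sum of readings in scope (per foot by
default), each normalized reading is mapped by a sigmoid membership function

    mu(F*) = 1 / (1 + exp(-s * (F* - F0)))

to a "High" grade (with "Low" = 1 - mu), and every rule of an eight-row
rule base takes the minimum grade over its six High/Low conditions as the
membership grade of its gait phase.  The phase with the largest grade is
the classification; the sum of all eight grades serves as an internal
consistency check — values well below nominal suggest an abnormal loading
pattern, values well above it a conflicting one.

Normalizing by the in-scope sum rather than a fixed full-scale value makes
the segmentation robust to FSR saturation, drift and user-to-user weight
differences without per-user calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import yaml

__all__ = [
    "PLACEMENTS",
    "LEFT_PLACEMENTS",
    "RIGHT_PLACEMENTS",
    "PHASES",
    "FuzzyConfig",
    "FsrVector",
    "Rule",
    "RuleBase",
    "PhaseGrades",
    "FrameClassification",
    "normalize_fsr",
    "membership",
    "linguistic_grades",
    "evaluate_rules",
    "mirror_rules",
    "classify_sequence",
    "default_rules",
    "rules_eq5_variant",
    "load_rules_yaml",
    "dump_rules_yaml",
]

PLACEMENTS = ("LH", "L5M", "L1M", "RH", "R5M", "R1M")
LEFT_PLACEMENTS = ("LH", "L5M", "L1M")
RIGHT_PLACEMENTS = ("RH", "R5M", "R1M")
_MIRROR = {"LH": "RH", "L5M": "R5M", "L1M": "R1M",
           "RH": "LH", "R5M": "L5M", "R1M": "L1M"}

PHASES = (
    "Heel Strike",
    "Loading Response",
    "Mid-stance",
    "Terminal Stance",
    "Pre-swing",
    "Initial Swing",
    "Mid-Swing",
    "Terminal Swing",
)


@dataclass(frozen=True)
class FuzzyConfig:
    """Membership-function and normalization parameters.

    ``s`` is the sigmoid slope and ``f0`` the threshold at which the
    membership grade is exactly 0.5.  The defaults apply the sigmoid
    directly to the [0, 1] normalized readings; a percent-scale variant
    (``input_scale=100, f0=45``) yields near-crisp grades and a phase-grade
    sum near 1 — see :func:`FuzzyConfig.rescaled`.
    """

    s: float = 0.15
    f0: float = 0.45
    normalization_scope: str = "per_foot"  # or "global"
    input_scale: float = 1.0
    consistency_band: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError(f"sigmoid slope s must be positive, got {self.s}")
        if self.normalization_scope not in ("per_foot", "global"):
            raise ValueError(
                f"normalization_scope must be 'per_foot' or 'global', "
                f"got {self.normalization_scope!r}"
            )
        if self.input_scale <= 0:
            raise ValueError("input_scale must be positive")
        if not 0 < self.f0 < self.input_scale:
            raise ValueError(
                f"f0 must lie strictly inside (0, {self.input_scale}), got {self.f0}"
            )

    @classmethod
    def rescaled(cls, **kwargs) -> "FuzzyConfig":
        """Percent-scale configuration: normalized readings x100, f0=45."""
        defaults = dict(s=0.15, f0=45.0, input_scale=100.0)
        defaults.update(kwargs)
        return cls(**defaults)


@dataclass(frozen=True)
class FsrVector:
    """Raw and (optionally) normalized readings for the six FSR placements."""

    raw: dict[str, float]
    normalized: dict[str, float] | None = None

    def __post_init__(self) -> None:
        missing = [p for p in PLACEMENTS if p not in self.raw]
        if missing:
            raise ValueError(f"missing FSR placements: {missing}")
        for p in PLACEMENTS:
            v = self.raw[p]
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"raw FSR reading {p} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class Rule:
    """One fuzzy rule: a High/Low requirement per placement and an outcome."""

    conditions: dict[str, str]  # placement -> "High" | "Low"
    phase: str

    def __post_init__(self) -> None:
        missing = [p for p in PLACEMENTS if p not in self.conditions]
        if missing:
            raise ValueError(f"rule for {self.phase!r} missing placements: {missing}")
        bad = {p: v for p, v in self.conditions.items() if v not in ("High", "Low")}
        if bad:
            raise ValueError(f"conditions must be 'High' or 'Low', got {bad}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown gait phase {self.phase!r}")


@dataclass(frozen=True)
class RuleBase:
    """Exactly eight rules with distinct phase outcomes, for one side."""

    rules: tuple[Rule, ...]
    side: str = "right"

    def __post_init__(self) -> None:
        if len(self.rules) != 8:
            raise ValueError(f"rule base must contain exactly 8 rules, got {len(self.rules)}")
        outcomes = [r.phase for r in self.rules]
        if len(set(outcomes)) != 8:
            raise ValueError("rule outcomes must be distinct")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass(frozen=True)
class PhaseGrades:
    """Per-phase membership grades with the consistency sum and argmax."""

    grades: dict[str, float]
    consistency: float
    predicted_phase: str
    predicted_grade: float


@dataclass(frozen=True)
class FrameClassification:
    timestamp: float
    phase: str
    grade: float
    consistency: float
    flag: str  # "ok" | "abnormal" | "conflicting"


# Reference rule table (right-insole outcomes), one row per gait phase in
# cycle order.  Columns: LH, L5M, L1M, RH, R5M, R1M; H = High, L = Low.
_TABLE_ROWS: tuple[tuple[str, str], ...] = (
    ("LHHHLH", "Heel Strike"),
    ("LLHHHL", "Loading Response"),
    ("LLLHHH", "Mid-stance"),
    ("HLLLHH", "Terminal Stance"),
    ("HLLLLH", "Pre-swing"),
    ("HHHLHL", "Initial Swing"),
    ("HHHLLL", "Mid-Swing"),
    ("LHHLLL", "Terminal Swing"),
)


def _rules_from_rows(rows: Iterable[tuple[str, str]]) -> RuleBase:
    rules = []
    for pattern, phase in rows:
        conditions = {
            placement: ("High" if flag == "H" else "Low")
            for placement, flag in zip(PLACEMENTS, pattern)
        }
        rules.append(Rule(conditions=conditions, phase=phase))
    return RuleBase(rules=tuple(rules), side="right")


def default_rules() -> RuleBase:
    """The shipped eight-row rule base (right-insole outcomes)."""
    return _rules_from_rows(_TABLE_ROWS)


def rules_eq5_variant() -> RuleBase:
    """Alternate rule base whose Heel Strike row requires R1M Low.

    The logical-expression form of the heel-strike rule circulating with
    this rule family disagrees with the tabulated row on the right first
    metatarsal; both variants are shipped as configuration, neither is
    "corrected".
    """
    rows = (("LHHHLL", "Heel Strike"),) + _TABLE_ROWS[1:]
    return _rules_from_rows(rows)


def normalize_fsr(raw: FsrVector | Mapping[str, float], scope: str = "per_foot") -> FsrVector:
    """Scale readings by the sum of readings in scope.

    ``per_foot`` divides each foot's three readings by that foot's sum;
    ``global`` divides all six by the grand sum.  A zero scope sum (foot in
    swing, or no load at all) yields zeros for that scope, never NaN.
    """
    values = raw.raw if isinstance(raw, FsrVector) else dict(raw)
    vec = raw if isinstance(raw, FsrVector) else FsrVector(raw=values)
    if scope == "per_foot":
        groups: tuple[tuple[str, ...], ...] = (LEFT_PLACEMENTS, RIGHT_PLACEMENTS)
    elif scope == "global":
        groups = (PLACEMENTS,)
    else:
        raise ValueError(f"unknown normalization scope {scope!r}")
    normalized: dict[str, float] = {}
    for group in groups:
        total = sum(vec.raw[p] for p in group)
        for p in group:
            normalized[p] = vec.raw[p] / total if total > 0 else 0.0
    return replace(vec, normalized=normalized)


def membership(f_star: float, cfg: FuzzyConfig = FuzzyConfig()) -> float:
    """Sigmoid membership grade of a normalized reading being 'High'.

    Strictly increasing in the input and exactly 0.5 at the threshold f0.
    """
    if not math.isfinite(f_star):
        raise ValueError(f"normalized reading must be finite, got {f_star}")
    z = -cfg.s * (f_star - cfg.f0)
    if z > 700.0:  # exp would overflow; the grade is indistinguishable from 0
        return 0.0
    return 1.0 / (1.0 + math.exp(z))


def linguistic_grades(f_star: float, cfg: FuzzyConfig = FuzzyConfig()) -> tuple[float, float]:
    """(High, Low) grades of a normalized reading; they sum to 1 exactly."""
    high = membership(f_star, cfg)
    return high, 1.0 - high


def evaluate_rules(
    fsr: FsrVector,
    rules: RuleBase | None = None,
    cfg: FuzzyConfig = FuzzyConfig(),
) -> PhaseGrades:
    """Evaluate all eight rules on a normalized FSR vector.

    Each rule's grade is the minimum, over its six conditions, of the High
    or Low grade the condition requires (fuzzy AND).  The predicted phase is
    the argmax; exact ties resolve to the earlier rule in cycle order.
    """
    rules = rules or default_rules()
    if fsr.normalized is None:
        raise ValueError("FSR vector must be normalized before rule evaluation")
    high_low: dict[str, tuple[float, float]] = {
        p: linguistic_grades(fsr.normalized[p] * cfg.input_scale, cfg)
        for p in PLACEMENTS
    }
    grades: dict[str, float] = {}
    best_phase = rules.rules[0].phase
    best_grade = -1.0
    for rule in rules.rules:
        grade = 1.0
        for placement, required in rule.conditions.items():
            high, low = high_low[placement]
            grade = min(grade, high if required == "High" else low)
        grades[rule.phase] = grade
        if grade > best_grade:
            best_grade = grade
            best_phase = rule.phase
    return PhaseGrades(
        grades=grades,
        consistency=sum(grades.values()),
        predicted_phase=best_phase,
        predicted_grade=best_grade,
    )


def mirror_rules(rules: RuleBase) -> RuleBase:
    """Swap left and right placement conditions; outcomes are unchanged.

    Applying the mirror twice returns the original rule base.
    """
    mirrored = tuple(
        Rule(
            conditions={_MIRROR[p]: v for p, v in rule.conditions.items()},
            phase=rule.phase,
        )
        for rule in rules.rules
    )
    return RuleBase(rules=mirrored, side="left" if rules.side == "right" else "right")


_FSR_CHANNELS = {
    "LH": "left_insole_fsr_heel",
    "L5M": "left_insole_fsr_m5",
    "L1M": "left_insole_fsr_m1",
    "RH": "right_insole_fsr_heel",
    "R5M": "right_insole_fsr_m5",
    "R1M": "right_insole_fsr_m1",
}


def classify_sequence(
    session,
    cfg: FuzzyConfig = FuzzyConfig(),
    rules: RuleBase | None = None,
) -> list[FrameClassification]:
    """Classify every complete frame of a recording session.

    Incomplete frames are skipped entirely (the safety contract: no phase
    estimate without all peripherals).  Frames whose phase-grade sum falls
    outside the configured consistency band are flagged ``abnormal`` (below)
    or ``conflicting`` (above) but still labelled.
    """
    rules = rules or default_rules()
    c_lo, c_hi = cfg.consistency_band
    out: list[FrameClassification] = []
    for frame in session.frames:
        if not frame.complete:
            continue
        if any(ch not in frame.channels for ch in _FSR_CHANNELS.values()):
            continue
        raw = {p: frame.channels[ch] for p, ch in _FSR_CHANNELS.items()}
        vec = normalize_fsr(raw, cfg.normalization_scope)
        result = evaluate_rules(vec, rules, cfg)
        if result.consistency < c_lo:
            flag = "abnormal"
        elif result.consistency > c_hi:
            flag = "conflicting"
        else:
            flag = "ok"
        out.append(
            FrameClassification(
                timestamp=frame.timestamp,
                phase=result.predicted_phase,
                grade=result.predicted_grade,
                consistency=result.consistency,
                flag=flag,
            )
        )
    return out


def dump_rules_yaml(rules: RuleBase, path) -> None:
    """Write a rule base as a declarative YAML document."""
    doc = {
        "side": rules.side,
        "rules": [
            {"phase": r.phase, "conditions": dict(r.conditions)} for r in rules.rules
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_rules_yaml(path) -> RuleBase:
    """Load a rule base written by :func:`dump_rules_yaml`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    rules = tuple(
        Rule(conditions=dict(entry["conditions"]), phase=entry["phase"])
        for entry in doc["rules"]
    )
    return RuleBase(rules=rules, side=doc.get("side", "right"))
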