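"""Study-quality scoring: MINIS grade, opinion scores, and reliability likelihood.

A toxicity study is graded 1-5 by counting failures among sixteen
minimum-inclusion-criteria rules (study design completeness, dose
grouping, reporting detail, ...): no failures -> grade 5, one or two ->
4, three or four -> 3, more than four -> 2, and summary-only records ->
grade 1 regardless of rule outcomes. The grade is crossed with a 1-5
expert Opinion Score through a lookup grid to yield the Study
Reliability Likelihood, a [0.5, 1] probability-like weight usable in
evidence combination. Rule outcomes and opinion scores are inputs -
the rules' content is organisation-specific and expert judgement is
never computed.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

N_RULES = 16

# Grid defaults: rows MINIS grade 5..1, columns opinion score 5..1.
# Values are modelled likelihoods, bounded below by ~0.5 (a study that
# exists at all retains some evidential weight).
DEFAULT_LIKELIHOOD = {
    5: {5: 1.0, 4: 0.95, 3: 0.85, 2: 0.75, 1: 0.6},
    4: {5: 0.95, 4: 0.9, 3: 0.8, 2: 0.7, 1: 0.6},
    3: {5: 0.9, 4: 0.85, 3: 0.75, 2: 0.65, 1: 0.6},
    2: {5: 0.85, 4: 0.8, 3: 0.7, 2: 0.6, 1: 0.5},
    1: {5: 0.8, 4: 0.75, 3: 0.65, 2: 0.6, 1: 0.5},
}

OPINION_ANCHORS = {
    5: "conclusion fully supported; no ambiguity in interpretation",
    4: "conclusion supported; minor interpretation caveats",
    3: "conclusion plausible; notable interpretation uncertainty",
    2: "conclusion weakly supported; major caveats",
    1: "conclusion not interpretable from the reported data",
}


class ReliabilityError(Exception):
    pass


def minis_grade(rule_outcomes: Sequence[bool], summary_only: bool = False) -> int:
    """Grade a study 1-5 from its sixteen rule outcomes.

    ``rule_outcomes[i]`` is True when rule i passes. Summary-only data
    is grade 1 unconditionally.
    """
    if len(rule_outcomes) != N_RULES:
        raise ReliabilityError(f"expected {N_RULES} rule outcomes, got {len(rule_outcomes)}")
    if summary_only:
        return 1
    failures = sum(1 for ok in rule_outcomes if not ok)
    if failures == 0:
        return 5
    if failures <= 2:
        return 4
    if failures <= 4:
        return 3
    return 2


@dataclass
class MinisAssessment:
    rule_outcomes: tuple
    summary_only: bool = False

    def __post_init__(self):
        self.rule_outcomes = tuple(bool(x) for x in self.rule_outcomes)
        if len(self.rule_outcomes) != N_RULES:
            raise ReliabilityError(f"expected {N_RULES} rule outcomes")

    @property
    def grade(self) -> int:
        return minis_grade(self.rule_outcomes, self.summary_only)

    @classmethod
    def from_string(cls, outcome_string: str, summary_only: bool = False) -> "MinisAssessment":
        """Parse a 16-character pass/fail string, e.g. 'PPPPPPPPPPPPPPFF'."""
        marks = outcome_string.strip().upper()
        if len(marks) != N_RULES or set(marks) - {"P", "F"}:
            raise ReliabilityError("outcome string must be 16 characters of P/F")
        return cls(tuple(ch == "P" for ch in marks), summary_only)


@dataclass
class StudyRecord:
    """One toxicity study attached to a compound.

    NOAEL/LOAEL are in mg/kg-bw/day (the 'mkd' shorthand of regulatory
    dossiers is normalised on input).
    """

    study_id: str
    compound_id: str
    endpoint: str = "repeated_dose_90d"
    species: str = ""
    strain: str = ""
    duration: str = ""
    route: str = ""
    dose_range: str = ""
    study_design: str = ""
    study_results: str = ""
    noael: Optional[float] = None
    loael: Optional[float] = None
    source: str = ""
    minis: Optional[MinisAssessment] = None
    minis_grade_override: Optional[int] = None
    opinion_score: Optional[int] = None

    def __post_init__(self):
        if self.noael is not None and self.loael is not None and not self.noael < self.loael:
            raise ReliabilityError(
                f"study {self.study_id!r}: NOAEL ({self.noael}) must be below LOAEL ({self.loael})"
            )
        if self.opinion_score is not None and self.opinion_score not in range(1, 6):
            raise ReliabilityError(f"opinion_score must be 1-5, got {self.opinion_score}")
        if self.minis_grade_override is not None and self.minis_grade_override not in range(1, 6):
            raise ReliabilityError(f"minis grade must be 1-5, got {self.minis_grade_override}")

    @property
    def grade(self) -> Optional[int]:
        """MINIS grade: derived from rule outcomes when present, else the override."""
        if self.minis is not None:
            return self.minis.grade
        return self.minis_grade_override


@dataclass
class ReliabilityTable:
    """(grade, opinion) -> likelihood grid; defaults to the modelled grid above."""

    likelihood: dict = field(default_factory=lambda: {g: dict(row) for g, row in DEFAULT_LIKELIHOOD.items()})

    def lookup(self, grade: int, opinion: int) -> float:
        if grade not in range(1, 6) or opinion not in range(1, 6):
            raise ReliabilityError(f"grade/opinion out of range: ({grade}, {opinion})")
        return self.likelihood[grade][opinion]

    @classmethod
    def from_json(cls, path) -> "ReliabilityTable":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        grid = {int(g): {int(o): float(v) for o, v in row.items()} for g, row in raw.items()}
        return cls(likelihood=grid)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.likelihood, fh, indent=2)


def reliability_likelihood(grade: int, opinion: int, table: Optional[ReliabilityTable] = None) -> float:
    """Study Reliability Likelihood lookup for a MINIS grade and opinion score."""
    table = table or ReliabilityTable()
    return table.lookup(grade, opinion)


def validate_reliability_table(table: ReliabilityTable) -> list:
    """Violations of the grid's structural requirements; empty list means valid.

    Checks [0, 1] bounds, completeness of the 5x5 grid, and both
    monotonicity directions (likelihood never increases when grade or
    opinion decreases).
    """
    violations = []
    for g in range(1, 6):
        row = table.likelihood.get(g)
        if row is None or set(row) != set(range(1, 6)):
            violations.append(f"grade {g}: incomplete opinion row")
            continue
        for o in range(1, 6):
            v = row[o]
            if not (0.0 <= v <= 1.0):
                violations.append(f"({g},{o}): value {v} outside [0, 1]")
    if violations:
        return violations
    for o in range(1, 6):
        for g in range(2, 6):
            if table.likelihood[g][o] < table.likelihood[g - 1][o]:
                violations.append(
                    f"grade monotonicity: ({g},{o})={table.likelihood[g][o]} < "
                    f"({g - 1},{o})={table.likelihood[g - 1][o]}"
                )
    for g in range(1, 6):
        for o in range(2, 6):
            if table.likelihood[g][o] < table.likelihood[g][o - 1]:
                violations.append(
                    f"opinion monotonicity: ({g},{o})={table.likelihood[g][o]} < "
                    f"({g},{o - 1})={table.likelihood[g][o - 1]}"
                )
    return violations


def grade_distribution(records: Iterable[StudyRecord]) -> dict:
    """Histogram of MINIS grades; records without any assessment count as 'ungraded'."""
    counts = Counter()
    for rec in records:
        grade = rec.grade
        counts[grade if grade is not None else "ungraded"] += 1
    out = {g: counts.get(g, 0) for g in range(1, 6)}
    out["ungraded"] = counts.get("ungraded", 0)
    return out
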