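"""Non-cancer Threshold of Toxicological Concern (TTC) decision tree.

The TTC approach waives compound-specific toxicity data when human
exposure falls below a structure-class-dependent threshold. The
implemented path is the non-cancer tree: first exclude the cohort of
concern (COC) — metals and metal-containing compounds, polyhalogenated
dibenzo-p-dioxins, dibenzofurans and biphenyls — for which no TTC
applies (Q1, immediate Fail); then route organophosphates to their own,
lower threshold (Q6); otherwise compare exposure to the Cramer-class
threshold (Q9). Exposure below the threshold (strictly) passes.

Only the Cramer III threshold (90 µg/person/day) is fixed by the guided
workflow this package reproduces; the Class I/II and organophosphate
defaults are editable configuration taken from the standard published
non-cancer TTC scheme. Cramer classification itself is an input (or a
pluggable classifier): tree implementations are known to disagree, and
a warning flag surfaces that caveat to the user.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional

from rdkit import Chem

from .registry import Compound, largest_organic_fragment


class TTCError(Exception):
    pass


class CramerClass(str, Enum):
    I = "I"
    II = "II"
    III = "III"


class Outcome(str, Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_APPLICABLE = "not_applicable"


DEFAULT_BODY_WEIGHT_KG = 60.0

# µg/person/day; Cramer thresholds ordered I >= II >= III.
DEFAULT_THRESHOLDS = {"I": 1800.0, "II": 540.0, "III": 90.0}
DEFAULT_ORGANOPHOSPHATE_THRESHOLD = 18.0

# Elements treated as non-metals for the COC metal rule.
_NONMETALS = {1, 2, 5, 6, 7, 8, 9, 10, 14, 15, 16, 17, 18, 34, 35, 36, 52, 53, 54, 86}
# Group 1/2 cations routinely present as counterions in salts.
_COUNTERION_METALS = {3, 11, 19, 37, 55, 4, 12, 20, 38, 56}

_COC_CORES = {
    "polyhalogenated dibenzodioxin": "c1ccc2Oc3ccccc3Oc2c1",
    "polyhalogenated dibenzofuran": "c1ccc2c(c1)oc1ccccc12",
    "polyhalogenated biphenyl": "c1ccc(-c2ccccc2)cc1",
}
_HALOGEN_ON_AROMATIC = "[F,Cl,Br,I;$([F,Cl,Br,I]c)]"

_ORGANOPHOSPHATE_SMARTS = "[PX4](=[OX1,SX1])([OX2,SX2])([OX2,SX2])"


@dataclass
class ThresholdConfig:
    """Editable thresholds (µg/person/day) for the decision tree."""

    cramer_thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    organophosphate_threshold: float = DEFAULT_ORGANOPHOSPHATE_THRESHOLD
    min_core_halogens: int = 2  # 'polyhalogenated' requires at least this many

    def __post_init__(self):
        t = self.cramer_thresholds
        if not (t["I"] >= t["II"] >= t["III"] > 0):
            raise TTCError(f"Cramer thresholds must satisfy I >= II >= III > 0, got {t}")

    @classmethod
    def from_json(cls, path) -> "ThresholdConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls(
            cramer_thresholds=raw.get("cramer_thresholds", dict(DEFAULT_THRESHOLDS)),
            organophosphate_threshold=raw.get(
                "organophosphate_threshold", DEFAULT_ORGANOPHOSPHATE_THRESHOLD
            ),
            min_core_halogens=raw.get("min_core_halogens", 2),
        )


@dataclass
class TTCQuery:
    compound: Compound
    exposure: float
    exposure_unit: str = "ug_per_kg_bw_day"  # or "ug_per_person_day"
    cramer_class: Optional[CramerClass] = None
    body_weight_kg: float = DEFAULT_BODY_WEIGHT_KG
    cramer_warning: Optional[str] = None  # e.g. classifier-disagreement notes

    def __post_init__(self):
        if self.exposure <= 0:
            raise TTCError("exposure must be positive")
        if self.body_weight_kg <= 0:
            raise TTCError("body weight must be positive")
        if self.exposure_unit not in ("ug_per_kg_bw_day", "ug_per_person_day"):
            raise TTCError(f"unknown exposure unit {self.exposure_unit!r}")
        if self.cramer_class is not None:
            self.cramer_class = CramerClass(self.cramer_class)


@dataclass
class TTCVerdict:
    outcome: Outcome
    fired_node: str
    exposure_per_person: float
    threshold_applied: Optional[float] = None
    trace: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome.value,
            "fired_node": self.fired_node,
            "exposure_ug_per_person_day": self.exposure_per_person,
            "threshold_ug_per_person_day": self.threshold_applied,
            "trace": [list(step) for step in self.trace],
            "warnings": list(self.warnings),
        }


def convert_exposure(value_ug_per_kg_bw_day: float, body_weight_kg: float = DEFAULT_BODY_WEIGHT_KG) -> float:
    """Per-kg daily exposure to per-person daily exposure (µg/person/day)."""
    if value_ug_per_kg_bw_day <= 0 or body_weight_kg <= 0:
        raise TTCError("exposure and body weight must be positive")
    return value_ug_per_kg_bw_day * body_weight_kg


def coc_check(compound: Compound, config: Optional[ThresholdConfig] = None) -> tuple:
    """(is_coc, group) — does the compound belong to the cohort of concern?

    Metal detection runs on the full record: any atom that is neither a
    non-metal nor a monoatomic group-1/2 counterion (in a salt that also
    has an organic fragment) makes the compound 'metal containing'. The
    halogenated-core groups are matched on the main organic fragment and
    require >= config.min_core_halogens aromatic halogens.
    """
    config = config or ThresholdConfig()
    compound.require_structure()
    mol = compound.mol()
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    has_organic = any(any(a.GetAtomicNum() == 6 for a in f.GetAtoms()) for f in frags)
    for frag in frags:
        atoms = list(frag.GetAtoms())
        is_counterion = (
            has_organic
            and len(atoms) == 1
            and atoms[0].GetAtomicNum() in _COUNTERION_METALS
        )
        if is_counterion:
            continue
        for atom in atoms:
            if atom.GetAtomicNum() not in _NONMETALS:
                return True, "metal containing compounds"
    main = largest_organic_fragment(mol)
    n_halogens = len(main.GetSubstructMatches(Chem.MolFromSmarts(_HALOGEN_ON_AROMATIC)))
    if n_halogens >= config.min_core_halogens:
        for group, core in _COC_CORES.items():
            if main.HasSubstructMatch(Chem.MolFromSmarts(core)):
                return True, group
    return False, None


def is_organophosphate(compound: Compound) -> bool:
    """Phosphate/phosphorothioate ester core present in the main fragment?"""
    compound.require_structure()
    return compound.main_fragment().HasSubstructMatch(Chem.MolFromSmarts(_ORGANOPHOSPHATE_SMARTS))


def ttc_evaluate(
    query: TTCQuery,
    config: Optional[ThresholdConfig] = None,
    classifier: Optional[Callable[[Compound], CramerClass]] = None,
) -> TTCVerdict:
    """Run the non-cancer TTC tree: COC (Q1) -> organophosphate (Q6) -> Cramer (Q9).

    Threshold comparisons are strict: exposure equal to the threshold
    fails (conservative reading of 'lower than'). The verdict carries a
    full question/answer trace.
    """
    config = config or ThresholdConfig()
    trace: list = []
    warnings: list = []
    if query.cramer_warning:
        warnings.append(query.cramer_warning)

    if query.exposure_unit == "ug_per_kg_bw_day":
        exposure = convert_exposure(query.exposure, query.body_weight_kg)
        trace.append(
            ("exposure_conversion",
             f"{query.exposure} ug/kg-bw/day x {query.body_weight_kg} kg = {exposure} ug/person/day")
        )
    else:
        exposure = query.exposure
        trace.append(("exposure_conversion", f"{exposure} ug/person/day (no conversion)"))

    if not query.compound.has_structure:
        trace.append(("Q1 COC", "not evaluable: no structure"))
        return TTCVerdict(Outcome.NOT_APPLICABLE, "Q1 COC", exposure, trace=trace, warnings=warnings)

    is_coc, group = coc_check(query.compound, config)
    trace.append(("Q1 COC", f"cohort of concern: {group}" if is_coc else "not in cohort of concern"))
    if is_coc:
        return TTCVerdict(Outcome.FAIL, "Q1 COC", exposure, trace=trace, warnings=warnings)

    organophosphate = is_organophosphate(query.compound)
    trace.append(("Q6 organophosphate", "yes" if organophosphate else "no"))
    if organophosphate:
        threshold = config.organophosphate_threshold
        outcome = Outcome.PASS if exposure < threshold else Outcome.FAIL
        trace.append(
            ("Q6 threshold", f"{exposure} vs organophosphate threshold {threshold} ug/person/day")
        )
        return TTCVerdict(outcome, "Q6 organophosphate", exposure, threshold, trace, warnings)

    cramer = query.cramer_class
    if cramer is None:
        if classifier is None:
            raise TTCError("no Cramer class supplied and no classifier configured")
        cramer = CramerClass(classifier(query.compound))
        warnings.append(
            "Cramer class assigned by plug-in classifier; tree implementations are known "
            "to disagree for some compound classes — verify the assignment"
        )
    threshold = float(config.cramer_thresholds[cramer.value])
    trace.append((f"Q9 Cramer {cramer.value}", f"{exposure} vs threshold {threshold} ug/person/day"))
    outcome = Outcome.PASS if exposure < threshold else Outcome.FAIL
    return TTCVerdict(outcome, f"Q9 Cramer {cramer.value}", exposure, threshold, trace, warnings)
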