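"""Weight-of-evidence combination and read-across reliability.

Two independent sources of evidence support a read-across: how good the
analogue is (Analogue Quality, AQ) and how trustworthy its study is
(Study Reliability Likelihood, SRL). The point estimate of read-across
reliability is their joint probability AQ x SRL; a belief/plausibility
interval comes from combining the two as discounted Dempster-Shafer
mass functions over the frame {reliable, not reliable}.

Qualification floors: a candidate qualifies as an analogue only when
both AQ and SRL reach 0.7; an SRL below 0.5 marks the study data as
unusable for read-across regardless of similarity.

The endpoint value itself (a NOAEL for the target) is interval-estimated
from the NOAELs of structural nearest neighbours, by default assuming a
normal distribution of neighbour NOAELs (mean +/- z*sd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats as scipy_stats

from .registry import Compound, CompoundLibrary
from .similarity import compute_fingerprint, round_report, tanimoto

AQ_FLOOR = 0.70
SRL_FLOOR = 0.70
SRL_HARD_FLOOR = 0.50
DEFAULT_DISCOUNT = 0.90


class EvidenceError(Exception):
    pass


class Qualification(str, Enum):
    QUALIFIED = "qualified"
    NOT_FEASIBLE = "not_feasible"
    DATA_UNUSABLE = "data_unusable"


def _check_unit(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise EvidenceError(f"{name} must be in [0, 1], got {value}")


def joint_reliability(analogue_quality: float, study_reliability: float) -> float:
    """Read-across reliability point estimate: the product AQ x SRL.

    Full precision is kept; use :func:`readacross.similarity.round_report`
    for 2-dp table output (the two-decimal report can differ from the
    product of rounded inputs — 0.6258 x 0.9 reports as 0.56, not 0.57).
    """
    _check_unit(analogue_quality, "analogue_quality")
    _check_unit(study_reliability, "study_reliability")
    return analogue_quality * study_reliability


def qualify_analogue(
    analogue_quality,
    study_reliability: Optional[float] = None,
    aq_floor: float = AQ_FLOOR,
    srl_floor: float = SRL_FLOOR,
    srl_hard_floor: float = SRL_HARD_FLOOR,
) -> tuple:
    """(Qualification, rationale) for one candidate/study pair.

    Accepts either (aq, srl) scalars or an :class:`EvidenceRow` carrying
    both. ``data_unusable`` (SRL below the hard floor) takes precedence:
    no degree of structural similarity rescues unusable study data.
    """
    if isinstance(analogue_quality, EvidenceRow):
        row = analogue_quality
        if row.analogue_quality is None or row.study_reliability is None:
            raise EvidenceError(
                f"evidence row {row.compound_id!r} is missing analogue quality or study reliability"
            )
        analogue_quality, study_reliability = row.analogue_quality, row.study_reliability
    if study_reliability is None:
        raise EvidenceError("study_reliability is required")
    _check_unit(analogue_quality, "analogue_quality")
    _check_unit(study_reliability, "study_reliability")
    if study_reliability < srl_hard_floor:
        return (
            Qualification.DATA_UNUSABLE,
            f"study reliability {study_reliability:.2f} below the hard floor "
            f"{srl_hard_floor:.2f}; this study does not warrant read-across",
        )
    if analogue_quality >= aq_floor and study_reliability >= srl_floor:
        return (
            Qualification.QUALIFIED,
            f"analogue quality {analogue_quality:.2f} and study reliability "
            f"{study_reliability:.2f} both reach the {aq_floor:.2f} floor",
        )
    low = []
    if analogue_quality < aq_floor:
        low.append(f"analogue quality {analogue_quality:.2f} < {aq_floor:.2f}")
    if study_reliability < srl_floor:
        low.append(f"study reliability {study_reliability:.2f} < {srl_floor:.2f}")
    return (Qualification.NOT_FEASIBLE, "read-across unlikely to be feasible: " + "; ".join(low))


@dataclass(frozen=True)
class MassFunction:
    """Belief masses over {reliable, not_reliable, either (ignorance)}."""

    reliable: float
    not_reliable: float
    either: float

    def __post_init__(self):
        for v in (self.reliable, self.not_reliable, self.either):
            if v < -1e-12:
                raise EvidenceError("mass values must be non-negative")
        if abs(self.reliable + self.not_reliable + self.either - 1.0) > 1e-9:
            raise EvidenceError("masses must sum to 1 within 1e-9")

    def as_tuple(self) -> tuple:
        return (self.reliable, self.not_reliable, self.either)


VACUOUS_MASS = MassFunction(0.0, 0.0, 1.0)


def build_mass(score: float, discount: float = DEFAULT_DISCOUNT) -> MassFunction:
    """Turn a [0,1] reliability score into a discounted mass function.

    The discount caps how much of the score is committed to the frame's
    singletons; the remainder 1-discount stays on 'either' as structural
    ignorance. discount=0 yields the vacuous (totally ignorant) mass.
    """
    _check_unit(score, "score")
    _check_unit(discount, "discount")
    return MassFunction(
        reliable=discount * score,
        not_reliable=discount * (1.0 - score),
        either=1.0 - discount,
    )


def dst_combine(m1: MassFunction, m2: MassFunction) -> MassFunction:
    """Dempster's rule of combination over the two-hypothesis frame.

    Conflict is the mass assigned to contradictory pairs
    (reliable x not_reliable); compatible products are renormalised by
    1 - conflict. Total conflict (normaliser 0) is an error.
    """
    conflict = m1.reliable * m2.not_reliable + m1.not_reliable * m2.reliable
    norm = 1.0 - conflict
    if norm <= 0.0:
        raise EvidenceError("total conflict between mass functions; combination undefined")
    reliable = (
        m1.reliable * m2.reliable + m1.reliable * m2.either + m1.either * m2.reliable
    ) / norm
    not_reliable = (
        m1.not_reliable * m2.not_reliable
        + m1.not_reliable * m2.either
        + m1.either * m2.not_reliable
    ) / norm
    either = (m1.either * m2.either) / norm
    return MassFunction(reliable, not_reliable, either)


def belief_plausibility(m: MassFunction) -> tuple:
    """(belief, plausibility) of 'reliable'; the gap is residual uncertainty."""
    return (m.reliable, m.reliable + m.either)


def read_across_interval(
    analogue_quality: float,
    study_reliability: float,
    discount: float = DEFAULT_DISCOUNT,
) -> tuple:
    """Belief/plausibility interval for read-across reliability.

    Discounts AQ and SRL into mass functions and combines them by
    Dempster's rule. With the default discount the interval brackets
    the joint-probability point estimate's neighbourhood; the interval
    narrows as discount -> 1 (less structural ignorance).
    """
    m = dst_combine(build_mass(analogue_quality, discount), build_mass(study_reliability, discount))
    return belief_plausibility(m)


@dataclass
class EvidenceRow:
    """One weight-of-evidence table row for a target or candidate compound."""

    compound_id: str
    role: str  # target / analogue / similar
    analogue_quality: Optional[float] = None
    aq_variant: str = "euclidean"
    category_flags: dict = field(default_factory=dict)
    study_id: Optional[str] = None
    study_design: str = ""
    study_results: str = ""
    study_source: str = ""
    minis_grade: Optional[int] = None
    opinion_score: Optional[int] = None
    study_reliability: Optional[float] = None
    noael: Optional[float] = None
    loael: Optional[float] = None
    qualification: Optional[Qualification] = None
    qualification_rationale: str = ""
    read_across_reliability: Optional[float] = None
    read_across_interval: Optional[tuple] = None

    def report_row(self) -> dict:
        """Flat dict with 2-dp reliability figures for table export."""
        out = {
            "compound_id": self.compound_id,
            "role": self.role,
            "aq": round_report(self.analogue_quality) if self.analogue_quality is not None else None,
            "minis_grade": self.minis_grade,
            "opinion_score": self.opinion_score,
            "study_reliability": round_report(self.study_reliability)
            if self.study_reliability is not None
            else None,
            "read_across_reliability": round_report(self.read_across_reliability)
            if self.read_across_reliability is not None
            else None,
            "noael_mg_kg_day": self.noael,
            "study_source": self.study_source,
            "qualification": self.qualification.value if self.qualification else None,
        }
        if self.read_across_interval is not None:
            lo, hi = self.read_across_interval
            out["read_across_belief"] = round_report(lo)
            out["read_across_plausibility"] = round_report(hi)
        for cat, flag in self.category_flags.items():
            out[f"category_{cat}"] = flag
        return out


def noael_bounds(
    noael_values: Sequence[float],
    level: float = 0.95,
    mode: str = "normal_sd",
) -> tuple:
    """Interval estimate for a read-across NOAEL from neighbour NOAELs.

    Modes:
      normal_sd      mean +/- z * sd        (population spread; the default
                     reading of 'assuming a normal distribution of NOAELs')
      normal_mean_ci mean +/- z * sd/sqrt(n) (confidence interval on the mean)
      lognormal_sd   normal_sd applied on log values, bounds exponentiated

    The lower bound is clipped at 0 (a NOAEL cannot be negative). A single
    value is an error: report that analogue's NOAEL directly, without an
    interval, instead.
    """
    values = np.asarray(list(noael_values), dtype=float)
    if values.size < 2:
        raise EvidenceError(
            "need >= 2 NOAEL values for an interval; with a single value, report the "
            "analogue's NOAEL directly as a surrogate (no confidence interval is possible)"
        )
    if np.any(values <= 0):
        raise EvidenceError("NOAEL values must be positive (mg/kg-bw/day)")
    if not (0.0 < level < 1.0):
        raise EvidenceError("confidence level must be in (0, 1)")
    z = float(scipy_stats.norm.ppf(0.5 + level / 2.0))
    if mode == "normal_sd":
        mean, sd = values.mean(), values.std(ddof=1)
        lo, hi = mean - z * sd, mean + z * sd
    elif mode == "normal_mean_ci":
        mean, sd = values.mean(), values.std(ddof=1)
        half = z * sd / math.sqrt(values.size)
        lo, hi = mean - half, mean + half
    elif mode == "lognormal_sd":
        logs = np.log(values)
        mean, sd = logs.mean(), logs.std(ddof=1)
        lo, hi = math.exp(mean - z * sd), math.exp(mean + z * sd)
    else:
        raise EvidenceError(f"unknown bound mode {mode!r}")
    return (max(lo, 0.0), hi)


def nearest_neighbor_noaels(
    target: Compound,
    dataset: CompoundLibrary,
    noaels: dict,
    fp_method: str = "chemotype_library",
    threshold: float = 0.70,
    exclusion_alerts=None,
) -> tuple:
    """NOAELs of dataset structures within the similarity neighbourhood.

    ``noaels`` maps compound_id -> NOAEL (mg/kg-bw/day). Neighbours are
    dataset compounds with Tanimoto >= threshold to the target under
    ``fp_method``; compounds matching any alert in ``exclusion_alerts``
    (e.g. a reproductive-toxicant profile absent from the target) are
    removed. Returns (values, status) where status is "ok" or
    "empty_neighbourhood".
    """
    from .profiling import match_alerts

    target.require_structure()
    target_fp = compute_fingerprint(target, fp_method)
    values = []
    for compound in dataset.with_structures():
        if compound.compound_id not in noaels:
            continue
        if tanimoto(target_fp, compute_fingerprint(compound, fp_method)) < threshold:
            continue
        if exclusion_alerts is not None and match_alerts(compound, exclusion_alerts):
            continue
        values.append(float(noaels[compound.compound_id]))
    return (values, "ok" if values else "empty_neighbourhood")
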