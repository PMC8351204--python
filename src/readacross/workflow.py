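"""Guided read-across workflow: seven steps from similarity search to NOAEL bounds.

Step 1  similarity search -> hit list
Step 2  property table (computed or attached external values)
Step 3  similarity profiles and Analogue Quality
Step 4  chemotype/alert screen
Step 5  study records with Study Reliability Likelihood
Step 6  weight-of-evidence table: roles, qualification, read-across
        reliability (joint probability + Dempster-Shafer interval)
Step 7  NOAEL bound estimation from qualified analogues (and optionally
        from a user-supplied NOAEL dataset of structural neighbours)

The pipeline is deterministic: the only randomness in the package lives
in the synthetic fixture generator, and a fixed config reproduces a
byte-identical report. Any step failure downgrades the run to a partial
report that keeps all completed steps.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .evidence import (
    EvidenceRow,
    Qualification,
    joint_reliability,
    noael_bounds,
    qualify_analogue,
    read_across_interval,
)
from .fixtures import FixtureBundle
from .profiling import AlertLibrary, default_alert_library, screen_library
from .registry import CompoundRole
from .reliability import ReliabilityTable, reliability_likelihood
from .similarity import (
    DEFAULT_SEARCH_THRESHOLD,
    pairwise_profile,
    round_report,
)

logger = logging.getLogger(__name__)

STEP_NAMES = {
    1: "similarity_search",
    2: "property_table",
    3: "similarity_profiles",
    4: "chemotype_screen",
    5: "study_reliability",
    6: "weight_of_evidence",
    7: "noael_bounds",
}


@dataclass
class WorkflowConfig:
    bundle: FixtureBundle
    threshold: float = DEFAULT_SEARCH_THRESHOLD
    aq_variant: str = "euclidean"
    reliability_table: ReliabilityTable = field(default_factory=ReliabilityTable)
    alerts: Optional[AlertLibrary] = None
    noael_level: float = 0.95
    noael_mode: str = "normal_sd"
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(
            {
                "target": self.bundle.target_id,
                "source": self.bundle.library.source_label,
                "threshold": self.threshold,
                "aq_variant": self.aq_variant,
                "noael_level": self.noael_level,
                "noael_mode": self.noael_mode,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class WorkflowReport:
    target_id: str
    status: str = "complete"
    steps: dict = field(default_factory=dict)  # step number -> payload
    provenance: dict = field(default_factory=dict)

    def step(self, number: int):
        return self.steps.get(number)

    def as_dict(self) -> dict:
        return {
            "target_id": self.target_id,
            "status": self.status,
            "steps": {STEP_NAMES[k]: v for k, v in sorted(self.steps.items())},
            "provenance": self.provenance,
        }


def run_guided_workflow(config: WorkflowConfig) -> WorkflowReport:
    """Execute Steps 1-7 on a fixture bundle, halting gracefully on gaps."""
    bundle = config.bundle
    if bundle.target_id not in bundle.library:
        raise KeyError(f"target {bundle.target_id!r} not in library")
    target = bundle.library[bundle.target_id]
    report = WorkflowReport(
        target_id=bundle.target_id,
        provenance={
            "package_version": __version__,
            "seed": config.seed,
            "config_digest": config.digest(),
            "source_label": bundle.library.source_label,
        },
    )

    # Step 1 — similarity hit list at the search threshold. External
    # Tanimoto tables (exported from the source system) take precedence
    # over recomputation; ranking uses the first fingerprint method.
    rank_method = bundle.fp_methods[0]
    candidates = bundle.candidates()
    hits = []
    for cand in candidates:
        ext = bundle.external_tanimoto.get(cand.compound_id, {})
        if rank_method in ext:
            t = float(ext[rank_method])
        else:
            from .similarity import compute_fingerprint, tanimoto

            t = tanimoto(
                compute_fingerprint(target, rank_method),
                compute_fingerprint(cand, rank_method),
            )
        if t >= config.threshold:
            hits.append({"compound_id": cand.compound_id, "tanimoto": t, "method": rank_method})
    hits.sort(key=lambda h: (-h["tanimoto"], h["compound_id"]))
    report.steps[1] = {"threshold": config.threshold, "hits": hits}
    if not hits:
        report.status = "partial: no candidates above the similarity threshold"
        return report
    hit_ids = [h["compound_id"] for h in hits]

    # Step 2 — property table for target + hits (external values flagged).
    members = [target] + [bundle.library[cid] for cid in hit_ids]
    prop_rows = []
    for compound in members:
        row = {"compound_id": compound.compound_id, "name": compound.preferred_name}
        if bundle.properties:
            try:
                from .descriptors import compute_descriptors

                vec = compute_descriptors(compound, bundle.properties)
                for name, value in zip(vec.names, vec.values):
                    row[name] = value
                    row[f"{name}_provenance"] = compound.property_provenance.get(name, "computed")
            except Exception as exc:
                row["error"] = str(exc)
        prop_rows.append(row)
    report.steps[2] = {"properties": list(bundle.properties), "rows": prop_rows}

    # Step 3 — similarity profiles and AQ.
    if bundle.external_profiles is not None:
        profiles = [p for p in bundle.external_profiles if p.candidate_id in hit_ids or
                    p.candidate_id == bundle.target_id]
    else:
        profiles = pairwise_profile(
            target,
            [bundle.library[cid] for cid in hit_ids],
            fp_methods=bundle.fp_methods,
            properties=bundle.properties,
            ref=bundle.reference,
            external_tanimoto=bundle.external_tanimoto,
            external_z=bundle.external_z,
        )
    profile_by_id = {p.candidate_id: p for p in profiles}
    report.steps[3] = {"profiles": [p.report_row() for p in profiles]}

    # Step 4 — chemotype/alert screen over target + hits.
    alerts = config.alerts or default_alert_library()
    sub_lib = type(bundle.library)(members, source_label=bundle.library.source_label)
    screen = screen_library(sub_lib, alerts)
    import pandas as pd

    screen_payload = {
        cid: {cat: (None if pd.isna(flag) else bool(flag)) for cat, flag in row.items()}
        for cid, row in screen.iterrows()
    }
    report.steps[4] = {"categories": list(screen.columns), "flags": screen_payload}

    # Step 5 — study records with reliability likelihood.
    study_rows = []
    srl_by_compound = {}
    study_by_compound = {}
    for rec in bundle.study_records:
        grade = rec.grade
        srl = None
        if grade is not None and rec.opinion_score is not None:
            srl = reliability_likelihood(grade, rec.opinion_score, config.reliability_table)
        study_rows.append(
            {
                "study_id": rec.study_id,
                "compound_id": rec.compound_id,
                "study_design": rec.study_design,
                "study_results": rec.study_results,
                "noael_mg_kg_day": rec.noael,
                "loael_mg_kg_day": rec.loael,
                "source": rec.source,
                "minis_grade": grade,
                "opinion_score": rec.opinion_score,
                "study_reliability": srl,
            }
        )
        if srl is not None:
            # keep the most reliable study per compound
            if rec.compound_id not in srl_by_compound or srl > srl_by_compound[rec.compound_id]:
                srl_by_compound[rec.compound_id] = srl
                study_by_compound[rec.compound_id] = rec
    report.steps[5] = {"studies": study_rows}

    # Step 6 — weight-of-evidence table.
    evidence_rows = [
        EvidenceRow(
            compound_id=target.compound_id,
            role=CompoundRole.TARGET.value,
            analogue_quality=1.0,
            aq_variant=config.aq_variant,
            category_flags=screen_payload.get(target.compound_id, {}),
            study_design="assumed no data",
        )
    ]
    qualified_noaels = []
    for cid in hit_ids:
        profile = profile_by_id.get(cid)
        aq = profile.analogue_quality.get(config.aq_variant) if profile and not profile.error else None
        srl = srl_by_compound.get(cid)
        rec = study_by_compound.get(cid)
        row = EvidenceRow(
            compound_id=cid,
            role=CompoundRole.SIMILAR.value,
            analogue_quality=aq,
            aq_variant=config.aq_variant,
            category_flags=screen_payload.get(cid, {}),
        )
        if rec is not None:
            row.study_id = rec.study_id
            row.study_design = rec.study_design
            row.study_results = rec.study_results
            row.study_source = rec.source
            row.minis_grade = rec.grade
            row.opinion_score = rec.opinion_score
            row.noael = rec.noael
            row.loael = rec.loael
        row.study_reliability = srl
        if aq is not None and srl is not None:
            qualification, rationale = qualify_analogue(aq, srl)
            row.qualification = qualification
            row.qualification_rationale = rationale
            row.read_across_reliability = joint_reliability(aq, srl)
            row.read_across_interval = read_across_interval(aq, srl)
            if qualification is Qualification.QUALIFIED:
                row.role = CompoundRole.ANALOGUE.value
                if row.noael is not None:
                    qualified_noaels.append(row.noael)
        evidence_rows.append(row)
    report.steps[6] = {"rows": [r.report_row() for r in evidence_rows]}

    # Step 7 — NOAEL estimation for the target.
    step7: dict = {"level": config.noael_level, "mode": config.noael_mode}
    analogue_rows = [r for r in evidence_rows if r.role == CompoundRole.ANALOGUE.value]
    if len(qualified_noaels) >= 2:
        lo, hi = noael_bounds(qualified_noaels, level=config.noael_level, mode=config.noael_mode)
        step7.update(
            {"status": "interval", "n": len(qualified_noaels),
             "lower_mg_kg_day": lo, "upper_mg_kg_day": hi}
        )
    elif len(qualified_noaels) == 1:
        step7.update(
            {
                "status": "single_value_surrogate",
                "n": 1,
                "surrogate_noael_mg_kg_day": qualified_noaels[0],
                "note": ("only one qualified analogue NOAEL; reported as a surrogate value — "
                         "no confidence interval can be derived from a single value"),
            }
        )
    else:
        step7.update({"status": "no_qualified_analogue_noael", "n": 0})
        if not analogue_rows:
            report.status = "partial: no qualified analogue for NOAEL estimation"
    report.steps[7] = step7
    return report


def export_report(report: WorkflowReport, out_dir, format: str = "csv_bundle") -> list:
    """Write a report as ``csv_bundle`` (one file per step), ``json`` or ``markdown``.

    Returns the list of written paths; output is deterministic for a
    fixed report.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if format == "json":
        path = out_dir / "report.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report.as_dict(), fh, indent=2, default=str)
        return [path]
    if format == "csv_bundle":
        for number, payload in sorted(report.steps.items()):
            path = out_dir / f"step{number}_{STEP_NAMES[number]}.csv"
            rows = _tabulate(number, payload)
            with open(path, "w", newline="", encoding="utf-8") as fh:
                if rows:
                    fields: list[str] = []
                    for row in rows:
                        for key in row:
                            if key not in fields:
                                fields.append(key)
                    writer = csv.DictWriter(fh, fieldnames=fields)
                    writer.writeheader()
                    writer.writerows(rows)
                else:
                    fh.write("empty\n")
            written.append(path)
        return written
    if format == "markdown":
        path = out_dir / "report.md"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_markdown(report))
        return [path]
    raise ValueError(f"unknown export format {format!r}")


def _tabulate(number: int, payload: dict) -> list:
    if number == 1:
        return payload["hits"]
    if number == 2:
        return payload["rows"]
    if number == 3:
        return payload["profiles"]
    if number == 4:
        return [
            {"compound_id": cid, **flags} for cid, flags in payload["flags"].items()
        ]
    if number == 5:
        return payload["studies"]
    if number == 6:
        return payload["rows"]
    if number == 7:
        return [payload]
    return []


def _markdown(report: WorkflowReport) -> str:
    lines = [f"# Guided read-across report — target {report.target_id}", ""]
    lines.append(f"Status: {report.status}")
    lines.append("")
    for number, payload in sorted(report.steps.items()):
        lines.append(f"## Step {number}: {STEP_NAMES[number].replace('_', ' ')}")
        rows = _tabulate(number, payload)
        if not rows:
            lines.append("")
            lines.append("(empty)")
            lines.append("")
            continue
        fields: list[str] = []
        for row in rows:
            for key in row:
                if key not in fields:
                    fields.append(key)
        lines.append("")
        lines.append("| " + " | ".join(fields) + " |")
        lines.append("|" + "---|" * len(fields))
        for row in rows:
            cells = []
            for key in fields:
                value = row.get(key)
                if isinstance(value, float):
                    value = f"{round_report(value):.2f}"
                cells.append("" if value is None else str(value))
            lines.append("| " + " | ".join(cells) + " |")
        lines.append("")
    prov = report.provenance
    lines.append("## Provenance")
    lines.append("")
    for key, value in prov.items():
        lines.append(f"- {key}: {value}")
    lines.append("")
    return "\n".join(lines)
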