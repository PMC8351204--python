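"""Structural-alert (chemotype) profiling and endpoint enrichment z-scores.

Alerts are SMARTS patterns grouped into categories (liver, DNA binder,
developmental/reproductive, ...). Matching a compound against an alert
library yields interpretable category flags; across a compound set, the
association between a chemotype and an endpoint is summarised by a
two-proportion z statistic (hit rate inside the chemotype subset vs the
complement, pooled variance) binned into five colour-coded strength
classes.

The bundled default library is a small curated set covering the hair-dye
chemistry exercised in the guided workflow (quinone precursors, aromatic
nitro and amine DNA binders, and a nitroaromatic reproductive-toxicant
alert); real assessments should load a full published chemotype set via
the same CSV/JSON format.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem

from .registry import Compound, CompoundLibrary


class ProfilingError(Exception):
    pass


@dataclass(frozen=True)
class Alert:
    alert_id: str
    category: str
    label: str
    smarts: str

    def pattern(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise ProfilingError(f"SMARTS for alert {self.alert_id!r} does not compile: {self.smarts!r}")
        return patt


class AlertLibrary:
    """Ordered collection of unique structural alerts."""

    def __init__(self, entries: Iterable[Alert]):
        self.entries: list[Alert] = []
        seen = set()
        for alert in entries:
            if alert.alert_id in seen:
                raise ProfilingError(f"duplicate alert_id {alert.alert_id!r}")
            alert.pattern()  # compile check at load
            seen.add(alert.alert_id)
            self.entries.append(alert)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def categories(self) -> list[str]:
        out = []
        for a in self.entries:
            if a.category not in out:
                out.append(a.category)
        return out

    @classmethod
    def from_file(cls, path) -> "AlertLibrary":
        path = Path(path)
        if path.suffix.lower() == ".json":
            with open(path, encoding="utf-8") as fh:
                rows = json.load(fh)
        else:
            with open(path, newline="", encoding="utf-8") as fh:
                rows = list(csv.DictReader(fh))
        return cls(
            Alert(
                alert_id=row["alert_id"],
                category=row["category"],
                label=row.get("label", row["alert_id"]),
                smarts=row["smarts"],
            )
            for row in rows
        )


# Curated mini-library: enough chemistry to profile nitroaromatic hair-dye
# analogues. Quinone/pro-quinone precursors (ortho/para aminophenols and
# phenylenediamines) flag oxidative liver metabolites; aromatic nitro and
# aromatic amine groups are classical DNA-binder alerts; a nitro group
# para to an aromatic amine or hydroxyl marks the reproductive-toxicant
# nitroaromatic substitution pattern.
_DEFAULT_ALERTS = [
    ("liver_quinone", "liver", "quinones and pro-quinones",
     "[$([OX1]=C1C=CC(=[OX1])C=C1),$([OX2H,NX3;H1,H2]c1ccc([OX2H,NX3;H1,H2])cc1),$([OX2H,NX3;H1,H2]c1ccccc1[OX2H,NX3;H1,H2])]"),
    ("dna_aromatic_nitro", "DNA binder", "aromatic nitro",
     "[$(c[N+](=O)[O-]),$(c[N](=O)=O)]"),
    ("dna_aromatic_amine", "DNA binder", "aromatic amine",
     "[NX3;H1,H2;!$(NC=O)]c"),
    ("dart_nitroaromatic", "developmental/reproductive", "aromatic nitro system; reproductive toxicant",
     "[$([NX3+](=O)[O-]),$([NX3](=O)=O)]c1ccc([$([NX3;H1,H2;!$(NC=O)]),$([OX2H])])cc1"),
]


def default_alert_library() -> AlertLibrary:
    return AlertLibrary(Alert(a, c, l, s) for a, c, l, s in _DEFAULT_ALERTS)


def match_alerts(compound: Compound, library: AlertLibrary) -> list:
    """All alerts with >= 1 substructure match on the compound's main fragment.

    Returns (alert_id, category, match_count) triples in library order.
    """
    compound.require_structure()
    mol = compound.main_fragment()
    out = []
    for alert in library:
        matches = mol.GetSubstructMatches(alert.pattern())
        if matches:
            out.append((alert.alert_id, alert.category, len(matches)))
    return out


def screen_library(library: CompoundLibrary, alerts: AlertLibrary):
    """Boolean compounds x categories flag table as a pandas DataFrame.

    Structureless compounds get pandas NA in every category (not
    evaluable) rather than False.
    """
    import pandas as pd

    categories = alerts.categories()
    rows = {}
    for compound in library:
        if not compound.has_structure:
            rows[compound.compound_id] = {c: pd.NA for c in categories}
            continue
        hit_cats = {cat for _, cat, _ in match_alerts(compound, alerts)}
        rows[compound.compound_id] = {c: c in hit_cats for c in categories}
    frame = pd.DataFrame.from_dict(rows, orient="index", dtype="boolean")
    if len(frame):
        frame = frame.reindex(columns=categories)
    else:
        frame = pd.DataFrame(columns=categories, dtype="boolean")
    frame.index.name = "compound_id"
    return frame


def smarts_fingerprint(compound: Compound, library: AlertLibrary, method: str = "chemotype_library"):
    """Alert library as a fingerprint: bit i set iff library entry i matches."""
    from .similarity import FingerprintBitset

    compound.require_structure()
    mol = compound.main_fragment()
    bits = frozenset(
        i for i, alert in enumerate(library) if mol.HasSubstructMatch(alert.pattern())
    )
    return FingerprintBitset(method=method, bits=bits, n_bits=len(library))


def enrichment_z(hits_in_subset: int, subset_size: int, hits_total: int, total: int) -> float:
    """Two-proportion z: endpoint hit rate inside a chemotype subset vs outside.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled
    proportion. Degenerate cases (empty subset/complement, pooled
    proportion 0 or 1) return NaN; positive z means the chemotype is
    enriched for the endpoint.
    """
    if not (0 <= hits_in_subset <= subset_size <= total):
        raise ProfilingError("counts out of bounds")
    if not (hits_in_subset <= hits_total <= total):
        raise ProfilingError("total hit count inconsistent with subset hits")
    n1, n2 = subset_size, total - subset_size
    if n1 == 0 or n2 == 0:
        return math.nan
    p1 = hits_in_subset / n1
    p2 = (hits_total - hits_in_subset) / n2
    pooled = hits_total / total
    if pooled in (0.0, 1.0):
        return math.nan
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    return (p1 - p2) / se


# bin name -> half-open/closed interval per the heat-map legend; the
# shared boundary at |z| = 1 belongs to the neutral bin (-1 < z <= 1).
Z_BINS = (
    ("strong_neg", lambda z: z <= -2.0),
    ("neg", lambda z: -2.0 < z <= -1.0),
    ("neutral", lambda z: -1.0 < z <= 1.0),
    ("pos", lambda z: 1.0 < z < 2.0),
    ("strong_pos", lambda z: z >= 2.0),
)


def bin_z(z: float) -> str:
    """Assign an enrichment z-score to its colour-legend strength bin."""
    if not math.isfinite(z):
        return "not_evaluable"
    for name, pred in Z_BINS:
        if pred(z):
            return name
    raise AssertionError("z-bins must partition the real line")  # pragma: no cover


def profile_matrix(
    library: CompoundLibrary,
    alerts: AlertLibrary,
    endpoint_flags,
):
    """Chemotype x endpoint enrichment z-score matrix.

    ``endpoint_flags`` is a mapping endpoint -> {compound_id: bool}.
    For each (alert, endpoint) cell, the subset is the compounds matching
    the alert; cells also carry the subset's relative frequency.
    Returns a pandas DataFrame of z-scores (rows alerts, columns endpoints).
    """
    import pandas as pd

    evaluable = [c.compound_id for c in library if c.has_structure]
    matrix = {}
    for alert in alerts:
        patt = alert.pattern()
        member = {
            cid: library[cid].main_fragment().HasSubstructMatch(patt) for cid in evaluable
        }
        row = {}
        for endpoint, flags in endpoint_flags.items():
            ids = [cid for cid in evaluable if cid in flags]
            subset = [cid for cid in ids if member[cid]]
            row[endpoint] = enrichment_z(
                sum(bool(flags[cid]) for cid in subset),
                len(subset),
                sum(bool(flags[cid]) for cid in ids),
                len(ids),
            )
        matrix[alert.alert_id] = row
    frame = pd.DataFrame.from_dict(matrix, orient="index")
    frame.index.name = "alert_id"
    return frame
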