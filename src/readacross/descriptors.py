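"""Molecular property computation, external property tables, and z-standardisation.

Property-based similarity operates on property vectors standardised
against a reference population: z_i = (x_i - mean_i) / sd_i. Reference
means and standard deviations normally come from a large reference set
(tens of thousands of structures); a small example-calibrated reference
ships with the package fixtures and users supply their own for real work.

Descriptors are pluggable: they are computed with RDKit by default, and
any value can be overridden per compound from an external CSV (flagged
"external" in provenance), so workflows calibrated against a different
descriptor engine reproduce exactly.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .registry import Compound, CompoundLibrary

logger = logging.getLogger(__name__)


class DescriptorError(Exception):
    pass


# name -> function of an RDKit Mol. rotational_bonds uses the non-strict
# definition (single acyclic bonds between non-terminal heavy atoms,
# including ester C-O), which matches the reference workflow's counts.
_DESCRIPTOR_FUNCS = {
    "rotational_bonds": lambda m: float(
        rdMolDescriptors.CalcNumRotatableBonds(m, rdMolDescriptors.NumRotatableBondsOptions.NonStrict)
    ),
    "molecular_weight": Descriptors.MolWt,
    "complexity": Descriptors.BertzCT,
    "tpsa": Descriptors.TPSA,
    "logp": Crippen.MolLogP,
    "hbond_donors": lambda m: float(rdMolDescriptors.CalcNumHBD(m)),
    "hbond_acceptors": lambda m: float(rdMolDescriptors.CalcNumHBA(m)),
    "molar_refractivity": Crippen.MolMR,
}

SUPPORTED_PROPERTIES = tuple(_DESCRIPTOR_FUNCS)


@dataclass(frozen=True)
class PropertyVector:
    """Ordered mapping of property name -> value for one compound.

    Units: molecular_weight g/mol, tpsa Å²; rotational_bonds, complexity
    and logp are unitless.
    """

    names: tuple
    values: tuple

    def __post_init__(self):
        if len(self.names) != len(self.values):
            raise DescriptorError("names/values length mismatch")

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float], names: Optional[Sequence[str]] = None):
        names = tuple(names if names is not None else mapping)
        missing = [n for n in names if n not in mapping]
        if missing:
            raise DescriptorError(f"missing property values for {missing}")
        return cls(names=names, values=tuple(float(mapping[n]) for n in names))


@dataclass
class ReferenceStatistics:
    """Per-property mean and standard deviation of a reference population."""

    stats: dict  # property -> {"mean": float, "sd": float, "n": int}

    def __post_init__(self):
        for prop, entry in self.stats.items():
            if entry["sd"] <= 0:
                raise DescriptorError(f"non-positive sd for property {prop!r}")

    def mean(self, prop: str) -> float:
        return self._entry(prop)["mean"]

    def sd(self, prop: str) -> float:
        return self._entry(prop)["sd"]

    def _entry(self, prop: str) -> dict:
        try:
            return self.stats[prop]
        except KeyError:
            raise DescriptorError(f"no reference statistics for property {prop!r}") from None

    @classmethod
    def from_json(cls, path) -> "ReferenceStatistics":
        with open(path, encoding="utf-8") as fh:
            return cls(stats=json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.stats, fh, indent=2)


def compute_descriptors(compound: Compound, property_names: Sequence[str]) -> PropertyVector:
    """Compute the requested descriptors on the compound's main organic fragment.

    External (attached) values take precedence over computed ones.
    Structureless compounds are a hard error unless every requested
    property is already attached externally.
    """
    unknown = [p for p in property_names if p not in _DESCRIPTOR_FUNCS and p not in compound.properties]
    if unknown:
        raise DescriptorError(
            f"unknown properties {unknown}; supported: {list(SUPPORTED_PROPERTIES)}"
        )
    needs_structure = [p for p in property_names if p not in compound.properties]
    mol = None
    if needs_structure:
        compound.require_structure()
        mol = compound.main_fragment()
    values = []
    for prop in property_names:
        if prop in compound.properties:
            values.append(float(compound.properties[prop]))
        else:
            values.append(float(_DESCRIPTOR_FUNCS[prop](mol)))
    return PropertyVector(names=tuple(property_names), values=tuple(values))


def attach_property_table(library: CompoundLibrary, table) -> CompoundLibrary:
    """Attach externally supplied property values to library compounds.

    ``table`` is a CSV path or an iterable of dict rows keyed by
    ``compound_id``. External values override computed ones and are
    flagged "external". Rows for unknown ids are skipped with a warning;
    duplicate ids are last-row-wins (with a warning). Returns the same
    library for chaining.
    """
    if isinstance(table, (str, Path)):
        with open(table, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    else:
        rows = [dict(r) for r in table]
    seen: set[str] = set()
    for row in rows:
        cid = str(row.get("compound_id", "")).strip()
        compound = library.get(cid)
        if compound is None:
            logger.warning("property row for unknown compound_id %r skipped", cid)
            continue
        if cid in seen:
            logger.warning("duplicate property rows for %r; last row wins", cid)
        seen.add(cid)
        for key, raw in row.items():
            if key == "compound_id" or raw in (None, ""):
                continue
            compound.properties[key] = float(raw)
            compound.property_provenance[key] = "external"
    return library


def standardise(raw: PropertyVector, ref: ReferenceStatistics) -> PropertyVector:
    """z-score a raw property vector against reference mean/sd per property."""
    z = tuple((v - ref.mean(n)) / ref.sd(n) for n, v in zip(raw.names, raw.values))
    return PropertyVector(names=raw.names, values=z)


def fit_reference_statistics(
    raw_rows: Iterable[Mapping[str, float]],
    z_rows: Iterable[Mapping[str, float]],
    n_reference: int = 0,
    constant_sd: float = 40.0,
) -> ReferenceStatistics:
    """Back-solve reference mean/sd from paired raw and standardised vectors.

    For each property, fits z = (x - mean)/sd by least squares over the
    supplied (raw, z) pairs; needs at least two distinct raw values per
    property. A property whose raw values are all equal is unidentifiable:
    its sd is pinned to ``constant_sd`` and the mean chosen to reproduce
    the (necessarily constant) z.
    """
    raw_rows = list(raw_rows)
    z_rows = list(z_rows)
    if len(raw_rows) != len(z_rows) or len(raw_rows) < 2:
        raise DescriptorError("need >= 2 paired raw/standardised rows")
    props = list(raw_rows[0])
    stats = {}
    for prop in props:
        x = np.array([float(r[prop]) for r in raw_rows])
        z = np.array([float(r[prop]) for r in z_rows])
        if np.ptp(x) == 0:
            sd = constant_sd
            mean = x[0] - z[0] * sd
        else:
            slope, intercept = np.polyfit(x, z, 1)  # z = x/sd - mean/sd
            sd = 1.0 / slope
            mean = -intercept * sd
        stats[prop] = {"mean": float(mean), "sd": float(sd), "n": int(n_reference)}
    return ReferenceStatistics(stats=stats)
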