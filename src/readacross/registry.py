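"""Compound data model and structure/table I/O.

A compound library is substance-centric: records without a parsable
structure are first-class citizens (many regulatory inventories carry
UVCBs, polymers and ill-defined substances), and every operation that
needs a structure must reject structureless records explicitly instead
of silently skipping them.

Multi-component (dot-disconnected) SMILES are accepted; descriptor and
fingerprint computation uses the largest organic fragment, so e.g. the
sodium salt of an organic acid is profiled through its organic anion.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # parse failures are reported through our own logging


class CompoundRole(str, Enum):
    TARGET = "target"
    CANDIDATE = "candidate"
    ANALOGUE = "analogue"
    SIMILAR = "similar"


class RegistryError(Exception):
    """Raised for I/O and configuration failures in library loading."""


def validate_cas(cas_rn: object) -> bool:
    """Check a CAS Registry Number's format and checksum.

    The format is 2-7 digits, a hyphen, two digits, a hyphen and a single
    check digit; the check digit is the weighted digit sum (rightmost
    non-check digit has weight 1, increasing leftwards) modulo 10.
    Malformed input returns False, never raises.
    """
    if not isinstance(cas_rn, str):
        return False
    parts = cas_rn.strip().split("-")
    if len(parts) != 3:
        return False
    head, mid, check = parts
    if not (head.isdigit() and mid.isdigit() and check.isdigit()):
        return False
    if not (2 <= len(head) <= 7 and len(mid) == 2 and len(check) == 1):
        return False
    digits = head + mid
    weighted = sum(int(d) * w for d, w in zip(reversed(digits), range(1, len(digits) + 1)))
    return weighted % 10 == int(check)


def largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Return the largest carbon-containing fragment of a molecule.

    Falls back to the largest fragment by heavy-atom count when no
    fragment contains carbon (fully inorganic records).
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return mol
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    pool = organic or list(frags)
    return max(pool, key=lambda f: f.GetNumHeavyAtoms())


@dataclass
class Compound:
    """An identified substance, optionally carrying a structure and properties.

    ``smiles`` holds the canonical SMILES when the input parsed; the raw
    input string is preserved in ``input_smiles`` as provenance.
    ``properties`` maps property name -> value, ``property_provenance``
    maps property name -> "computed" | "external".
    """

    compound_id: str
    preferred_name: str = ""
    cas_rn: Optional[str] = None
    smiles: Optional[str] = None
    input_smiles: Optional[str] = None
    role: CompoundRole = CompoundRole.CANDIDATE
    properties: dict = field(default_factory=dict)
    property_provenance: dict = field(default_factory=dict)

    @property
    def has_structure(self) -> bool:
        return self.smiles is not None

    def mol(self) -> Chem.Mol:
        """RDKit molecule for the full record (all components)."""
        if self.smiles is None:
            raise ValueError(f"compound {self.compound_id!r} has no structure")
        return Chem.MolFromSmiles(self.smiles)

    def main_fragment(self) -> Chem.Mol:
        """Largest organic fragment, the unit used for descriptors/fingerprints."""
        return largest_organic_fragment(self.mol())

    def require_structure(self) -> None:
        if not self.has_structure:
            raise ValueError(
                f"compound {self.compound_id!r} has no parsable structure; "
                "structure-based operations are not applicable"
            )

    @classmethod
    def from_smiles(
        cls,
        compound_id: str,
        smiles: Optional[str],
        preferred_name: str = "",
        cas_rn: Optional[str] = None,
        role: CompoundRole = CompoundRole.CANDIDATE,
    ) -> "Compound":
        canonical = None
        if smiles:
            mol = Chem.MolFromSmiles(smiles)
            if mol is not None:
                canonical = Chem.MolToSmiles(mol)
            else:
                logger.warning("unparsable SMILES for %s: %r", compound_id, smiles)
        return cls(
            compound_id=compound_id,
            preferred_name=preferred_name,
            cas_rn=cas_rn or None,
            smiles=canonical,
            input_smiles=smiles or None,
            role=role,
        )


class CompoundLibrary:
    """Ordered, id-unique collection of compounds."""

    def __init__(self, compounds: Iterable[Compound] = (), source_label: str = ""):
        self.source_label = source_label
        self._by_id: dict[str, Compound] = {}
        for c in compounds:
            self.add(c)

    def add(self, compound: Compound) -> None:
        if compound.compound_id in self._by_id:
            raise RegistryError(f"duplicate compound_id {compound.compound_id!r}")
        self._by_id[compound.compound_id] = compound

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._by_id

    def __getitem__(self, compound_id: str) -> Compound:
        try:
            return self._by_id[compound_id]
        except KeyError:
            raise KeyError(f"compound_id {compound_id!r} not in library") from None

    def get(self, compound_id: str, default=None):
        return self._by_id.get(compound_id, default)

    def ids(self) -> list[str]:
        return list(self._by_id)

    def with_structures(self) -> list[Compound]:
        return [c for c in self if c.has_structure]


CSV_COLUMNS = ["compound_id", "name", "cas_rn", "smiles"]


def load_compounds(path, format: str = "smiles_csv") -> CompoundLibrary:
    """Load a compound library from ``smiles_csv``, ``sdf`` or ``json``.

    Records whose structures fail to parse are retained with
    ``has_structure`` False and logged, never dropped.
    """
    path = Path(path)
    if not path.exists():
        raise RegistryError(f"file not found: {path}")
    loaders = {"smiles_csv": _load_csv, "sdf": _load_sdf, "json": _load_json}
    try:
        loader = loaders[format]
    except KeyError:
        raise RegistryError(
            f"unknown format {format!r}; expected one of {sorted(loaders)}"
        ) from None
    return loader(path)


def _load_csv(path: Path) -> CompoundLibrary:
    lib = CompoundLibrary(source_label=str(path))
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise RegistryError(f"empty CSV (no header): {path}")
        missing = set(CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise RegistryError(f"CSV missing columns {sorted(missing)}: {path}")
        for row in reader:
            lib.add(
                Compound.from_smiles(
                    compound_id=row["compound_id"].strip(),
                    smiles=(row.get("smiles") or "").strip() or None,
                    preferred_name=(row.get("name") or "").strip(),
                    cas_rn=(row.get("cas_rn") or "").strip() or None,
                )
            )
    return lib


def _load_sdf(path: Path) -> CompoundLibrary:
    lib = CompoundLibrary(source_label=str(path))
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            # corrupt record: keep a structureless placeholder so counts match
            lib.add(Compound(compound_id=f"{path.stem}-rec{i + 1}"))
            logger.warning("unparsable SDF record %d in %s", i + 1, path)
            continue
        props = mol.GetPropsAsDict()
        cid = str(
            props.get("compound_id") or (mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else "")
        ).strip() or f"{path.stem}-rec{i + 1}"
        lib.add(
            Compound(
                compound_id=cid,
                preferred_name=str(props.get("name", "")),
                cas_rn=str(props.get("cas_rn")) if props.get("cas_rn") else None,
                smiles=Chem.MolToSmiles(mol),
                input_smiles=Chem.MolToSmiles(mol),
            )
        )
    return lib


def _load_json(path: Path) -> CompoundLibrary:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    records = payload["compounds"] if isinstance(payload, dict) else payload
    lib = CompoundLibrary(
        source_label=payload.get("source_label", str(path)) if isinstance(payload, dict) else str(path)
    )
    for rec in records:
        c = Compound.from_smiles(
            compound_id=rec["compound_id"],
            smiles=rec.get("smiles"),
            preferred_name=rec.get("name", ""),
            cas_rn=rec.get("cas_rn"),
            role=CompoundRole(rec.get("role", "candidate")),
        )
        if rec.get("properties"):
            c.properties.update(rec["properties"])
            c.property_provenance.update(
                rec.get("property_provenance", {k: "external" for k in rec["properties"]})
            )
        lib.add(c)
    return lib


def save_compounds(library: CompoundLibrary, path, format: str = "smiles_csv") -> None:
    """Write a library to ``smiles_csv`` or ``json`` (round-trip safe)."""
    path = Path(path)
    if format == "smiles_csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_COLUMNS)
            for c in library:
                writer.writerow([c.compound_id, c.preferred_name, c.cas_rn or "", c.smiles or ""])
    elif format == "json":
        payload = {
            "source_label": library.source_label,
            "compounds": [
                {
                    "compound_id": c.compound_id,
                    "name": c.preferred_name,
                    "cas_rn": c.cas_rn,
                    "smiles": c.smiles,
                    "role": c.role.value,
                    "properties": c.properties,
                    "property_provenance": c.property_provenance,
                }
                for c in library
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
    else:
        raise RegistryError(f"unknown save format {format!r}")
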