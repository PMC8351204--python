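"""Structure- and property-based similarity and Analogue Quality.

Structure similarity is the Tanimoto coefficient |A∩B|/|A∪B| over
fingerprint bit sets. Property similarity is computed on standardised
property vectors, either as

    PearsonSimilarity  = (1 + r) / 2
    EuclideanSimilarity = 1 / (1 + d)      with d the Euclidean distance,

and the Analogue Quality (AQ) is the geometric mean of any N similarity
measures — conventionally two structure fingerprints plus one property
measure. All internal arithmetic is full precision; reported tables are
rounded half-up to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys

from .descriptors import PropertyVector, ReferenceStatistics, compute_descriptors, standardise
from .registry import Compound, CompoundLibrary

# the reference system caps how permissive a similarity search may be
TANIMOTO_SEARCH_FLOOR = 0.65
DEFAULT_SEARCH_THRESHOLD = 0.70


class SimilarityError(Exception):
    pass


def round_report(value: float, ndigits: int = 2) -> float:
    """Round half-up for table reporting (0.005 -> 0.01), as in the worked tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FingerprintBitset:
    """A fingerprint as an explicit set of on-bit indices."""

    method: str
    bits: frozenset
    n_bits: int

    def __post_init__(self):
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.n_bits):
            raise SimilarityError("bit index out of range")


def compute_fingerprint(compound: Compound, method: str = "topological_path") -> FingerprintBitset:
    """Fingerprint the compound's main organic fragment.

    Methods: ``topological_path`` (RDKit path fingerprint, 2048 bits),
    ``structural_keys_166`` (166 MACCS-type structural keys), or
    ``chemotype_library``/``custom_smarts`` via
    :func:`readacross.profiling.smarts_fingerprint`.
    """
    compound.require_structure()
    mol = compound.main_fragment()
    if method == "topological_path":
        bv = Chem.RDKFingerprint(mol, fpSize=2048)
        return FingerprintBitset(method=method, bits=frozenset(bv.GetOnBits()), n_bits=2048)
    if method == "structural_keys_166":
        bv = MACCSkeys.GenMACCSKeys(mol)
        return FingerprintBitset(method=method, bits=frozenset(bv.GetOnBits()), n_bits=bv.GetNumBits())
    if method in ("chemotype_library", "custom_smarts"):
        from .profiling import default_alert_library, smarts_fingerprint

        return smarts_fingerprint(compound, default_alert_library(), method=method)
    raise SimilarityError(f"unknown fingerprint method {method!r}")


def tanimoto(a: FingerprintBitset, b: FingerprintBitset) -> float:
    """Tanimoto coefficient |A∩B|/|A∪B|; 1.0 when both bitsets are empty.

    The empty/empty convention treats two structures that set no bits as
    indistinguishable to the fingerprint, hence maximally similar.
    """
    if a.method != b.method or a.n_bits != b.n_bits:
        raise SimilarityError(
            f"fingerprint mismatch: {a.method}/{a.n_bits} vs {b.method}/{b.n_bits}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def _check_same_properties(x: PropertyVector, y: PropertyVector) -> None:
    if x.names != y.names:
        raise SimilarityError(f"property sets differ: {x.names} vs {y.names}")


def pearson_similarity(x: PropertyVector, y: PropertyVector) -> float:
    """(1 + r)/2 with r the sample Pearson correlation of the two vectors.

    Requires at least three properties and non-constant vectors; a
    zero-variance vector leaves the correlation undefined and raises.
    """
    _check_same_properties(x, y)
    xv, yv = x.as_array(), y.as_array()
    if xv.size < 3:
        raise SimilarityError("pearson similarity needs >= 3 properties")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise SimilarityError(
            "pearson correlation is undefined for a constant property vector "
            "(zero variance); drop the constant property or use the Euclidean measure"
        )
    r = float(np.corrcoef(xv, yv)[0, 1])
    return (1.0 + r) / 2.0


def euclidean_similarity(x: PropertyVector, y: PropertyVector) -> tuple:
    """(distance, 1/(1+distance)) on standardised property vectors."""
    _check_same_properties(x, y)
    d = float(np.linalg.norm(x.as_array() - y.as_array()))
    return d, 1.0 / (1.0 + d)


def analogue_quality(measures: Sequence[float]) -> float:
    """Geometric mean of N similarity measures, each in [0, 1]."""
    if len(measures) == 0:
        raise SimilarityError("analogue quality of an empty measure list is undefined")
    for m in measures:
        if not (0.0 <= m <= 1.0):
            raise SimilarityError(f"similarity measure {m} outside [0, 1]")
    if any(m == 0.0 for m in measures):
        return 0.0
    return math.exp(sum(math.log(m) for m in measures) / len(measures))


@dataclass
class SimilarityProfile:
    """All pairwise measures between a target and one candidate."""

    target_id: str
    candidate_id: str
    tanimoto: dict = field(default_factory=dict)  # method -> value
    euclidean_distance: float = 0.0
    euclidean_similarity: float = 1.0
    pearson_similarity: float = 1.0
    analogue_quality: dict = field(default_factory=dict)  # "euclidean"/"pearson" -> AQ
    error: Optional[str] = None

    def report_row(self) -> dict:
        """2-dp rounded row mirroring the exported similarity tables."""
        row = {"target_id": self.target_id, "candidate_id": self.candidate_id}
        if self.error:
            row["error"] = self.error
            return row
        for method, value in self.tanimoto.items():
            row[f"tanimoto_{method}"] = round_report(value)
        row["euclidean_distance"] = round_report(self.euclidean_distance)
        row["euclidean_similarity"] = round_report(self.euclidean_similarity)
        row["pearson_similarity"] = round_report(self.pearson_similarity)
        for variant, value in self.analogue_quality.items():
            row[f"aq_{variant}"] = round_report(value)
        return row


def profile_from_components(
    target_id: str,
    candidate_id: str,
    tanimotos: Mapping[str, float],
    target_z: PropertyVector,
    candidate_z: PropertyVector,
) -> SimilarityProfile:
    """Assemble a full profile from fingerprint Tanimotos and standardised vectors.

    Both AQ variants are computed over the structure Tanimotos plus the
    respective property-based measure (geometric mean of N = len(tanimotos)+1).
    """
    dist, esim = euclidean_similarity(target_z, candidate_z)
    psim = pearson_similarity(target_z, candidate_z)
    structure = list(tanimotos.values())
    return SimilarityProfile(
        target_id=target_id,
        candidate_id=candidate_id,
        tanimoto=dict(tanimotos),
        euclidean_distance=dist,
        euclidean_similarity=esim,
        pearson_similarity=psim,
        analogue_quality={
            "euclidean": analogue_quality(structure + [esim]),
            "pearson": analogue_quality(structure + [psim]),
        },
    )


def similarity_search(
    query: Compound,
    library: CompoundLibrary,
    method: str = "topological_path",
    threshold: float = DEFAULT_SEARCH_THRESHOLD,
) -> list:
    """All library hits with Tanimoto >= threshold, best first.

    Thresholds below the 0.65 floor are rejected: similarity hits below
    that level are too weak to support analogue reasoning in this
    workflow. Ties are broken by compound_id so rankings are deterministic.
    Structureless library records are skipped (they cannot be fingerprinted).
    """
    if not (TANIMOTO_SEARCH_FLOOR <= threshold <= 1.0):
        raise SimilarityError(
            f"similarity threshold {threshold} outside [{TANIMOTO_SEARCH_FLOOR}, 1.0]; "
            f"searches below the {TANIMOTO_SEARCH_FLOOR} floor are not supported"
        )
    qfp = compute_fingerprint(query, method)
    hits = []
    for compound in library.with_structures():
        t = tanimoto(qfp, compute_fingerprint(compound, method))
        if t >= threshold:
            hits.append((compound, t))
    hits.sort(key=lambda pair: (-pair[1], pair[0].compound_id))
    return hits


def pairwise_profile(
    target: Compound,
    candidates: Sequence[Compound],
    fp_methods: Sequence[str] = ("topological_path", "structural_keys_166"),
    properties: Sequence[str] = ("rotational_bonds", "molecular_weight", "complexity", "tpsa", "logp"),
    ref: Optional[ReferenceStatistics] = None,
    external_tanimoto: Optional[Mapping[str, Mapping[str, float]]] = None,
    external_z: Optional[Mapping[str, PropertyVector]] = None,
) -> list:
    """One complete SimilarityProfile per candidate.

    By default fingerprints and descriptors are computed with the bundled
    toolkit; ``external_tanimoto`` (candidate_id -> method -> value) and
    ``external_z`` (compound_id -> standardised PropertyVector) override
    computation so externally exported similarity tables reproduce
    exactly. A candidate that cannot be profiled yields a profile with
    its ``error`` field set rather than being silently dropped.
    """
    external_tanimoto = external_tanimoto or {}
    external_z = external_z or {}

    def z_vector(compound: Compound) -> PropertyVector:
        if compound.compound_id in external_z:
            return external_z[compound.compound_id]
        if ref is None:
            raise SimilarityError("reference statistics required to standardise computed properties")
        return standardise(compute_descriptors(compound, properties), ref)

    target_z = z_vector(target)
    target_fps = {}
    profiles = []
    for cand in candidates:
        try:
            tans = {}
            for method in fp_methods:
                ext = external_tanimoto.get(cand.compound_id, {})
                if method in ext:
                    tans[method] = float(ext[method])
                else:
                    if method not in target_fps:
                        target_fps[method] = compute_fingerprint(target, method)
                    tans[method] = tanimoto(target_fps[method], compute_fingerprint(cand, method))
            profiles.append(
                profile_from_components(
                    target.compound_id, cand.compound_id, tans, target_z, z_vector(cand)
                )
            )
        except Exception as exc:  # per-candidate error entry, not silent omission
            profiles.append(
                SimilarityProfile(
                    target_id=target.compound_id, candidate_id=cand.compound_id, error=str(exc)
                )
            )
    return profiles


def export_profiles_csv(profiles: Iterable[SimilarityProfile], path) -> None:
    """Write profiles as a CSV table mirroring the exported similarity sheets."""
    import csv as _csv

    rows = [p.report_row() for p in profiles]
    fields: list[str] = []
    for row in rows:
        for key in row:
            if key not in fields:
                fields.append(key)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = _csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(rows)
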