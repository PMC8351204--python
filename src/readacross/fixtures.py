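"""Worked-example fixtures and a seeded synthetic homologue generator.

Two curated fixtures reproduce the guided read-across worked examples:

* ``parabens`` — four alkyl parabens with the exported raw property
  table, the standardised property vectors and the per-fingerprint
  Tanimoto coefficients attached as external values. Propyl paraben is
  the target.
* ``hair_dyes`` — a nitroaromatic hair-dye target with three candidates.
  The printed similarity components (Euclidean distance/similarity,
  Pearson similarity, ToxPrint and RDKit-path Tanimotos) and the three
  90-day study records (NOAEL 17/50/80 mg/kg-bw/day, sources
  SCCS/SCC/SCCP, MINIS grade 4, opinion 4) ship as attached externals.
  The hair-dye SMILES are synthetic surrogate structures (the source
  tables print no structures): plausible nitro-phenylenediamine
  chemistry chosen so the bundled alert library reproduces the
  published category pattern, never used to recompute similarities.

``random_homologues`` builds a seed-deterministic alkyl/aryl homologue
series with planted NOAELs for stress-testing search and neighbour
recovery against brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .descriptors import PropertyVector, ReferenceStatistics, fit_reference_statistics
from .registry import Compound, CompoundLibrary, CompoundRole
from .reliability import StudyRecord
from .similarity import SimilarityProfile, analogue_quality

PARABEN_PROPERTIES = ("rotational_bonds", "molecular_weight", "complexity", "tpsa", "logp")

# Exported data table: per-compound fingerprint Tanimoto (vs the propyl
# target) and raw property values from the external descriptor engine.
_PARABENS = {
    "CMS-2411": {
        "name": "Propyl paraben", "cas": "94-13-3", "smiles": "CCCOC(=O)c1ccc(O)cc1",
        "tanimoto": {"maccs": 1.00, "rdkit": 1.00, "toxprint": 1.00, "liver_biopath": 1.00},
        "raw": (4, 180.2, 159.6, 46.5, 2.32),
        "z": (-0.19, -0.56, -0.51, -0.27, -0.08),
    },
    "CMS-216": {
        "name": "Butyl paraben", "cas": "94-26-8", "smiles": "CCCCOC(=O)c1ccc(O)cc1",
        "tanimoto": {"maccs": 0.94, "rdkit": 0.94, "toxprint": 0.91, "liver_biopath": 0.90},
        "raw": (5, 194.2, 171.4, 46.5, 2.87),
        "z": (-0.08, -0.50, -0.49, -0.27, 0.09),
    },
    "CMS-2412": {
        "name": "Ethyl paraben", "cas": "120-47-8", "smiles": "CCOC(=O)c1ccc(O)cc1",
        "tanimoto": {"maccs": 0.93, "rdkit": 0.92, "toxprint": 0.80, "liver_biopath": 0.67},
        "raw": (3, 166.2, 147.9, 46.5, 1.98),
        "z": (-0.31, -0.62, -0.53, -0.27, -0.18),
    },
    "CMS-2413": {
        "name": "Methyl paraben", "cas": "99-76-3", "smiles": "COC(=O)c1ccc(O)cc1",
        "tanimoto": {"maccs": 0.81, "rdkit": 0.82, "toxprint": 0.70, "liver_biopath": 0.50},
        "raw": (2, 152.1, 136.3, 46.5, 1.55),
        "z": (-0.42, -0.68, -0.56, -0.27, -0.31),
    },
}

# Hair-dye candidate components: Tanimotos plus property-based measures
# as printed in the exported similarity table. SMILES are synthetic
# surrogates (see module docstring).
_HAIR_DYES = {
    "CMS-23938": {
        "name": "HC Red No. 7", "cas": "24905-87-1",
        "smiles": "OCCNc1ccc(N)cc1[N+](=O)[O-]",  # synthetic surrogate structure
        "tanimoto": {"toxprint": 1.0, "rdkit": 1.0},
        "euclidean_distance": 0.0, "euclidean_similarity": 1.0, "pearson_similarity": 1.0,
    },
    "CMS-60520": {
        "name": "HC Violet No. 1", "cas": None,
        "smiles": "OCCNc1ccc(NCCO)cc1[N+](=O)[O-]",  # synthetic surrogate structure
        "tanimoto": {"toxprint": 0.85, "rdkit": 0.77},
        "euclidean_distance": 0.13, "euclidean_similarity": 0.88, "pearson_similarity": 0.999,
    },
    "CMS-43204": {
        "name": "HC Violet No. 2", "cas": None,
        "smiles": "Nc1cc([N+](=O)[O-])ccc1O",  # synthetic surrogate structure
        "tanimoto": {"toxprint": 0.65, "rdkit": 0.72},
        "euclidean_distance": 1.05, "euclidean_similarity": 0.49, "pearson_similarity": 0.95,
    },
    "CMS-72054": {
        "name": "HC Blue No. 11", "cas": None,
        "smiles": "Nc1ccc([N+](=O)[O-])cc1N",  # synthetic surrogate structure
        "tanimoto": {"toxprint": 0.68, "rdkit": 0.75},
        "euclidean_distance": 1.08, "euclidean_similarity": 0.48, "pearson_similarity": 0.90,
    },
}

_HAIR_DYE_STUDIES = [
    dict(
        study_id="S-60520", compound_id="CMS-60520", species="rat", strain="SD",
        duration="90d", route="oral-gavage/intubation", dose_range="50-500 mg/kg-bw/day",
        study_design="90-day SD rat, oral-gavage/intubation; 50-500 mg/kg-bw/day",
        study_results=("clinical signs, clinical chemistry, organ weight decrease, "
                       "leading to liver pathology at higher dose"),
        noael=17.0, loael=50.0, source="SCCS", minis_grade_override=4, opinion_score=4,
    ),
    dict(
        study_id="S-43204", compound_id="CMS-43204", species="rat", strain="SD",
        duration="90d", route="oral-gavage/intubation", dose_range="50-800 mg/kg-bw/day",
        study_design="90-day SD rat, oral-gavage/intubation; 50-800 mg/kg-bw/day",
        study_results="no adverse effect", noael=50.0, loael=None,
        source="SCC", minis_grade_override=4, opinion_score=4,
    ),
    dict(
        study_id="S-72054", compound_id="CMS-72054", species="rat", strain="Wistar",
        duration="90d", route="oral-gavage/intubation", dose_range="50-160 mg/kg-bw/day",
        study_design="90-day Wistar rat, oral-gavage/intubation; 50-160 mg/kg-bw/day",
        study_results="no adverse effect", noael=80.0, loael=None,
        source="SCCP", minis_grade_override=4, opinion_score=4,
    ),
]


@dataclass
class FixtureBundle:
    """A library plus its attached external tables, ready for the workflow."""

    library: CompoundLibrary
    target_id: str
    fp_methods: tuple
    properties: tuple = ()
    reference: Optional[ReferenceStatistics] = None
    external_tanimoto: dict = field(default_factory=dict)  # id -> method -> value
    external_z: dict = field(default_factory=dict)  # id -> PropertyVector
    external_profiles: Optional[list] = None  # precomputed SimilarityProfile rows
    study_records: list = field(default_factory=list)
    noaels: dict = field(default_factory=dict)  # id -> NOAEL (mg/kg-bw/day)

    def candidates(self) -> list:
        return [c for c in self.library if c.compound_id != self.target_id]


def paraben_reference_statistics() -> ReferenceStatistics:
    """Reference mean/sd back-solved from the paraben raw/standardised pairs.

    Example-calibrated: TPSA is constant across the four parabens, so its
    sd is pinned by convention (see fit_reference_statistics). Real
    analyses should standardise against a large reference population.
    """
    raw_rows = [dict(zip(PARABEN_PROPERTIES, rec["raw"])) for rec in _PARABENS.values()]
    z_rows = [dict(zip(PARABEN_PROPERTIES, rec["z"])) for rec in _PARABENS.values()]
    return fit_reference_statistics(raw_rows, z_rows)


def _paraben_bundle() -> FixtureBundle:
    lib = CompoundLibrary(source_label="parabens fixture")
    for cid, rec in _PARABENS.items():
        c = Compound.from_smiles(cid, rec["smiles"], rec["name"], rec["cas"])
        c.role = CompoundRole.TARGET if cid == "CMS-2411" else CompoundRole.CANDIDATE
        for prop, value in zip(PARABEN_PROPERTIES, rec["raw"]):
            c.properties[prop] = float(value)
            c.property_provenance[prop] = "external"
        lib.add(c)
    return FixtureBundle(
        library=lib,
        target_id="CMS-2411",
        fp_methods=("rdkit", "toxprint"),
        properties=PARABEN_PROPERTIES,
        reference=paraben_reference_statistics(),
        external_tanimoto={cid: dict(rec["tanimoto"]) for cid, rec in _PARABENS.items()},
        external_z={
            cid: PropertyVector(names=PARABEN_PROPERTIES, values=tuple(rec["z"]))
            for cid, rec in _PARABENS.items()
        },
    )


def _hair_dye_bundle() -> FixtureBundle:
    lib = CompoundLibrary(source_label="hair dyes fixture (synthetic surrogate structures)")
    profiles = []
    for cid, rec in _HAIR_DYES.items():
        c = Compound.from_smiles(cid, rec["smiles"], rec["name"], rec["cas"])
        c.role = CompoundRole.TARGET if cid == "CMS-23938" else CompoundRole.CANDIDATE
        lib.add(c)
        structure = list(rec["tanimoto"].values())
        profiles.append(
            SimilarityProfile(
                target_id="CMS-23938",
                candidate_id=cid,
                tanimoto=dict(rec["tanimoto"]),
                euclidean_distance=rec["euclidean_distance"],
                euclidean_similarity=rec["euclidean_similarity"],
                pearson_similarity=rec["pearson_similarity"],
                analogue_quality={
                    "euclidean": analogue_quality(structure + [rec["euclidean_similarity"]]),
                    "pearson": analogue_quality(structure + [rec["pearson_similarity"]]),
                },
            )
        )
    return FixtureBundle(
        library=lib,
        target_id="CMS-23938",
        fp_methods=("rdkit", "toxprint"),
        external_tanimoto={cid: dict(rec["tanimoto"]) for cid, rec in _HAIR_DYES.items()},
        external_profiles=profiles,
        study_records=[StudyRecord(**kw) for kw in _HAIR_DYE_STUDIES],
        noaels={"CMS-60520": 17.0, "CMS-43204": 50.0, "CMS-72054": 80.0},
    )


def _random_homologue_bundle(seed: int, n: int) -> FixtureBundle:
    """Seeded alkylbenzene/alkylphenol homologue series with planted NOAELs.

    Chain-length and substituent choices are drawn from a seeded RNG, so
    identical (seed, n) pairs produce byte-identical libraries. Pairwise
    similarity structure is 'planted' in the sense that neighbouring
    chain lengths share most of their path fingerprint.
    """
    rng = np.random.default_rng(seed)
    scaffolds = [
        ("benzene", "c1ccccc1"),
        ("phenol", "c1ccc(O)cc1"),
        ("aniline", "c1ccc(N)cc1"),
    ]
    lib = CompoundLibrary(source_label=f"random homologues (seed={seed})")
    noaels = {}
    for i in range(n):
        name, core = scaffolds[int(rng.integers(0, len(scaffolds)))]
        chain = int(rng.integers(1, 9))
        smiles = "C" * chain + core
        cid = f"HOM-{i + 1:03d}"
        compound = Compound.from_smiles(cid, smiles, f"{chain}-alkyl {name}")
        compound.role = CompoundRole.TARGET if i == 0 else CompoundRole.CANDIDATE
        lib.add(compound)
        noaels[cid] = float(np.round(rng.lognormal(mean=3.0, sigma=0.8), 1))
    return FixtureBundle(
        library=lib,
        target_id="HOM-001",
        fp_methods=("topological_path",),
        properties=PARABEN_PROPERTIES,
        noaels=noaels,
    )


def generate_fixture_library(kind: str, seed: int = 0, n: int = 10) -> FixtureBundle:
    """Build one of the bundled fixture libraries.

    Kinds: ``parabens``, ``hair_dyes`` (seed-independent worked-example
    bundles) or ``random_homologues`` (seeded synthetic series of ``n``
    compounds).
    """
    if kind == "parabens":
        return _paraben_bundle()
    if kind == "hair_dyes":
        return _hair_dye_bundle()
    if kind == "random_homologues":
        return _random_homologue_bundle(seed, n)
    raise ValueError(f"unknown fixture kind {kind!r}; expected parabens/hair_dyes/random_homologues")
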