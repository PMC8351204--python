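"""Tanimoto, property-based similarity, analogue quality, and search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from readacross import (
    Compound,
    CompoundLibrary,
    FingerprintBitset,
    PropertyVector,
    analogue_quality,
    compute_fingerprint,
    euclidean_similarity,
    pairwise_profile,
    pearson_similarity,
    similarity_search,
    tanimoto,
)
from readacross.similarity import SimilarityError, round_report


def bits(*idx, n=16, method="m"):
    return FingerprintBitset(method=method, bits=frozenset(idx), n_bits=n)


class TestTanimoto:
    def test_identical_and_disjoint(self):
        assert tanimoto(bits(1, 2, 3), bits(1, 2, 3)) == 1.0
        assert tanimoto(bits(1, 2), bits(3, 4)) == 0.0

    def test_partial_overlap(self):
        # |{1,2,3} ∩ {2,3,4}| = 2, union 4
        assert tanimoto(bits(1, 2, 3), bits(2, 3, 4)) == 0.5

    def test_empty_empty_convention(self):
        assert tanimoto(bits(), bits()) == 1.0

    def test_method_mismatch_rejected(self):
        with pytest.raises(SimilarityError, match="mismatch"):
            tanimoto(bits(1, method="a"), bits(1, method="b"))

    @given(
        a=st.sets(st.integers(0, 31)),
        b=st.sets(st.integers(0, 31)),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetry_and_bounds(self, a, b):
        fa, fb = bits(*a, n=32), bits(*b, n=32)
        t = tanimoto(fa, fb)
        assert t == tanimoto(fb, fa)
        assert 0.0 <= t <= 1.0


def vec(*vals, names=None):
    names = names or tuple(f"p{i}" for i in range(len(vals)))
    return PropertyVector(tuple(names), tuple(float(v) for v in vals))


class TestPropertySimilarity:
    def test_pearson_extremes(self):
        x = vec(1, 2, 3, 4)
        assert pearson_similarity(x, x) == pytest.approx(1.0)
        y = vec(-1, -2, -3, -4)
        assert pearson_similarity(x, y) == pytest.approx(0.0)

    def test_pearson_constant_vector_is_explicit_error(self):
        with pytest.raises(SimilarityError, match="zero variance"):
            pearson_similarity(vec(1, 2, 3), vec(5, 5, 5))

    def test_pearson_requires_three_properties(self):
        with pytest.raises(SimilarityError, match=">= 3"):
            pearson_similarity(vec(1, 2), vec(2, 1))

    def test_euclidean_identity_and_mismatch(self):
        x = vec(1, 2, 3)
        assert euclidean_similarity(x, x) == (0.0, 1.0)
        with pytest.raises(SimilarityError, match="property sets differ"):
            euclidean_similarity(x, vec(1, 2, 3, names=("a", "b", "c")))

    @pytest.mark.parametrize(
        "other,distance,similarity",
        [
            # standardised paraben vectors: butyl, ethyl, methyl vs propyl
            ((-0.08, -0.50, -0.49, -0.27, 0.09), 0.21, 0.82),
            ((-0.31, -0.62, -0.53, -0.27, -0.18), 0.17, 0.86),
            ((-0.42, -0.68, -0.56, -0.27, -0.31), 0.35, 0.74),
        ],
    )
    def test_paraben_euclidean_values(self, other, distance, similarity):
        propyl = vec(-0.19, -0.56, -0.51, -0.27, -0.08)
        d, s = euclidean_similarity(propyl, vec(*other))
        assert d == pytest.approx(distance, abs=0.005)
        assert s == pytest.approx(similarity, abs=0.005)

    def test_paraben_pearson_values(self):
        propyl = vec(-0.19, -0.56, -0.51, -0.27, -0.08)
        butyl = vec(-0.08, -0.50, -0.49, -0.27, 0.09)
        methyl = vec(-0.42, -0.68, -0.56, -0.27, -0.31)
        assert pearson_similarity(propyl, butyl) == pytest.approx(0.99, abs=0.005)
        assert pearson_similarity(propyl, methyl) == pytest.approx(0.93, abs=0.005)


class TestAnalogueQuality:
    @pytest.mark.parametrize(
        "measures,expected",
        [
            ((1.0, 1.0, 1.0), 1.0),
            ((0.91, 0.94, 0.82), 0.89),   # butyl paraben, Euclidean variant
            ((0.85, 0.77, 0.88), 0.83),   # hair-dye analogue, Euclidean variant
            ((0.5, 0.0, 0.9), 0.0),
        ],
    )
    def test_worked_values(self, measures, expected):
        assert analogue_quality(measures) == pytest.approx(expected, abs=0.005)

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(SimilarityError):
            analogue_quality([])
        with pytest.raises(SimilarityError):
            analogue_quality([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_bounded_by_min_and_max(self, measures):
        aq = analogue_quality(measures)
        assert min(measures) - 1e-12 <= aq <= max(measures) + 1e-12

    @given(st.floats(0.0, 1.0), st.integers(1, 6))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_identity_on_copies(self, v, n):
        assert analogue_quality([v] * n) == pytest.approx(v, abs=1e-12)

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5),
        st.floats(0.01, 1.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_each_measure(self, measures, bumped):
        base = analogue_quality(measures)
        raised = list(measures)
        raised[0] = max(raised[0], bumped)
        assert analogue_quality(raised) >= base - 1e-12


def _alkylbenzene_library(max_chain=10):
    return CompoundLibrary(
        Compound.from_smiles(f"ALK-{n:02d}", "C" * n + "c1ccccc1") for n in range(1, max_chain + 1)
    )


class TestSimilaritySearch:
    def test_query_in_library_ranks_first(self):
        lib = _alkylbenzene_library()
        query = lib["ALK-05"]
        hits = similarity_search(query, lib, threshold=0.65)
        assert hits[0][0].compound_id == "ALK-05"
        assert hits[0][1] == 1.0

    def test_threshold_one_without_duplicate_is_empty(self):
        lib = _alkylbenzene_library()
        query = Compound.from_smiles("q", "c1ccc(cc1)C(F)(F)F")
        assert similarity_search(query, lib, threshold=1.0) == []

    def test_threshold_floor_enforced(self):
        lib = _alkylbenzene_library()
        with pytest.raises(SimilarityError, match="0.65"):
            similarity_search(lib["ALK-01"], lib, threshold=0.5)

    def test_hits_match_brute_force_oracle(self):
        lib = _alkylbenzene_library()
        query = lib["ALK-06"]
        hits = similarity_search(query, lib, threshold=0.7)
        # independent oracle: full pairwise Tanimoto matrix, filtered by hand
        qfp = compute_fingerprint(query, "topological_path")
        expected = {
            c.compound_id: tanimoto(qfp, compute_fingerprint(c, "topological_path"))
            for c in lib
        }
        expected = {cid: t for cid, t in expected.items() if t >= 0.7}
        assert {c.compound_id: t for c, t in hits} == expected
        # descending similarity, id tiebreak
        ranks = [(t, c.compound_id) for c, t in hits]
        assert ranks == sorted(ranks, key=lambda r: (-r[0], r[1]))


class TestPairwiseProfile:
    def test_self_profile_is_all_ones(self, paraben_bundle):
        target = paraben_bundle.library["CMS-2411"]
        [profile] = pairwise_profile(
            target,
            [target],
            fp_methods=paraben_bundle.fp_methods,
            properties=paraben_bundle.properties,
            external_tanimoto=paraben_bundle.external_tanimoto,
            external_z=paraben_bundle.external_z,
        )
        assert profile.euclidean_distance == 0.0
        assert profile.euclidean_similarity == 1.0
        assert profile.pearson_similarity == pytest.approx(1.0)
        assert all(v == 1.0 for v in profile.tanimoto.values())
        assert all(v == pytest.approx(1.0) for v in profile.analogue_quality.values())

    def test_paraben_profiles_reproduce_exported_table(self, paraben_bundle):
        target = paraben_bundle.library["CMS-2411"]
        profiles = pairwise_profile(
            target,
            paraben_bundle.candidates(),
            fp_methods=paraben_bundle.fp_methods,
            properties=paraben_bundle.properties,
            external_tanimoto=paraben_bundle.external_tanimoto,
            external_z=paraben_bundle.external_z,
        )
        by_id = {p.candidate_id: p for p in profiles}
        expected = {
            # id: (distance, euclid sim, pearson sim, AQ pearson, AQ euclid)
            "CMS-216": (0.21, 0.82, 0.99, 0.95, 0.89),
            "CMS-2412": (0.17, 0.86, 0.99, 0.90, 0.86),
            "CMS-2413": (0.35, 0.74, 0.93, 0.81, 0.75),
        }
        for cid, (d, es, ps, aqp, aqe) in expected.items():
            p = by_id[cid]
            assert p.euclidean_distance == pytest.approx(d, abs=0.005)
            assert p.euclidean_similarity == pytest.approx(es, abs=0.005)
            assert p.pearson_similarity == pytest.approx(ps, abs=0.005)
            assert p.analogue_quality["pearson"] == pytest.approx(aqp, abs=0.005)
            assert p.analogue_quality["euclidean"] == pytest.approx(aqe, abs=0.005)

    def test_hair_dye_profiles_reproduce_printed_aq(self, hair_dye_bundle):
        by_id = {p.candidate_id: p for p in hair_dye_bundle.external_profiles}
        expected = {
            "CMS-60520": (0.83, 0.87),
            "CMS-43204": (0.61, 0.76),
            "CMS-72054": (0.63, 0.77),
        }
        for cid, (aqe, aqp) in expected.items():
            assert by_id[cid].analogue_quality["euclidean"] == pytest.approx(aqe, abs=0.005)
            assert by_id[cid].analogue_quality["pearson"] == pytest.approx(aqp, abs=0.005)

    def test_missing_property_yields_error_entry_not_omission(self):
        target = Compound.from_smiles("t", "CCO")
        broken = Compound(compound_id="broken")  # no structure, no externals
        profiles = pairwise_profile(target, [broken], ref=None,
                                    external_z={"t": vec(0, 0, 0)})
        assert len(profiles) == 1
        assert profiles[0].error is not None


class TestMeasureSymmetry:
    @pytest.mark.parametrize("seed", range(5))
    def test_property_measures_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        x = vec(*rng.normal(size=5))
        y = vec(*rng.normal(size=5))
        assert pearson_similarity(x, y) == pytest.approx(pearson_similarity(y, x))
        assert euclidean_similarity(x, y) == pytest.approx(euclidean_similarity(y, x))


def test_round_report_is_half_up():
    assert round_report(0.005) == 0.01
    assert round_report(0.745) == 0.75
    assert round_report(0.744999) == 0.74
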