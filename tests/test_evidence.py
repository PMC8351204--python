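"""Weight-of-evidence: joint probability, DST combination, NOAEL bounds."""

import numpy as np
import pytest
from scipy import stats as scipy_stats

from readacross import (
    Compound,
    CompoundLibrary,
    EvidenceRow,
    MassFunction,
    Qualification,
    belief_plausibility,
    build_mass,
    default_alert_library,
    dst_combine,
    joint_reliability,
    nearest_neighbor_noaels,
    noael_bounds,
    qualify_analogue,
    read_across_interval,
)
from readacross.evidence import VACUOUS_MASS, EvidenceError
from readacross.similarity import round_report


class TestJointReliability:
    def test_perfect_evidence(self):
        assert joint_reliability(1.0, 1.0) == 1.0

    def test_worked_example_point_estimates(self):
        # full-precision AQ x SRL, reported at 2 dp
        assert round_report(joint_reliability(0.8320, 0.9)) == 0.75
        assert round_report(joint_reliability(0.6118, 0.9)) == 0.55
        assert round_report(joint_reliability(0.6258, 0.9)) == 0.56

    def test_out_of_range_rejected(self):
        with pytest.raises(EvidenceError):
            joint_reliability(1.1, 0.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_bounded_by_min_of_inputs(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            aq, srl = rng.uniform(0, 1, 2)
            assert joint_reliability(aq, srl) <= min(aq, srl) + 1e-12


class TestQualification:
    @pytest.mark.parametrize(
        "aq,srl,expected",
        [
            (0.83, 0.9, Qualification.QUALIFIED),
            (0.61, 0.9, Qualification.NOT_FEASIBLE),   # similar, not analogue
            (0.9, 0.65, Qualification.NOT_FEASIBLE),   # reliable structure, weak study
            (0.9, 0.4, Qualification.DATA_UNUSABLE),   # below the hard floor
            (0.3, 0.4, Qualification.DATA_UNUSABLE),   # hard floor takes precedence
            (0.7, 0.7, Qualification.QUALIFIED),       # floors are inclusive
        ],
    )
    def test_floor_logic(self, aq, srl, expected):
        qualification, rationale = qualify_analogue(aq, srl)
        assert qualification is expected
        assert rationale

    def test_accepts_evidence_row(self):
        row = EvidenceRow(compound_id="c", role="candidate",
                          analogue_quality=0.83, study_reliability=0.9)
        assert qualify_analogue(row)[0] is Qualification.QUALIFIED
        with pytest.raises(EvidenceError, match="missing"):
            qualify_analogue(EvidenceRow(compound_id="c", role="candidate"))


class TestMassFunctions:
    def test_build_mass_extremes(self):
        assert build_mass(1.0, 1.0).as_tuple() == (1.0, 0.0, 0.0)
        assert build_mass(0.7, 0.0).as_tuple() == (0.0, 0.0, 1.0)  # vacuous

    def test_build_mass_arithmetic(self):
        m = build_mass(0.83, 0.9)
        assert m.reliable == pytest.approx(0.747)
        assert m.not_reliable == pytest.approx(0.153)
        assert m.either == pytest.approx(0.1)

    def test_mass_must_normalise(self):
        with pytest.raises(EvidenceError, match="sum to 1"):
            MassFunction(0.5, 0.5, 0.5)

    def test_vacuous_identity(self):
        m = build_mass(0.83, 0.9)
        combined = dst_combine(m, VACUOUS_MASS)
        assert combined.as_tuple() == pytest.approx(m.as_tuple())

    def test_hand_computed_combination(self):
        m1 = MassFunction(0.747, 0.153, 0.1)
        m2 = MassFunction(0.81, 0.09, 0.1)
        # conflict = 0.747*0.09 + 0.153*0.81 = 0.19116; normaliser 0.80884
        combined = dst_combine(m1, m2)
        assert combined.reliable == pytest.approx(0.940, abs=0.001)
        assert combined.not_reliable == pytest.approx(0.047, abs=0.001)
        assert combined.either == pytest.approx(0.012, abs=0.001)

    def test_total_conflict_rejected(self):
        with pytest.raises(EvidenceError, match="conflict"):
            dst_combine(MassFunction(1.0, 0.0, 0.0), MassFunction(0.0, 1.0, 0.0))

    def test_belief_plausibility_cases(self):
        assert belief_plausibility(MassFunction(1, 0, 0)) == (1.0, 1.0)
        assert belief_plausibility(VACUOUS_MASS) == (0.0, 1.0)
        bel, pl = belief_plausibility(MassFunction(0.940, 0.047, 0.013))
        assert (bel, pl) == pytest.approx((0.940, 0.953))

    def test_random_mass_pair_properties(self):
        """Commutativity, normalisation and belief <= plausibility over 1000 pairs."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a = rng.dirichlet(np.ones(3))
            b = rng.dirichlet(np.ones(3))
            m1, m2 = MassFunction(*a), MassFunction(*b)
            if m1.reliable * m2.not_reliable + m1.not_reliable * m2.reliable >= 1.0:
                continue
            ab = dst_combine(m1, m2)
            ba = dst_combine(m2, m1)
            assert ab.as_tuple() == pytest.approx(ba.as_tuple())
            assert sum(ab.as_tuple()) == pytest.approx(1.0, abs=1e-9)
            bel, pl = belief_plausibility(ab)
            assert bel <= pl + 1e-12

    def test_interval_shrinks_as_discount_grows(self):
        widths = []
        for discount in (0.5, 0.7, 0.9, 0.99):
            bel, pl = read_across_interval(0.83, 0.9, discount=discount)
            widths.append(pl - bel)
        assert widths == sorted(widths, reverse=True)


class TestNoaelBounds:
    @pytest.mark.parametrize("mode", ["normal_sd", "normal_mean_ci", "lognormal_sd"])
    def test_equal_values_collapse_interval(self, mode):
        lo, hi = noael_bounds([20.0, 20.0, 20.0], mode=mode)
        assert lo == pytest.approx(20.0)
        assert hi == pytest.approx(20.0)

    def test_normal_sd_matches_closed_form(self):
        values = [10.0, 20.0, 30.0]
        lo, hi = noael_bounds(values, level=0.95, mode="normal_sd")
        mean, sd = np.mean(values), np.std(values, ddof=1)
        z = 1.959963984540054
        assert lo == pytest.approx(max(mean - z * sd, 0.0), abs=1e-9)
        assert hi == pytest.approx(mean + z * sd, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_normal_sd_closed_form_on_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.lognormal(3, 0.5, size=rng.integers(2, 12))
        level = float(rng.uniform(0.8, 0.99))
        lo, hi = noael_bounds(values, level=level, mode="normal_sd")
        z = scipy_stats.norm.ppf(0.5 + level / 2)
        assert lo == pytest.approx(max(values.mean() - z * values.std(ddof=1), 0.0), abs=1e-9)
        assert hi == pytest.approx(values.mean() + z * values.std(ddof=1), abs=1e-9)

    def test_lognormal_mode_bounds_positive(self):
        lo, hi = noael_bounds([1.0, 100.0], mode="lognormal_sd")
        assert 0 < lo < hi

    def test_single_value_instructs_fallback(self):
        with pytest.raises(EvidenceError, match="surrogate"):
            noael_bounds([17.0])

    def test_nonpositive_values_rejected(self):
        with pytest.raises(EvidenceError, match="positive"):
            noael_bounds([10.0, -1.0])


def _neighbour_library():
    """20 compounds: a nitroaniline neighbourhood plus unrelated chemistry."""
    compounds, noaels = [], {}
    # 8 close homologues of the target core (2-nitroaniline N-alkyl series)
    for i in range(8):
        smiles = "C" * (i + 1) + "Nc1ccccc1[N+](=O)[O-]"
        compounds.append(Compound.from_smiles(f"N-{i}", smiles))
        noaels[f"N-{i}"] = 10.0 + i
    # 12 unrelated aliphatics
    for i in range(12):
        compounds.append(Compound.from_smiles(f"U-{i}", "C" * (i + 2) + "O"))
        noaels[f"U-{i}"] = 100.0 + i
    return CompoundLibrary(compounds), noaels


class TestNearestNeighbourNoaels:
    def test_target_in_dataset_includes_own_noael(self):
        lib, noaels = _neighbour_library()
        target = lib["N-0"]
        values, status = nearest_neighbor_noaels(
            target, lib, noaels, fp_method="topological_path", threshold=0.7
        )
        assert status == "ok"
        assert noaels["N-0"] in values

    def test_matches_brute_force_oracle_with_exclusions(self):
        from readacross.profiling import Alert, AlertLibrary, match_alerts
        from readacross.similarity import compute_fingerprint, tanimoto

        lib, noaels = _neighbour_library()
        target = lib["N-0"]
        # excludes only the longer-chain members of the neighbourhood
        exclusion = AlertLibrary(
            [Alert("long_chain", "dart", "pentyl or longer N-alkyl", "CCCCC[NX3]")]
        )
        values, status = nearest_neighbor_noaels(
            target, lib, noaels, fp_method="topological_path",
            threshold=0.7, exclusion_alerts=exclusion,
        )
        # brute force: pairwise Tanimoto filter then alert filter
        tfp = compute_fingerprint(target, "topological_path")
        expected = []
        for c in lib:
            t = tanimoto(tfp, compute_fingerprint(c, "topological_path"))
            if t >= 0.7 and not match_alerts(c, exclusion):
                expected.append(noaels[c.compound_id])
        assert sorted(values) == sorted(expected)
        assert status == "ok" and len(values) >= 1

    def test_impossible_threshold_reports_empty(self):
        lib, noaels = _neighbour_library()
        query = Compound.from_smiles("q", "c1ccncc1")
        values, status = nearest_neighbor_noaels(
            query, lib, noaels, fp_method="topological_path", threshold=1.0
        )
        assert values == [] and status == "empty_neighbourhood"
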