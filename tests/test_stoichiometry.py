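import numpy as np
import pytest

from colchain import (
    CompositionVector,
    HydrolysateMeasurement,
    TrimerComposition,
    diagnostic_ranking,
    enumerate_candidates,
    infer_composition,
    marker_residue_test,
    mixture_consistency,
    theoretical_ratio,
)
from colchain.reference import ILE_LEU_THEORETIC, TISSUE_ILE_LEU


def comps_from_counts(ile, leu, tyr=(0, 0, 0)):
    out = {}
    for key, i, l, y in zip(("alpha1", "alpha2", "alpha3"), ile, leu, tyr):
        counts = {aa: 0 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        counts.update({"I": i, "L": l, "Y": y})
        out[key] = CompositionVector(chain_id=key, region="triple_helix", counts=counts)
    return out


TOY = comps_from_counts(ile=(20, 12, 8), leu=(22, 30, 22))


class TestTrimerComposition:
    def test_counts_must_sum_to_three(self):
        with pytest.raises(ValueError):
            TrimerComposition(2, 2, 0)

    def test_label(self):
        assert TrimerComposition(1, 1, 1).label == "1:1:1"


class TestTheoreticalRatio:
    def test_homotrimer_reduces_to_single_chain_ratio(self):
        assert theoretical_ratio(TrimerComposition(3, 0, 0), TOY, ("I", "L")) == (
            pytest.approx(20 / 22)
        )

    def test_heterotrimer_hand_arithmetic(self):
        assert theoretical_ratio(TrimerComposition(1, 1, 1), TOY, ("I", "L")) == (
            pytest.approx(40 / 74)
        )

    def test_invariant_under_count_scaling(self):
        doubled = comps_from_counts(ile=(40, 24, 16), leu=(44, 60, 44))
        for cand in enumerate_candidates():
            assert theoretical_ratio(cand, TOY, ("I", "L")) == pytest.approx(
                theoretical_ratio(cand, doubled, ("I", "L"))
            )

    def test_zero_denominator_is_an_error(self):
        empty = comps_from_counts(ile=(1, 1, 1), leu=(0, 0, 0))
        with pytest.raises(ZeroDivisionError):
            theoretical_ratio(TrimerComposition(1, 1, 1), empty, ("I", "L"))

    def test_monotone_along_alpha1_to_alpha3_path(self, zebra_comps):
        """When alpha1's ratio exceeds alpha3's, the trimer ratio decreases
        from 2:1:0 through 1:1:1 to 0:1:2."""
        path = [TrimerComposition(2, 1, 0), TrimerComposition(1, 1, 1), TrimerComposition(0, 1, 2)]
        vals = [theoretical_ratio(c, zebra_comps, ("I", "L")) for c in path]
        assert vals[0] > vals[1] > vals[2]


class TestEnumerateCandidates:
    def test_single_alpha2_constraint_gives_canonical_triple(self):
        assert [c.counts for c in enumerate_candidates(n_alpha2=1)] == [
            (2, 1, 0),
            (1, 1, 1),
            (0, 1, 2),
        ]

    def test_unconstrained_enumeration_is_stars_and_bars(self):
        cands = enumerate_candidates()
        assert len(cands) == 10
        assert len(set(cands)) == 10

    def test_infeasible_constraint_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="contradictory"):
            assert enumerate_candidates(n_alpha2=4) == []


class TestMarkerResidueTest:
    TYR = comps_from_counts(ile=(20, 12, 8), leu=(22, 30, 22), tyr=(0, 2, 0))

    def meas(self, observed, sd):
        return HydrolysateMeasurement(
            "skin", ("I", "L"), 0.5, 0.05, marker_counts={"Y": (observed, sd)}
        )

    def test_homotrimer_excluded_when_marker_detected(self):
        excl = marker_residue_test(
            self.meas(2.0, 0.3), [TrimerComposition(3, 0, 0)], self.TYR
        )
        assert [e.composition.counts for e in excl] == [(3, 0, 0)]

    def test_zero_expectation_candidate_retained_at_zero_observation(self):
        excl = marker_residue_test(
            self.meas(0.01, 0.1), [TrimerComposition(3, 0, 0)], self.TYR
        )
        assert excl == []

    def test_marker_uninformative_among_single_alpha2_candidates(self):
        excl = marker_residue_test(
            self.meas(2.0, 0.3), enumerate_candidates(n_alpha2=1), self.TYR
        )
        assert excl == []

    def test_contamination_flag_when_marker_absent_everywhere(self):
        with pytest.warns(UserWarning, match="contamination"):
            excl = marker_residue_test(
                self.meas(2.0, 0.3), [TrimerComposition(3, 0, 0)], TOY
            )
        assert excl == []


class TestInferComposition:
    def test_published_tissue_ratios_select_heterotrimer(self, candidates):
        for tissue, (ratio, sd) in TISSUE_ILE_LEU.items():
            meas = HydrolysateMeasurement(tissue, ("I", "L"), ratio, sd)
            res = infer_composition(meas, candidates, theoretical_values=ILE_LEU_THEORETIC)
            assert [c.label for c in res.selected] == ["1:1:1"]
            assert not res.poor_fit

    def test_exact_match_has_zero_deviation_and_z(self, candidates, zebra_comps):
        theo = theoretical_ratio(TrimerComposition(1, 1, 1), zebra_comps, ("I", "L"))
        meas = HydrolysateMeasurement("t", ("I", "L"), theo, 0.05)
        res = infer_composition(meas, candidates, zebra_comps)
        assert res.best.deviation == 0.0
        assert res.best.z_score == 0.0

    def test_midpoint_observation_reports_tie(self, candidates, zebra_comps):
        r1 = theoretical_ratio(TrimerComposition(2, 1, 0), zebra_comps, ("I", "L"))
        r2 = theoretical_ratio(TrimerComposition(1, 1, 1), zebra_comps, ("I", "L"))
        meas = HydrolysateMeasurement("t", ("I", "L"), (r1 + r2) / 2, 0.05)
        res = infer_composition(meas, candidates, zebra_comps)
        assert res.is_tie
        assert {c.label for c in res.selected} == {"2:1:0", "1:1:1"}

    def test_all_candidates_excluded_is_an_error(self, candidates, zebra_comps):
        from colchain import Exclusion

        meas = HydrolysateMeasurement("t", ("I", "L"), 0.5, 0.05)
        excl = [Exclusion(c, "test") for c in candidates]
        with pytest.raises(ValueError, match="all candidates excluded"):
            infer_composition(meas, candidates, zebra_comps, exclusions=excl)

    def test_parameter_recovery_under_measurement_noise(self, candidates, zebra_comps):
        """Truth 1:1:1, Gaussian ratio noise sd 0.05: the nearest-candidate
        rule recovers the truth in >=95% of simulations (separations ~0.19)."""
        from colchain import aggregate_measurements, simulate_hydrolysate

        truth = TrimerComposition(1, 1, 1)
        hits = 0
        n_sim = 400
        for seed in range(n_sim):
            meas = aggregate_measurements(
                simulate_hydrolysate(truth, zebra_comps, noise_sd=0.05, seed=seed)
            )
            res = infer_composition(meas, candidates, zebra_comps)
            hits += (not res.is_tie) and res.selected[0] == truth
        assert hits / n_sim >= 0.95


class TestMixtureConsistency:
    def test_equal_mix_of_extremes_equals_heterotrimer(self, zebra_comps):
        r111 = theoretical_ratio(TrimerComposition(1, 1, 1), zebra_comps, ("I", "L"))
        res = mixture_consistency(
            r111,
            [TrimerComposition(2, 1, 0), TrimerComposition(0, 1, 2)],
            zebra_comps,
            ("I", "L"),
        )
        assert res.feasible
        assert res.fractions[0] == pytest.approx((0.5, 0.5))

    def test_observed_outside_achievable_range_is_infeasible(self, zebra_comps):
        res = mixture_consistency(
            0.9,
            [TrimerComposition(2, 1, 0), TrimerComposition(0, 1, 2)],
            zebra_comps,
            ("I", "L"),
        )
        assert not res.feasible
        lo, hi = res.achievable_range
        assert not lo <= 0.9 <= hi

    def test_two_type_solution_agrees_with_grid_search(self, zebra_comps):
        types = [TrimerComposition(2, 1, 0), TrimerComposition(0, 1, 2)]
        A = [sum(n * zebra_comps[k].counts["I"] for n, k in zip(t.counts, ("alpha1", "alpha2", "alpha3"))) for t in types]
        B = [sum(n * zebra_comps[k].counts["L"] for n, k in zip(t.counts, ("alpha1", "alpha2", "alpha3"))) for t in types]
        for observed in (0.45, 0.55, 0.65, 0.75):
            res = mixture_consistency(observed, types, zebra_comps, ("I", "L"))
            grid = np.linspace(0, 1, 1001)
            ratios = (grid * A[0] + (1 - grid) * A[1]) / (grid * B[0] + (1 - grid) * B[1])
            f_grid = grid[np.argmin(np.abs(ratios - observed))]
            if res.feasible:
                assert res.fractions[0][0] == pytest.approx(f_grid, abs=1e-3)
            else:
                assert min(abs(ratios - observed)) > 1e-3

    def test_three_type_segment_contains_known_solutions(self, zebra_comps):
        r111 = theoretical_ratio(TrimerComposition(1, 1, 1), zebra_comps, ("I", "L"))
        types = [
            TrimerComposition(1, 1, 1),
            TrimerComposition(2, 1, 0),
            TrimerComposition(0, 1, 2),
        ]
        res = mixture_consistency(r111, types, zebra_comps, ("I", "L"))
        assert res.feasible
        fr = np.array(res.fractions)
        # pure heterotrimer is on the segment
        assert np.min(np.abs(fr - [1, 0, 0]).sum(axis=1)) < 1e-6
        # the 50/50 mix of the two flanking trimers is too
        assert np.min(np.abs(fr - [0, 0.5, 0.5]).sum(axis=1)) < 0.02


class TestDiagnosticRanking:
    def test_identical_chains_have_zero_separation(self, candidates):
        same = comps_from_counts(ile=(10, 10, 10), leu=(20, 20, 20))
        ranked = diagnostic_ranking(same, candidates, residues="IL")
        assert all(score == 0 for _, score, _ in ranked)

    def test_only_pairs_involving_the_differing_residue_separate(self, candidates):
        comps = comps_from_counts(ile=(10, 10, 10), leu=(20, 20, 20))
        for key, a_count in zip(("alpha1", "alpha2", "alpha3"), (5, 10, 15)):
            comps[key].counts["A"] = a_count
        ranked = diagnostic_ranking(comps, candidates, residues="AIL")
        for pair, score, _ in ranked:
            if "A" in pair:
                assert score > 0
            else:
                assert score == 0

    def test_ile_leu_ranks_in_top_group_for_zebrafish_chains(self, zebra_comps, candidates):
        ranked = diagnostic_ranking(zebra_comps, candidates)
        top_score = ranked[0][1]
        il_score = next(s for pair, s, _ in ranked if pair == ("I", "L"))
        assert il_score == pytest.approx(top_score, rel=1e-9)
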