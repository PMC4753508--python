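import numpy as np
import pytest
from scipy import stats

from colchain import (
    CrosslinkSite,
    Domain,
    DomainMap,
    DomainName,
    ProCollagenChain,
    TripletParse,
    aa_composition,
    count_stability_motifs,
    crosslink_site_report,
    cysteine_conservation,
    generate_chain,
    net_charge,
    parse_collagenous_domain,
    recognition_region_diff,
    theoretical_mass,
    theoretical_pI,
    xy_identity,
)

WATER = 18.0153


def chain(seq, cid="c"):
    return ProCollagenChain(id=cid, sequence=seq)


def full_helix_map(seq, cid="c"):
    return DomainMap(cid, [Domain(DomainName.triple_helix, 0, len(seq))])


class TestTripletParse:
    def test_pure_gpp_repeat(self):
        p = parse_collagenous_domain(chain("GPP" * 5))
        assert len(p.triplets) == 5
        assert p.interruptions == []

    def test_longest_run_located_without_domain_map(self):
        p = parse_collagenous_domain(chain("AAAGPPGPPGPPAAA"))
        assert (p.helix_start, p.helix_end) == (3, 12)
        assert len(p.triplets) == 3

    def test_interruption_recorded_and_span_reconstructs(self):
        seq = "GPPGPASSGPP"
        p = parse_collagenous_domain(chain(seq), full_helix_map(seq))
        assert p.interruptions == [(6, 2)]
        assert p.reconstruct() == seq

    def test_no_triplet_is_an_error(self):
        with pytest.raises(ValueError, match="no G-X-Y"):
            parse_collagenous_domain(chain("AAAAAA"))

    @pytest.mark.parametrize("seed", range(4))
    def test_reconstruction_invariant_on_synthetic_chains(self, seed):
        c, dm = generate_chain(n_triplets=60, seed=seed)
        p = parse_collagenous_domain(c, dm)
        assert p.reconstruct() == c.sequence[p.helix_start : p.helix_end]


class TestStabilityMotifs:
    def test_pure_gpp_counts(self):
        m = count_stability_motifs(parse_collagenous_domain(chain("GPP" * 5)))
        assert (m.gpp, m.gg, m.ggg) == (5, 0, 0)

    def test_hand_counted_gly_runs(self):
        seq = "GGAGPPGGG"
        m = count_stability_motifs(
            parse_collagenous_domain(chain(seq), full_helix_map(seq))
        )
        assert (m.gpp, m.gg, m.ggg, m.gg_plus_ggg) == (1, 1, 1, 2)

    @pytest.mark.parametrize(
        "seq,gg,ggg",
        [
            ("GGGGAPGPP", 0, 1),  # run of 4 -> one GGG, remainder dropped
            ("GGGGGAPGPP", 1, 1),  # run of 5 -> GGG + GG
            ("GGGGGGAPGPP", 0, 2),  # run of 6 -> two GGG
        ],
    )
    def test_long_run_greedy_decomposition_is_flagged(self, seq, gg, ggg):
        m = count_stability_motifs(
            parse_collagenous_domain(chain(seq), full_helix_map(seq))
        )
        assert (m.gg, m.ggg) == (gg, ggg)
        assert m.long_runs

    def test_gpp_frequency_within_binomial_bounds(self):
        n, p = 1000, 0.3
        c, dm = generate_chain(n_triplets=n, motif_freqs=(p, 0.0, 0.0), seed=5)
        m = count_stability_motifs(parse_collagenous_domain(c, dm))
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
        assert lo <= m.gpp <= hi


class TestXYIdentity:
    def test_chain_vs_itself_is_100(self):
        c, dm = generate_chain(n_triplets=50, seed=1)
        p = parse_collagenous_domain(c, dm)
        assert xy_identity(p, p) == 100.0

    def test_hand_counted_gapless(self):
        pa = parse_collagenous_domain(chain("GPPGAA"))
        pb = parse_collagenous_domain(chain("GPPGAG"))
        # X/Y strings PPAA vs PPAG
        assert xy_identity(pa, pb) == pytest.approx(75.0)


class TestComposition:
    def test_hand_counted_full_chain(self):
        comp = aa_composition(chain("GPPGAA"))
        assert comp.counts["G"] == 2 and comp.counts["P"] == 2 and comp.counts["A"] == 2
        assert sum(v for k, v in comp.counts.items() if k not in "GPA") == 0
        assert comp.length == 6

    def test_region_restriction(self):
        seq = "GPPGPPYYYY"
        dm = DomainMap(
            "c",
            [
                Domain(DomainName.triple_helix, 0, 6),
                Domain(DomainName.c_propeptide, 6, 10),
            ],
        )
        comp = aa_composition(chain(seq), "triple_helix", dm)
        assert comp.counts["Y"] == 0
        assert comp.length == 6

    def test_unresolvable_region_is_an_error(self):
        with pytest.raises(ValueError):
            aa_composition(chain("GPP"), "triple_helix", None)


class TestTheoreticalMass:
    def test_two_glycines_hand_summed(self):
        assert theoretical_mass(chain("GG")) == pytest.approx(132.1179, abs=0.005)

    def test_single_residue_plus_water(self):
        assert theoretical_mass(chain("G")) == pytest.approx(75.0666, abs=0.005)

    def test_additivity_minus_water(self, random_chain_pair):
        a, b = random_chain_pair(3)
        whole = theoretical_mass(chain(a.sequence + b.sequence))
        assert whole == pytest.approx(
            theoretical_mass(a) + theoretical_mass(b) - WATER, abs=1e-6
        )

    def test_unknown_residue_is_an_error(self):
        with pytest.raises(ValueError):
            theoretical_mass(chain("GXG"))


class TestTheoreticalPI:
    def test_no_sidechain_peptide_matches_closed_form(self):
        # exactly one acid (C-terminus, pKa 3.55) and one base (N-terminus, 7.5)
        assert theoretical_pI(chain("GG")) == pytest.approx((7.5 + 3.55) / 2, abs=0.01)

    @pytest.mark.parametrize("seq", ["GG", "DEKR", "ACDEFGHIKLMNPQRSTVWY", "KKKK", "DDDD"])
    def test_net_charge_vanishes_at_pi(self, seq):
        pi = theoretical_pI(chain(seq))
        assert abs(net_charge(seq, pi)) < 0.01

    def test_net_charge_strictly_decreasing_in_ph(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        charges = [net_charge(seq, ph) for ph in np.linspace(0, 14, 30)]
        assert all(c1 > c2 for c1, c2 in zip(charges, charges[1:]))

    def test_acidic_residue_never_raises_pi_basic_never_lowers(self):
        base = "GAVLGAVL"
        pi0 = theoretical_pI(chain(base))
        assert theoretical_pI(chain(base + "D")) <= pi0 + 1e-6
        assert theoretical_pI(chain(base + "K")) >= pi0 - 1e-6


CPRO_REF = "WSTCACFAGCACDEF"  # Cys at 4, 6, 10, 12


class TestCysteineConservation:
    def test_reference_against_itself_all_conserved(self):
        rep = cysteine_conservation(
            chain(CPRO_REF, "tgt"), chain(CPRO_REF, "ref"),
            [(4, "inter_chain"), (6, "intra_chain")],
        )
        assert rep.summary()["n_conserved"] == 2

    def test_toy_serine_substitution_detected(self):
        rep = cysteine_conservation(
            chain("ASGCA", "tgt"), chain("ACGCA", "ref"),
            [(2, "inter_chain"), (4, "intra_chain")],
        )
        by_label = {i.site_label: i for i in rep.items}
        assert not by_label["Cys2[inter_chain]"].conserved
        assert by_label["Cys2[inter_chain]"].target_residue == "S"
        assert by_label["Cys4[intra_chain]"].conserved

    def test_non_cys_reference_position_is_annotation_error(self):
        with pytest.raises(ValueError, match="not Cys"):
            cysteine_conservation(
                chain("ACGCA", "tgt"), chain("ACGCA", "ref"), [(3, "inter_chain")]
            )

    def test_invariant_to_identical_flanks(self):
        args = [(2, "inter_chain"), (4, "intra_chain")]
        plain = cysteine_conservation(chain("ASGCA", "t"), chain("ACGCA", "r"), args)
        flank = "MKTAYIA"
        padded = cysteine_conservation(
            chain(flank + "ASGCA" + flank, "t"),
            chain(flank + "ACGCA" + flank, "r"),
            [(p + len(flank), role) for p, role in args],
        )
        assert [i.conserved for i in plain.items] == [i.conserved for i in padded.items]


def helix_chain_with_lys(sub=None):
    """Helix of 40 triplets with Lys at helix positions 10 and 25."""
    helix = list("GPA" * 40)
    helix[9] = "K"
    helix[24] = "K"
    if sub:
        pos, res = sub
        helix[pos - 1] = res
    seq = "MMMM" + "".join(helix) + "WWWW"
    dm = DomainMap(
        "x",
        [
            Domain(DomainName.n_telopeptide, 0, 4),
            Domain(DomainName.triple_helix, 4, 4 + 120),
            Domain(DomainName.c_telopeptide, 124, 128),
        ],
    )
    return ProCollagenChain(id="x", sequence=seq), dm


SITES = [CrosslinkSite("h10", "triple_helix", 10), CrosslinkSite("h25", "triple_helix", 25)]


class TestCrosslinkSites:
    def test_reference_on_itself_all_lysines(self):
        ref, dm = helix_chain_with_lys()
        rep = crosslink_site_report(ref, ref, SITES, ref_domains=dm, target_domains=dm)
        assert all(i.conserved and i.target_residue == "K" for i in rep.items)

    def test_arg_substitution_with_compensating_lys(self):
        ref, dm = helix_chain_with_lys()
        # target: site 25 is Arg, but a Lys sits 3 residues upstream (pos 22)
        tgt, tdm = helix_chain_with_lys(sub=(25, "R"))
        tgt_seq = list(tgt.sequence)
        tgt_seq[4 + 21] = "K"
        tgt = ProCollagenChain(id="x", sequence="".join(tgt_seq))
        rep = crosslink_site_report(tgt, ref, SITES, ref_domains=dm, target_domains=tdm)
        item = {i.site_label: i for i in rep.items}["h25"]
        assert not item.conserved
        assert item.target_residue == "R"
        assert "basic substitution" in item.note
        assert item.compensating_offset == -3

    def test_deleted_site_reported(self):
        from colchain import PairwiseAlignment

        ref, dm = helix_chain_with_lys()
        # constructed alignment with a gap over helix position 25 (chain idx 28)
        seq = ref.sequence[:28] + ref.sequence[29:]
        tgt = ProCollagenChain(id="x", sequence=seq)
        aligned_b = seq[:28] + "-" + seq[28:]
        aln = PairwiseAlignment("x", "x", ref.sequence, aligned_b, 0.0)
        rep = crosslink_site_report(tgt, ref, SITES, ref_domains=dm, aln=aln)
        item = {i.site_label: i for i in rep.items}["h25"]
        assert item.target_residue == "deleted"

    def test_telopeptide_coordinates(self):
        ref, dm = helix_chain_with_lys()
        rep = crosslink_site_report(
            ref, ref, [CrosslinkSite("2N", "n_telopeptide", 2)], ref_domains=dm
        )
        assert rep.items[0].target_residue == "M"


class TestRecognitionRegion:
    REF = "AAAAQWERTYQWERTYQWEAAAA"  # 15-residue window at 5..19

    def test_self_has_zero_differences(self):
        n, wa, wb = recognition_region_diff(chain(self.REF, "t"), chain(self.REF, "r"), (5, 19))
        assert n == 0 and wa == wb

    def test_three_substitutions_counted(self):
        tgt = self.REF[:6] + "A" + self.REF[7:12] + "A" + self.REF[13:18] + "A" + self.REF[19:]
        n, _, _ = recognition_region_diff(chain(tgt, "t"), chain(self.REF, "r"), (5, 19))
        assert n == 3

    def test_gap_counts_as_difference(self):
        tgt = self.REF[:8] + self.REF[11:]  # 3-residue deletion inside the window
        n, _, wb = recognition_region_diff(chain(tgt, "t"), chain(self.REF, "r"), (5, 19))
        assert "-" in wb
        assert n >= 3

    def test_fully_deleted_window_is_an_error(self):
        tgt = self.REF[:4] + self.REF[19:]
        with pytest.raises(ValueError, match="deleted"):
            recognition_region_diff(chain(tgt, "t"), chain(self.REF, "r"), (5, 19))
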