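"""Pi, sliding windows, K2P and Nei-Gojobori Ka/Ks."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocompare import (GeneAlignment, SimulationConfig, evolve_k2p,
                         k2p_distance, mean_gene_distance, nei_gojobori,
                         nucleotide_diversity, pairwise_differences,
                         sliding_window_pi, vertebrate_mito_code)

CODE = vertebrate_mito_code()
PUR, PYR = set("AG"), set("CT")


def brute_force_counts(a, b):
    valid = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        valid += 1
        if x == y:
            continue
        if (x in PUR) == (y in PUR):
            ts += 1
        else:
            tv += 1
    return valid, ts, tv


class TestPairwiseDifferences:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACGT", "ACGT", (4, 0, 0)),
        ("AAAA", "GAAA", (4, 1, 0)),
        ("AAAA", "CAAA", (4, 0, 1)),
        ("AC-T", "ANGT", (2, 0, 0)),    # pairwise deletion of gap/N sites
    ])
    def test_examples(self, a, b, expected):
        assert pairwise_differences(a, b) == expected

    def test_matches_site_scan_oracle_on_random_pair(self):
        rng = random.Random(11)
        a = "".join(rng.choice("ACGTN-") for _ in range(300))
        b = "".join(rng.choice("ACGTN-") for _ in range(300))
        assert pairwise_differences(a, b) == brute_force_counts(a, b)

    def test_zero_valid_sites_is_error(self):
        with pytest.raises(ValueError):
            pairwise_differences("NNN", "ACG")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pairwise_differences("ACGT", "ACG")


class TestNucleotideDiversity:
    def test_identical_sequences_zero(self):
        aln = GeneAlignment("g", {"a": "ACGTACGT", "b": "ACGTACGT"})
        assert nucleotide_diversity(aln) == 0.0

    def test_single_pair_definition(self):
        aln = GeneAlignment("g", {"a": "A" * 100, "b": "G" + "A" * 99})
        assert nucleotide_diversity(aln) == pytest.approx(0.01)

    def test_invariant_under_taxon_relabeling(self, default_clade):
        aln = default_clade.alignments["ND3"]
        shuffled = GeneAlignment("ND3", {f"x{i}": s for i, s in enumerate(
            reversed(list(aln.sequences.values())))})
        assert nucleotide_diversity(shuffled) == \
            pytest.approx(nucleotide_diversity(aln))


class TestSlidingWindow:
    def test_constant_alignment_all_zero(self):
        aln = GeneAlignment("g", {"a": "ACGT" * 300, "b": "ACGT" * 300})
        prof = sliding_window_pi(aln, window=500, step=100)
        assert all(w[3] == 0 for w in prof.windows)
        assert prof.windows[0][:2] == (1, 500)
        assert prof.windows[1][0] == 101

    def test_signal_localized_to_covering_windows(self):
        # differences only at sites 1..50: oracle = window/segment overlap
        n = 1200
        a = "A" * n
        b = "G" * 50 + "A" * (n - 50)
        prof = sliding_window_pi(GeneAlignment("g", {"a": a, "b": b}),
                                 window=500, step=100)
        for start, end, _, pi in prof.windows:
            overlaps_signal = start <= 50
            assert (pi > 0) == overlaps_signal

    def test_short_alignment_single_truncated_window(self):
        aln = GeneAlignment("g", {"a": "ACGT" * 30, "b": "ACGT" * 30})
        prof = sliding_window_pi(aln, window=500, step=100)
        assert len(prof.windows) == 1
        assert prof.windows[0][1] == 120
        assert prof.last_window_partial


class TestK2P:
    def test_identical_pair_distance_zero(self):
        res = k2p_distance("ACGT" * 50, "ACGT" * 50)
        assert res.d_k2p == 0.0 and not res.saturated

    def test_closed_form_at_p01_q005(self):
        # 200 sites: 20 transitions, 10 transversions -> P=0.1, Q=0.05
        a = "A" * 200
        b = "G" * 20 + "C" * 10 + "A" * 170
        res = k2p_distance(a, b)
        expected = -0.5 * math.log(1 - 2 * 0.1 - 0.05) \
            - 0.25 * math.log(1 - 2 * 0.05)
        assert res.transition_p == pytest.approx(0.1)
        assert res.transversion_q == pytest.approx(0.05)
        assert res.d_k2p == pytest.approx(expected, abs=1e-9)
        assert res.d_k2p == pytest.approx(0.1702, abs=5e-5)

    def test_saturation_flagged_not_nan_surprise(self):
        a = "A" * 100
        b = "G" * 60 + "A" * 40     # P = 0.6 -> 1-2P-Q < 0
        res = k2p_distance(a, b)
        assert res.saturated and math.isnan(res.d_k2p)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_correction_never_below_p_distance(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), size=200))
        b = evolve_k2p(a, float(rng.uniform(0, 0.3)), 4.0, rng)
        res = k2p_distance(a, b)
        if not res.saturated:
            assert res.d_k2p >= res.p_distance - 1e-12
            if res.p_distance > 0:
                assert res.d_k2p > res.p_distance

    def test_estimator_consistent_on_simulated_pair(self):
        # K2P estimate within 3 delta-method SE of the simulated distance
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ACGT"), size=10000))
        b = evolve_k2p(a, 0.05, 4.0, rng)
        res = k2p_distance(a, b)
        w1 = 1 - 2 * res.transition_p - res.transversion_q
        w2 = 1 - 2 * res.transversion_q
        c1, c2 = 1 / w1, 0.5 * (1 / w1 + 1 / w2)
        var = (c1 ** 2 * res.transition_p + c2 ** 2 * res.transversion_q
               - (c1 * res.transition_p + c2 * res.transversion_q) ** 2) \
            / res.valid_sites
        assert abs(res.d_k2p - 0.05) < 3 * math.sqrt(var)

    def test_mean_distance_is_pair_average(self):
        seqs = {"a": "A" * 100, "b": "G" * 5 + "A" * 95,
                "c": "C" * 10 + "A" * 90}
        aln = GeneAlignment("g", seqs)
        expected = np.mean([
            k2p_distance(seqs["a"], seqs["b"]).d_k2p,
            k2p_distance(seqs["a"], seqs["c"]).d_k2p,
            k2p_distance(seqs["b"], seqs["c"]).d_k2p])
        assert mean_gene_distance(aln) == pytest.approx(float(expected))

    def test_two_taxa_mean_equals_single_pair(self):
        aln = GeneAlignment("g", {"a": "A" * 100, "b": "G" * 5 + "A" * 95})
        assert mean_gene_distance(aln) == \
            pytest.approx(k2p_distance("A" * 100, "G" * 5 + "A" * 95).d_k2p)


SENSE = sorted(set(CODE.forward))


def random_cds(rng, n_codons):
    return "".join(SENSE[rng.randrange(len(SENSE))] for _ in range(n_codons))


class TestNeiGojobori:
    def test_identical_pair_zero_by_convention(self):
        cds = "ATGCTATTTTAA"
        r = nei_gojobori(cds, cds, CODE)
        assert r.ka == 0 and r.ks == 0 and r.ratio == 0.0 and r.ratio_defined

    def test_single_synonymous_leucine_change(self):
        # TTA vs TTG are both Leu2: one synonymous difference, Ka = 0
        # (a lone two-codon family saturates the Ks correction: pS = 3)
        r = nei_gojobori("TTA", "TTG", CODE)
        assert r.syn_diffs == pytest.approx(1.0)
        assert r.nonsyn_diffs == pytest.approx(0.0)
        assert r.ka == 0.0

    def test_synonymous_change_in_context_gives_zero_ratio(self):
        a, b = "ATGGGGTTAGGG", "ATGGGGTTGGGG"
        r = nei_gojobori(a, b, CODE)
        assert r.nonsyn_diffs == 0.0 and r.ks > 0
        assert r.ratio == 0.0 and r.ratio_defined

    def test_single_nonsynonymous_change_flags_undefined_ratio(self):
        # TTT (Phe) vs GTT (Val): Ka > 0 with Ks == 0
        r = nei_gojobori("TTT", "GTT", CODE)
        assert r.nonsyn_diffs == pytest.approx(1.0)
        assert r.ks == 0.0 and not r.ratio_defined and math.isnan(r.ratio)

    def test_sites_sum_to_three_per_codon(self):
        rng = random.Random(3)
        a, b = random_cds(rng, 120), random_cds(rng, 120)
        r = nei_gojobori(a, b, CODE)
        assert r.syn_sites + r.nonsyn_sites == \
            pytest.approx(3 * r.codons_compared)
        assert r.syn_diffs + r.nonsyn_diffs >= 0

    def test_fourfold_codon_third_position_fully_synonymous(self):
        # every change at GGx third position keeps Gly: 1 syn site there
        r = nei_gojobori("GGA", "GGA", CODE)
        assert r.syn_sites == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_in_arguments(self, seed):
        rng = random.Random(seed)
        a, b = random_cds(rng, 60), random_cds(rng, 60)
        ra, rb = nei_gojobori(a, b, CODE), nei_gojobori(b, a, CODE)
        assert ra.syn_sites == pytest.approx(rb.syn_sites, abs=1e-9)
        assert ra.syn_diffs == pytest.approx(rb.syn_diffs, abs=1e-9)
        assert ra.nonsyn_diffs == pytest.approx(rb.nonsyn_diffs, abs=1e-9)

    def test_ambiguous_and_stop_codons_skipped(self):
        r = nei_gojobori("ATGNNNTTT", "ATGAAATTT", CODE)
        assert r.codons_compared == 2

    def test_omega_simulation_envelope(self):
        # omega=0.1 at proposal distance 0.3 on a 5 kb CDS: the NG86 ratio
        # lands in a broad envelope around the simulated omega
        from mitocompare import evolve_codon
        rng = np.random.default_rng(1)
        a = "ATG" + random_cds(random.Random(2), 1660) + "TAA"
        b = evolve_codon(a, 0.3, 4.0, 0.1, rng, CODE)
        r = nei_gojobori(a, b, CODE)
        assert r.ratio_defined
        assert 0.05 <= r.ratio <= 0.2
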