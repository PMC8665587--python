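"""NG86 site/difference counting, Jukes-Cantor correction, window scans."""

import math

import numpy as np
import pytest

from dupdiverge import selection as sel
from dupdiverge.synthetic_data import sim_codon_pair, realized_omega

from oracles import ng86_pair, ng86_sites, ng86_diffs


class TestCodonSites:
    @pytest.mark.parametrize("codon,s", [
        ("CCC", 1.0),        # fourfold-degenerate third position
        ("ATG", 0.0),        # Met: every mutation is nonsynonymous
        ("TTT", 1 / 3),      # Phe: one synonymous third-position change
    ])
    def test_known_site_counts(self, codon, s):
        ss, nn = sel.codon_sites(codon)
        assert ss == pytest.approx(s, abs=1e-12)
        assert ss + nn == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            sel.codon_sites("TAA")

    def test_all_sense_codons_match_enumeration_oracle(self):
        for codon in sel.CODON_TABLE:
            s_o, n_o = ng86_sites(codon)
            s, n = sel.codon_sites(codon)
            assert s == pytest.approx(float(s_o), abs=1e-12)
            assert n == pytest.approx(float(n_o), abs=1e-12)


class TestCodonDifferences:
    @pytest.mark.parametrize("a,b,sd,nd", [
        ("GTT", "GTT", 0.0, 0.0),
        ("GTT", "GTA", 1.0, 0.0),     # Val→Val, synonymous single step
        ("TTT", "GTA", 0.5, 1.5),     # two paths: nonsyn+syn / nonsyn+nonsyn
    ])
    def test_pathway_averaged_counts(self, a, b, sd, nd):
        got_sd, got_nd, _ = sel.codon_differences(a, b)
        assert (got_sd, got_nd) == (sd, nd)

    def test_difference_counts_sum_to_number_of_differing_positions(self):
        rng = np.random.default_rng(0)
        sense = sorted(sel.CODON_TABLE)
        for _ in range(200):
            a, b = rng.choice(sense, 2)
            sd, nd, _ = sel.codon_differences(a, b)
            k = sum(x != y for x, y in zip(a, b))
            assert sd + nd == pytest.approx(k)
            o_sd, o_nd = ng86_diffs(a, b)
            assert sd == pytest.approx(float(o_sd), abs=1e-12)


class TestJukesCantor:
    def test_zero_maps_to_zero(self):
        assert sel.jukes_cantor(0.0) == 0.0

    def test_closed_form_at_half(self):
        assert sel.jukes_cantor(0.5) == pytest.approx(0.823959216, abs=1e-8)

    def test_saturation_boundary_raises(self):
        with pytest.raises(ValueError):
            sel.jukes_cantor(0.75)

    def test_correction_dominates_p_distance(self):
        for p in np.linspace(0.01, 0.74, 40):
            assert sel.jukes_cantor(p) >= p


class TestPairwiseDnds:
    def test_identical_sequences_have_undefined_omega(self):
        r = sel.pairwise_dnds("ATGGTT", "ATGGTT")
        assert r.Sd == r.Nd == 0 and r.dS == 0 and r.omega is None

    def test_worked_example_phe_repeat(self):
        r = sel.pairwise_dnds("TTT" * 9, "TTC" + "TTT" * 8)
        assert (r.S, r.N, r.Sd, r.Nd) == (3.0, 24.0, 1.0, 0.0)
        assert r.pS == pytest.approx(1 / 3)
        assert r.dS == pytest.approx(0.4408, abs=1e-4)
        assert r.dN == 0.0

    def test_frame_and_length_validation(self):
        with pytest.raises(ValueError):
            sel.pairwise_dnds("ATGG", "ATGG")
        with pytest.raises(ValueError):
            sel.pairwise_dnds("ATG", "ATGATG")

    def test_matches_brute_force_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for i in range(50):
            n = int(rng.integers(5, 40))
            a, b, _ = sim_codon_pair(max(n, 15), omega=0.5,
                                     n_attempts=int(rng.integers(5, 60)),
                                     seed=1000 + i)
            got = sel.pairwise_dnds(a, b)
            exp = ng86_pair(a, b)
            for key in ("S", "N", "Sd", "Nd"):
                assert getattr(got, key) == pytest.approx(exp[key], abs=1e-9), key
            assert got.dS == pytest.approx(exp["dS"], abs=1e-9)
            assert got.dN == pytest.approx(exp["dN"], abs=1e-9)

    def test_site_counts_partition_three_per_codon(self):
        a, b, _ = sim_codon_pair(60, 0.3, 50, seed=9)
        r = sel.pairwise_dnds(a, b)
        assert r.S + r.N == pytest.approx(3 * r.n_codons)


class TestClassification:
    @pytest.mark.parametrize("omega,cls", [
        (1.6, sel.POSITIVE), (0.5, sel.PURIFYING), (1.0, sel.INTERMEDIATE),
        (1.5, sel.INTERMEDIATE), (0.67, sel.INTERMEDIATE), (None, sel.UNDEFINED),
    ])
    def test_thresholds(self, omega, cls):
        assert sel.classify_selection(omega) == cls

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            sel.classify_selection(-0.1)


class TestSlidingWindow:
    def test_window_count_for_90_codons(self):
        a, b, _ = sim_codon_pair(90, 1.0, 40, seed=1)
        track = sel.sliding_window(a, b, window=45, step=9)
        assert len(track.windows) == 6
        assert [w.start_codon for w in track.windows] == [0, 9, 18, 27, 36, 45]

    def test_identical_pair_all_windows_undefined(self):
        a, _, _ = sim_codon_pair(60, 1.0, 0, seed=2)
        track = sel.sliding_window(a, a)
        assert set(track.classes()) == {sel.UNDEFINED}

    def test_short_alignment_falls_back_to_whole_sequence(self):
        a, b, _ = sim_codon_pair(20, 1.0, 10, seed=3)
        track = sel.sliding_window(a, b, window=45)
        assert track.whole_sequence_fallback and len(track.windows) == 1

    def test_chimeric_pair_calls_purifying_then_positive(self):
        a1, b1, _ = sim_codon_pair(45, 0.0, 120, seed=7)   # synonymous only
        a2, b2, t2 = sim_codon_pair(45, 5.0, 60, seed=8)   # nonsyn-dominated
        assert t2.n_nonsyn > t2.n_syn
        a, b = a1 + a2, b1 + b2
        track = sel.sliding_window(a, b, window=45, step=9)
        assert track.windows[0].selection_class == sel.PURIFYING
        assert track.windows[-1].selection_class == sel.POSITIVE

    def test_nterm_cterm_summary_on_chimera(self):
        a1, b1, _ = sim_codon_pair(45, 0.0, 120, seed=7)
        a2, b2, _ = sim_codon_pair(45, 5.0, 60, seed=8)
        track = sel.sliding_window(a1 + a2, b1 + b2)
        summ = sel.nterm_cterm_summary(track, nterm_codons=50)
        assert summ["cterm_positive"]
        # start-codon grouping: all 6 windows start before codon 50; the 5
        # windows reaching past codon 50 are C-terminal (boundary window both)
        assert summ["n_nterm_windows"] == 6 and summ["n_cterm_windows"] == 5
        # windows fully inside the purifying half stay below 1
        assert all(w.result.omega < 1.0 for w in track.windows[:3]
                   if w.result.omega is not None)

    def test_single_window_track_is_both_termini(self):
        a, b, _ = sim_codon_pair(45, 1.0, 60, seed=4)
        track = sel.sliding_window(a, b)
        summ = sel.nterm_cterm_summary(track)
        assert summ["n_nterm_windows"] == summ["n_cterm_windows"] == 1


class TestOmegaRecovery:
    @pytest.mark.parametrize("omega", [0.2, 0.5])
    def test_mean_estimate_tracks_realized_value(self, omega):
        """Estimated dN/dS should track the simulation's realized value."""
        est, real = [], []
        for s in range(30):
            a, b, truth = sim_codon_pair(500, omega, 400, seed=10_000 + s)
            r = sel.pairwise_dnds(a, b)
            w = realized_omega(a, truth)
            if r.omega is not None and w is not None:
                est.append(r.omega)
                real.append(w)
        assert len(est) >= 25
        assert abs(np.mean(est) - np.mean(real)) < 0.15
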