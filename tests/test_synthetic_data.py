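"""Generator contracts: determinism, planted-truth construction, guards."""

import numpy as np
import pytest

from dupdiverge import synthetic_data as sim
from dupdiverge.io_models import read_newick
from dupdiverge.selection import CODON_TABLE, STOP_CODONS, codon_sites


class TestCatalogSim:
    def test_planted_clusters_and_singletons_by_construction(self):
        cat, fam, truth = sim.sim_catalog_with_family(
            n_chroms=1, genes_per_chrom=100,
            planted_clusters=((0, 10, 3, 3),), n_singletons=1, seed=0)
        assert len(truth.clusters) == 1 and len(truth.clusters[0]) == 3
        assert len(truth.singletons) == 1
        assert fam == set(truth.singletons) | set(truth.clusters[0])
        for g in fam:
            assert g in cat

    def test_empty_family(self):
        cat, fam, truth = sim.sim_catalog_with_family(
            planted_clusters=(), n_singletons=0, seed=0)
        assert fam == set() and truth.clusters == [] and truth.singletons == []

    def test_same_seed_reproduces_catalog(self):
        c1, f1, _ = sim.sim_catalog_with_family(seed=8)
        c2, f2, _ = sim.sim_catalog_with_family(seed=8)
        assert c1.genes == c2.genes and f1 == f2

    def test_infeasible_placement_raises_before_output(self):
        with pytest.raises(ValueError):
            sim.sim_catalog_with_family(genes_per_chrom=20,
                                        planted_clusters=((0, 18, 5, 3),))


class TestParalogPairSim:
    def test_none_pair_differs_only_by_point_mutations(self):
        a, b, truth = sim.sim_paralog_pair(sim.NONE, seed=1)
        assert truth.mechanism == sim.NONE and truth.detail == {}
        assert a.exons == b.exons
        assert len(a.genomic_seq) == len(b.genomic_seq)
        diff = sum(x != y for x, y in zip(a.genomic_seq, b.genomic_seq))
        assert 0 < diff / len(a.genomic_seq) < 0.12

    def test_intron_elongation_hits_target_factor(self):
        a, b, truth = sim.sim_paralog_pair(sim.INTRON_ELONGATION, seed=2,
                                           elongation_factor=14.0)
        i = truth.detail["intron_index"]
        ratio = b.intron_lengths()[i] / a.intron_lengths()[i]
        assert ratio >= 14.0
        assert truth.detail["unit_len"] == 50

    def test_exon_split_geometry_recorded(self):
        a, b, truth = sim.sim_paralog_pair(sim.EXON_SPLIT, seed=3)
        i, cut = truth.detail["exon_index"], truth.detail["cut_offset"]
        assert len(b.exons) == len(a.exons) + 1
        assert b.exon_lengths()[i] == cut
        assert b.exon_lengths()[i] + b.exon_lengths()[i + 1] == a.exon_lengths()[i]

    def test_elongation_factor_at_most_two_rejected(self):
        with pytest.raises(ValueError):
            sim.sim_paralog_pair(sim.INTRON_ELONGATION, elongation_factor=1.5)

    def test_same_seed_reproduces_pair(self):
        a1, b1, _ = sim.sim_paralog_pair(sim.EXONIZATION, seed=5)
        a2, b2, _ = sim.sim_paralog_pair(sim.EXONIZATION, seed=5)
        assert a1.genomic_seq == a2.genomic_seq and b1.exons == b2.exons


class TestCodonPairSim:
    def test_omega_zero_realizes_no_nonsynonymous_changes(self):
        a, b, truth = sim.sim_codon_pair(40, omega=0.0, n_attempts=50, seed=0)
        assert truth.n_nonsyn == 0
        assert all(c not in STOP_CODONS
                   for s in (a, b) for c in (s[i:i + 3] for i in range(0, len(s), 3)))

    def test_neutral_ratio_approaches_site_ratio(self):
        """At ω = 1 the realized Nd/Sd ratio tracks N/S of the start sequence."""
        tot_n = tot_s = 0.0
        exp_ratio = []
        for s in range(100):
            a, _, truth = sim.sim_codon_pair(300, omega=1.0, n_attempts=60,
                                             seed=100 + s)
            tot_n += truth.n_nonsyn
            tot_s += truth.n_syn
            S = N = 0.0
            for i in range(0, len(a), 3):
                si, ni = codon_sites(a[i:i + 3])
                S += si
                N += ni
            exp_ratio.append(N / S)
        assert tot_n / tot_s == pytest.approx(np.mean(exp_ratio), rel=0.15)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            sim.sim_codon_pair(10, 1.0, 5)

    def test_same_seed_reproduces_pair(self):
        p1 = sim.sim_codon_pair(50, 0.3, 40, seed=6)
        p2 = sim.sim_codon_pair(50, 0.3, 40, seed=6)
        assert p1[0] == p2[0] and p1[1] == p2[1]


class TestGeneTreeSim:
    def test_zero_rates_reproduce_species_tree_topology(self, species_tree_3):
        trees, truth = sim.sim_gene_trees_dl(species_tree_3, 0.0, 0.0, 5, seed=0)
        assert truth.dup_per_branch == {} and truth.loss_per_branch == {}
        for t in trees:
            species = sorted(lbl.split("|")[0] for lbl in t.leaf_labels)
            assert species == ["A", "B", "C"]

    def test_terminal_duplication_creates_same_species_cherry(self, species_tree_3):
        trees, truth = sim.sim_gene_trees_dl(species_tree_3, 0.6, 0.0, 10, seed=1)
        assert sum(truth.dup_per_branch.values()) > 0
        # at least one tree holds two leaves of one species
        assert any(len({l.split("|")[0] for l in t.leaf_labels}) <
                   len(t.leaf_labels) for t in trees)

    def test_extinct_forest_raises(self, species_tree_3):
        with pytest.raises(ValueError, match="loss_rate"):
            sim.sim_gene_trees_dl(species_tree_3, 0.0, 50.0, 5, seed=2)

    def test_same_seed_reproduces_forest(self, species_tree_5):
        t1, tr1 = sim.sim_gene_trees_dl(species_tree_5, 0.3, 0.1, 20, seed=3)
        t2, tr2 = sim.sim_gene_trees_dl(species_tree_5, 0.3, 0.1, 20, seed=3)
        assert [t.tree.as_string("newick") for t in t1] == \
            [t.tree.as_string("newick") for t in t2]
        assert tr1.dup_per_branch == tr2.dup_per_branch


class TestExpressionSim:
    def test_noiseless_gene_peaks_at_archetype_stage(self):
        mat, truth = sim.sim_expression(n_genes=70, k=7, noise_sd=0.0, seed=0)
        for g in mat.index:
            peak = truth.peak_stage[g]
            if peak is not None:
                assert mat.loc[g].idxmax() == peak

    def test_divergent_pair_planted_with_distinct_peaks(self):
        mat, truth = sim.sim_expression(noise_sd=0.1, seed=1,
                                        pair_plan=("divergent",))
        ((pair, flag),) = truth.pair_flags.items()
        assert flag is True
        a, b = pair
        assert truth.peak_stage[a] != truth.peak_stage[b]

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            sim.sim_expression(noise_sd=-0.1)

    def test_same_seed_reproduces_matrix(self):
        m1, _ = sim.sim_expression(seed=9)
        m2, _ = sim.sim_expression(seed=9)
        assert m1.equals(m2)


class TestRepeatSim:
    def test_span_and_unit_by_construction(self):
        seq, truth = sim.sim_repeat_sequence(unit_len=50, n_copies=6,
                                             flank_len=500, mutation_rate=0.0,
                                             seed=0)
        assert truth.span == (500, 800) and truth.unit_len == 50
        assert len(seq) == 1300
        unit = seq[500:550]
        assert seq[500:800] == unit * 6

    def test_excessive_mutation_rate_refused(self):
        with pytest.raises(ValueError):
            sim.sim_repeat_sequence(mutation_rate=1.0)

    def test_guards_on_unit_and_copies(self):
        with pytest.raises(ValueError):
            sim.sim_repeat_sequence(unit_len=5)
        with pytest.raises(ValueError):
            sim.sim_repeat_sequence(n_copies=1)
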