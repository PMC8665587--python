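"""Tandem clustering against a brute-force pairwise-linkage oracle."""

import numpy as np
import pytest

from dupdiverge.io_models import GeneCatalog
from dupdiverge.tandem import (big_clusters, cluster_tandem, density_track,
                               summarize_tandem)
from dupdiverge.synthetic_data import sim_catalog_with_family

from oracles import tandem_components


def catalog_from_ranks(n_genes=60, chrom="c"):
    return GeneCatalog(genes={chrom: [(f"g{i}", 100 * i, 100 * i + 50, "+")
                                      for i in range(n_genes)]})


def random_catalog(rng, n_chroms=2, max_genes=500):
    genes = {}
    for c in range(n_chroms):
        n = int(rng.integers(5, max_genes // n_chroms))
        genes[f"c{c}"] = [(f"c{c}g{i}", 100 * i, 100 * i + 50, "+")
                          for i in range(n)]
    return GeneCatalog(genes=genes)


class TestClusterTandem:
    def test_gap_within_20_links_beyond_does_not(self):
        cat = catalog_from_ranks()
        tcs = cluster_tandem(cat, {"g1", "g5", "g30"})
        assert [c.members for c in tcs.clusters] == [["g1", "g5"]]
        assert tcs.singletons == {"g30"}

    def test_transitive_chaining_joins_distant_ends(self):
        # consecutive gaps of 13; ends are 27 apart yet chained into one cluster
        cat = catalog_from_ranks()
        tcs = cluster_tandem(cat, {"g1", "g15", "g29"})
        assert [c.members for c in tcs.clusters] == [["g1", "g15", "g29"]]

    def test_chaining_disabled_splits_the_chain(self):
        cat = catalog_from_ranks()
        tcs = cluster_tandem(cat, {"g1", "g15", "g29"}, chain=False)
        assert {len(c.members) for c in tcs.clusters} == {2}

    def test_different_chromosomes_never_cluster(self):
        cat = GeneCatalog(genes={f"c{i}": [(f"g{i}", 0, 10, "+")] for i in range(4)})
        tcs = cluster_tandem(cat, {f"g{i}" for i in range(4)})
        assert not tcs.clusters and len(tcs.singletons) == 4

    def test_unknown_family_member_is_an_error(self):
        with pytest.raises(KeyError, match="ghost"):
            cluster_tandem(catalog_from_ranks(), {"g1", "ghost"})

    def test_matches_brute_force_components_on_random_catalogs(self):
        rng = np.random.default_rng(123)
        for rep in range(200):
            cat = random_catalog(rng)
            all_ids = [g for lst in cat.genes.values() for g, *_ in lst]
            fam = set(rng.choice(all_ids, size=min(len(all_ids), 25), replace=False))
            gap = int(rng.integers(0, 30))
            tcs = cluster_tandem(cat, fam, max_gap=gap)
            got = sorted(sorted(c.members) for c in tcs.clusters if True)
            got_all = sorted([sorted(c.members) for c in tcs.clusters]
                             + [[s] for s in tcs.singletons])
            ranks = {}
            for g in fam:
                chrom, r = cat.rank(g)
                ranks.setdefault(chrom, {})[g] = r
            exp = sorted(sorted(c) for c in tandem_components(ranks, gap))
            assert got_all == exp

    def test_tandem_count_monotone_in_max_gap(self):
        rng = np.random.default_rng(5)
        cat = random_catalog(rng, n_chroms=1)
        all_ids = [g for g, *_ in cat.genes["c0"]]
        fam = set(rng.choice(all_ids, size=min(20, len(all_ids)), replace=False))
        counts = [cluster_tandem(cat, fam, max_gap=g).n_tandem for g in range(0, 40, 3)]
        assert counts == sorted(counts)

    def test_contig_fragmentation_never_overestimates(self):
        """Splitting a chromosome into contigs only removes linkage."""
        rng = np.random.default_rng(11)
        for rep in range(20):
            cat = random_catalog(rng, n_chroms=1, max_genes=400)
            lst = cat.genes["c0"]
            all_ids = [g for g, *_ in lst]
            fam = set(rng.choice(all_ids, size=min(30, len(all_ids)), replace=False))
            full = cluster_tandem(cat, fam).n_tandem
            cut = sorted(rng.choice(len(lst), size=3, replace=False))
            pieces, prev = {}, 0
            for i, c in enumerate([*cut, len(lst)]):
                if c > prev:
                    pieces[f"ctg{i}"] = lst[prev:c]
                prev = c
            frag = cluster_tandem(GeneCatalog(genes=pieces), fam).n_tandem
            assert frag <= full


class TestSummaryAndFilters:
    def test_counts_and_rounded_percent(self):
        cat = catalog_from_ranks()
        fam = {"g0", "g1", "g2", "g30", "g55"}  # cluster of 3 + 2 singletons
        tcs = cluster_tandem(cat, fam)
        s = summarize_tandem(tcs, 5)
        assert s == {"n_single": 2, "n_tandem": 3, "percent_tandem": 60}

    def test_family_size_mismatch_is_an_error(self):
        tcs = cluster_tandem(catalog_from_ranks(), {"g1", "g2"})
        with pytest.raises(ValueError):
            summarize_tandem(tcs, 99)

    def test_all_singletons_zero_percent(self):
        tcs = cluster_tandem(catalog_from_ranks(), {"g0", "g30"})
        assert summarize_tandem(tcs, 2)["percent_tandem"] == 0

    def test_big_clusters_filters_by_size_in_order(self):
        cat = catalog_from_ranks(200)
        fam = {f"g{i}" for i in range(6)} | {f"g{i}" for i in range(100, 105)} \
            | {f"g{i}" for i in range(160, 164)}
        tcs = cluster_tandem(cat, fam)
        big = big_clusters(tcs, min_size=5)
        assert [len(c.members) for c in big] == [6, 5]
        assert big[0].span[0] <= big[1].span[0]

    def test_planted_partition_recovered_exactly(self):
        cat, fam, truth = sim_catalog_with_family(
            n_chroms=2, genes_per_chrom=150,
            planted_clusters=((0, 10, 5, 3), (1, 40, 7, 2)),
            n_singletons=3, seed=21)
        tcs = cluster_tandem(cat, fam)
        assert sorted(sorted(c.members) for c in tcs.clusters) == \
            sorted(sorted(c) for c in truth.clusters)
        assert tcs.singletons == set(truth.singletons)
        s = summarize_tandem(tcs, len(fam))
        assert s["n_tandem"] == 12 and s["n_single"] == 3


class TestDensityTrack:
    def test_counts_by_start_with_partial_last_window(self):
        cat = GeneCatalog(
            genes={"c": [("a", 100_000, 101_000, "+"), ("b", 200_000, 201_000, "+"),
                         ("x", 1_500_000, 1_501_000, "+")]},
            chrom_lengths={"c": 2_000_000})
        (track,) = density_track(cat, {"a", "b", "x"})
        assert track.counts == [2, 1]

    def test_window_sum_conserves_family_count(self):
        cat, fam, _ = sim_catalog_with_family(seed=3)
        tracks = density_track(cat, fam, window_bp=500_000)
        per_chrom = {}
        for g in fam:
            per_chrom[cat.rank(g)[0]] = per_chrom.get(cat.rank(g)[0], 0) + 1
        for t in tracks:
            assert sum(t.counts) == per_chrom.get(t.chrom, 0)

    def test_empty_family_gives_zero_track(self):
        cat, _, _ = sim_catalog_with_family(seed=4)
        assert all(sum(t.counts) == 0 for t in density_track(cat, set()))
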