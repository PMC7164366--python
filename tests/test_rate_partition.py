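"""HKY distances, rate binning, codon-position splits, clocklike ranking."""

import math

import numpy as np
import pytest

from cetdate.alignments import GeneAlignment
from cetdate.priors import BdParams, ClockModelSpec
from cetdate.rate_partition import (GeneRateTable, Partition,
                                    PartitionScheme, bin_genes,
                                    gene_rate_table, hky_distance,
                                    partition_alignments, rank_clocklike,
                                    split_codon_positions)
from cetdate.substitution import SubstitutionParams
from cetdate.synthetic_data import (gene_tree_newick, simulate_alignment,
                                    simulate_branch_rates,
                                    simulate_timetree)
from cetdate.trees import TimeTree


class TestHkyDistance:
    def test_identical_sequences_zero(self):
        s = "ACGTACGTAC" * 30
        res = hky_distance(s, s)
        assert res.distance == 0.0 and not res.saturated

    def test_jc69_closed_form_at_kappa_one(self):
        # 10% observed differences, kappa fixed to 1, equal frequencies:
        # HKY reduces to JC69, d = -(3/4) ln(1 - 4*0.1/3) = 0.10732
        n, k = 300, 30
        a = ("ACGT" * 75)[:n]
        b = list(a)
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}  # transversions
        idx = np.linspace(0, n - 1, k).astype(int)
        for i in idx:
            b[i] = flip[b[i]]
        res = hky_distance(a, "".join(b), freqs=(0.25,) * 4, kappa=1.0)
        want = -0.75 * math.log(1 - 4 * 0.1 / 3)
        assert res.distance == pytest.approx(want, abs=1e-4)

    def test_simulation_recovery(self, bd):
        # d = 0.2, kappa = 4, 10^5 sites
        tree = TimeTree(["a", "b"], np.array([2, 2, -1]),
                        np.array([0.0, 0.0, 10.0]))
        sub = SubstitutionParams(4.0, (0.3, 0.2, 0.2, 0.3), 1.0, 1)
        rates = np.full(3, 1.0)  # duration 0.1 units each -> d = 0.2
        aln = simulate_alignment(tree, rates, sub, 34000, seed=1,
                                 cp_multipliers=(1, 1, 1))
        res = hky_distance(aln.matrix[0], aln.matrix[1])
        assert res.distance == pytest.approx(0.2, abs=0.01)
        assert res.kappa == pytest.approx(4.0, rel=0.2)

    def test_no_shared_sites_rejected(self):
        a = GeneAlignment.from_strings("g", {"x": "AC--", "y": "--GT"})
        with pytest.raises(ValueError):
            hky_distance(a.row("x"), a.row("y"))

    def test_saturation_flag(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 4, 2000).astype(np.uint8)
        y = rng.integers(0, 4, 2000).astype(np.uint8)
        res = hky_distance(x, y)
        assert res.saturated
        assert res.distance == 10.0


class TestGeneRateTable:
    def _aln(self, gid, taxa, n=60, seed=0):
        from cetdate.synthetic_data import random_coding_alignment
        return random_coding_alignment(gid, taxa, n, seed=seed)

    def test_primary_pair_used(self):
        a = self._aln("g1", ["orca", "minke", "other"])
        t = gene_rate_table([a], ("orca", "minke"), ["fallback"])
        assert t.rates["g1"][1] == ("orca", "minke")

    def test_fallback_substitutes_missing_partner(self):
        a = self._aln("g1", ["orca", "fin", "sei"])
        t = gene_rate_table([a], ("orca", "minke"), ["humpback", "fin"])
        assert t.rates["g1"][1] == ("orca", "fin")

    def test_unratable_gene_logged(self):
        a = self._aln("g1", ["x", "y"])
        t = gene_rate_table([a], ("orca", "minke"), ["humpback"])
        assert t.unratable == ["g1"]
        assert "g1" not in t.rates


def make_table(n, seed=0):
    rng = np.random.default_rng(seed)
    d = np.sort(rng.uniform(0.01, 2.0, n))
    return GeneRateTable({f"g{i:05d}": (float(d[i]), ("a", "b"))
                          for i in range(n)})


class TestBinGenes:
    def test_3096_genes_into_3_equal_bins(self):
        scheme = bin_genes(make_table(3096), 3)
        assert [len(p.gene_ids) for p in scheme.partitions] == [1032] * 3

    def test_3096_genes_into_10_bins(self):
        scheme = bin_genes(make_table(3096), 10)
        sizes = [len(p.gene_ids) for p in scheme.partitions]
        assert sizes == [310] * 6 + [309] * 4
        assert sum(sizes) == 3096

    def test_single_bin_is_identity(self):
        t = make_table(50)
        scheme = bin_genes(t, 1)
        assert set(scheme.partitions[0].gene_ids) == set(t.rates)

    def test_k_exceeding_genes_rejected(self):
        with pytest.raises(ValueError):
            bin_genes(make_table(5), 6)

    def test_rate_ordering_and_permutation_invariance(self):
        t = make_table(200, seed=3)
        items = list(t.rates.items())
        rng = np.random.default_rng(4)
        rng.shuffle(items)
        t2 = GeneRateTable(dict(items))
        s1 = bin_genes(t, 7)
        s2 = bin_genes(t2, 7)
        assert [p.gene_ids for p in s1.partitions] == \
            [p.gene_ids for p in s2.partitions]
        # mean within-bin distance non-decreasing
        means = [np.mean([t.rates[g][0] for g in p.gene_ids])
                 for p in s1.partitions]
        assert all(a <= b for a, b in zip(means, means[1:]))


class TestSplitCodonPositions:
    def test_three_becomes_six(self):
        s = split_codon_positions(bin_genes(make_table(30), 3))
        assert s.n_partitions == 6
        assert [p.codon_class for p in s.partitions] == \
            ["12", "3"] * 3

    def test_ten_becomes_twenty(self):
        s = split_codon_positions(bin_genes(make_table(40), 10))
        assert s.n_partitions == 20

    def test_double_split_rejected(self):
        s = split_codon_positions(bin_genes(make_table(30), 3))
        with pytest.raises(ValueError):
            split_codon_positions(s)

    def test_site_counts_two_to_one(self, tree8, sub5):
        spec = ClockModelSpec("STR", 0.2, 0.0)
        r = simulate_branch_rates(tree8, spec, seed=1)
        genes = {f"g{i}": simulate_alignment(tree8, r, sub5, 50,
                                             seed=10 + i,
                                             gene_id=f"g{i}")
                 for i in range(6)}
        table = GeneRateTable({g: (0.1 * i, ("t1", "t8"))
                               for i, g in enumerate(genes)})
        scheme = split_codon_positions(bin_genes(table, 3))
        parts = partition_alignments(genes, scheme)
        for p12, p3 in zip(parts[::2], parts[1::2]):
            assert p12.n_sites == 2 * p3.n_sites


class TestRankClocklike:
    def test_ultrametric_tree_ranks_first(self, bd):
        tree = simulate_timetree(8, 100.0, bd, seed=5)
        strict = simulate_branch_rates(
            tree, ClockModelSpec("STR", 0.2, 0.0), seed=1)
        noisy = simulate_branch_rates(
            tree, ClockModelSpec("IR", 0.2, 0.6), seed=2)
        trees = {"clock": gene_tree_newick(tree, strict),
                 "wobbly": gene_tree_newick(tree, noisy)}
        ranked, _ = rank_clocklike(trees, tree, 2)
        assert ranked[0].gene_id == "clock"
        assert ranked[0].clock_variance == pytest.approx(0.0, abs=1e-12)

    def test_identical_topology_full_agreement(self, bd):
        tree = simulate_timetree(8, 100.0, bd, seed=6)
        r = simulate_branch_rates(tree, ClockModelSpec("STR", 0.2, 0.0),
                                  seed=1)
        ranked, _ = rank_clocklike(
            {"g": gene_tree_newick(tree, r)}, tree, 1)
        assert ranked[0].agreement == 1.0

    def test_small_trees_excluded(self, bd):
        tree = simulate_timetree(8, 100.0, bd, seed=7)
        ranked, excluded = rank_clocklike(
            {"tiny": "(a:1,(b:1,c:1):1);"}, tree, 5)
        assert ranked == []
        assert "tiny" in excluded[0]

    def test_strict_genes_outrank_variable_genes(self, bd):
        # 10 strict + 10 high-variance genes; the strict ones should
        # occupy the top 10 ranks in >= 9 of 10 replicates
        wins = 0
        for rep in range(10):
            tree = simulate_timetree(10, 100.0, bd, seed=100 + rep)
            trees = {}
            for i in range(10):
                r = simulate_branch_rates(
                    tree, ClockModelSpec("STR", 0.2, 0.0),
                    seed=rep * 40 + i)
                trees[f"s{i}"] = gene_tree_newick(tree, r)
            for i in range(10):
                r = simulate_branch_rates(
                    tree, ClockModelSpec("IR", 0.2, 0.5),
                    seed=rep * 40 + 20 + i)
                trees[f"v{i}"] = gene_tree_newick(tree, r)
            ranked, _ = rank_clocklike(trees, tree, 10)
            if all(s.gene_id.startswith("s") for s in ranked):
                wins += 1
        assert wins >= 9
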