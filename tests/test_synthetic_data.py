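"""Synthetic-data generator: distributions, determinism, corruption log."""

import numpy as np
import pytest

from cetdate.priors import (BdParams, Calibration, ClockModelSpec,
                            bd_kernel_cdf)
from cetdate.substitution import SubstitutionParams
from cetdate.synthetic_data import (CorruptionRules, corrupt_fixture,
                                    gene_rng, inject_stop,
                                    make_calibrations,
                                    random_coding_alignment,
                                    remove_internal_stops,
                                    simulate_alignment,
                                    simulate_branch_rates,
                                    simulate_timetree)


class TestSimulateTimetree:
    def test_two_tips_root_age_exact(self, bd):
        t = simulate_timetree(2, 36.4, bd, seed=1)
        assert t.n_tips == 2
        assert t.root_age == 36.4

    def test_invalid_arguments(self, bd):
        with pytest.raises(ValueError):
            simulate_timetree(1, 10.0, bd)
        with pytest.raises(ValueError):
            simulate_timetree(5, -1.0, bd)
        with pytest.raises(ValueError):
            BdParams(-1.0, 1.0, 0.1)

    def test_determinism(self, bd):
        a = simulate_timetree(30, 50.0, bd, seed=7)
        b = simulate_timetree(30, 50.0, bd, seed=7)
        assert np.array_equal(a.parent, b.parent)
        assert np.array_equal(a.ages, b.ages)
        c = simulate_timetree(30, 50.0, bd, seed=8)
        assert not np.array_equal(a.ages, c.ages)

    def test_age_ordering_invariant(self, bd):
        for seed in range(5):
            t = simulate_timetree(40, 80.0, bd, seed=seed)
            for v in range(t.n_nodes):
                p = t.parent[v]
                if p != -1:
                    assert t.ages[p] > t.ages[v]

    def test_node_age_ecdf_matches_kernel(self, bd):
        # pooled non-root internal ages across replicates vs the kernel
        # CDF, at a root age of 1 time unit (100 Ma)
        ages = []
        for seed in range(500):
            t = simulate_timetree(200, 100.0, bd, seed=seed)
            inner = t.ages[t.internal_nodes] / 100.0
            ages.append(inner[inner < 1.0])
        x = np.sort(np.concatenate(ages))
        ecdf = np.arange(1, x.size + 1) / x.size
        ks = np.max(np.abs(ecdf - bd_kernel_cdf(x, 1.0, bd)))
        assert ks < 0.05


class TestSimulateBranchRates:
    def test_strict_clock_constant(self, tree8):
        spec = ClockModelSpec("STR", 0.05, 0.0)
        r = simulate_branch_rates(tree8, spec, seed=1)
        vals = r[~np.isnan(r)]
        assert np.all(vals == 0.05)

    def test_ir_lognormal_mean_correction(self, bd):
        # mean of log rate = log(mu) - sigma2/2 (3 standard errors)
        big = simulate_timetree(5000, 100.0, bd, seed=3)
        spec = ClockModelSpec("IR", 0.1, 0.25)
        logs = []
        for seed in range(10):
            r = simulate_branch_rates(big, spec, seed=seed)
            logs.append(np.log(r[~np.isnan(r)]))
        logs = np.concatenate(logs)
        se = logs.std() / np.sqrt(logs.size)
        assert abs(logs.mean() - (np.log(0.1) - 0.125)) < 3 * se

    def test_ar_degenerate_diffusion(self, tree8):
        spec = ClockModelSpec("AR", 0.1, 0.0)
        r = simulate_branch_rates(tree8, spec, seed=2)
        assert np.allclose(r[~np.isnan(r)], 0.1)

    def test_ar_rate_martingale(self, bd):
        # E[child rate | parent rate] = parent rate: the mean of
        # child/parent ratios over many branches is 1 within 3 SE
        big = simulate_timetree(3000, 100.0, bd, seed=4)
        spec = ClockModelSpec("AR", 0.1, 0.4)
        ratios = []
        for seed in range(4):
            r = simulate_branch_rates(big, spec, seed=seed)
            for v in range(big.n_nodes):
                p = big.parent[v]
                if p != -1 and p != big.root and not np.isnan(r[p]):
                    ratios.append(r[v] / r[p])
        ratios = np.array(ratios)
        se = ratios.std() / np.sqrt(ratios.size)
        assert abs(ratios.mean() - 1.0) < 3 * se


class TestSimulateAlignment:
    def test_zero_rates_identical_sequences(self, tree8, sub5):
        r = np.zeros(tree8.n_nodes)
        a = simulate_alignment(tree8, r, sub5, 50, seed=1)
        for i in range(1, a.n_taxa):
            assert np.array_equal(a.matrix[0], a.matrix[i])

    def test_root_composition_matches_freqs(self, bd):
        t = simulate_timetree(2, 1.0, bd, seed=1)
        sub = SubstitutionParams(1.0, (0.4, 0.1, 0.1, 0.4), 1.0, 1)
        a = simulate_alignment(t, np.zeros(3), sub, 34000, seed=2)
        counts = np.bincount(a.matrix[0], minlength=4) / a.n_sites
        assert np.allclose(counts, (0.4, 0.1, 0.1, 0.4), atol=0.01)

    def test_extreme_kappa_suppresses_transversions(self, bd):
        t = simulate_timetree(2, 100.0, bd, seed=1)
        sub = SubstitutionParams(1000.0, (0.25,) * 4, 1.0, 1)
        rates = np.full(t.n_nodes, 0.15)
        a = simulate_alignment(t, rates, sub, 34000, seed=3,
                               cp_multipliers=(1, 1, 1))
        x, y = a.matrix[0], a.matrix[1]
        diff = x != y
        purine = np.isin(x, (0, 2))
        transition = diff & (purine == np.isin(y, (0, 2)))
        tv_frac = (diff & ~transition).sum() / diff.sum()
        assert tv_frac < 0.05

    def test_determinism(self, tree8, sub5):
        spec = ClockModelSpec("IR", 0.2, 0.3)
        r = simulate_branch_rates(tree8, spec, seed=5)
        a = simulate_alignment(tree8, r, sub5, 100, seed=6)
        b = simulate_alignment(tree8, r, sub5, 100, seed=6)
        assert np.array_equal(a.matrix, b.matrix)

    def test_site_count_and_labels(self, tree8, sub5):
        r = np.full(tree8.n_nodes, 0.1)
        a = simulate_alignment(tree8, r, sub5, 17, seed=1)
        assert a.n_sites == 51
        assert set(a.taxa) == set(tree8.labels)


class TestMakeCalibrations:
    def test_narrow_root_window(self, bd):
        t = simulate_timetree(4, 1.0, bd, seed=1)
        cals = make_calibrations(t, [("root", "root")], (0.001, 0.001),
                                 (0.0, 0.0))
        c = cals.entries[("root", "root")]
        assert (c.t_lower, c.t_upper) == pytest.approx((0.999, 1.001))

    def test_zero_width_rejected(self, tree8):
        with pytest.raises(ValueError):
            make_calibrations(tree8, [("root", "root")], (0.0, 0.0))

    def test_every_calibration_brackets_truth(self, tree16):
        anchors = [("root", "root")]
        for v in tree16.internal_nodes[:4]:
            tips = sorted(tree16.clade_tips(v))
            if len(tips) >= 2:
                anchors.append((tips[0], tips[-1]))
        cals = make_calibrations(tree16, anchors, (0.2, 0.3))
        for node, cal in cals.resolve(tree16).items():
            assert cal.t_lower <= tree16.ages[node] <= cal.t_upper

    def test_unknown_anchor_tip(self, tree8):
        with pytest.raises(KeyError):
            make_calibrations(tree8, [("nope", "t1")], (0.1, 0.1))


class TestCorruptFixture:
    def _genes(self, n=20, seed=0):
        taxa = [f"t{i}" for i in range(6)]
        return [random_coding_alignment(f"g{i:03d}", taxa, 50,
                                        seed=seed + i) for i in range(n)]

    def test_zero_rules_identity(self):
        genes = self._genes()
        out, log = corrupt_fixture(genes, CorruptionRules(), seed=1)
        assert log == []
        for a, b in zip(genes, out):
            assert np.array_equal(a.matrix, b.matrix)
        assert out[0] is not genes[0]  # copies, not aliases

    def test_stop_injection_logged_exactly(self):
        genes = self._genes()
        rules = CorruptionRules(n_stop_genes=5, stops_per_gene=2)
        out, log = corrupt_fixture(genes, rules, seed=2)
        stops = [e for e in log if e["kind"] == "stop"]
        assert len(stops) == 10
        by_gene = {a.gene_id: a for a in out}
        for e in stops:
            aln = by_gene[e["gene"]]
            i = aln.taxa.index(e["taxon"])
            codon = aln.matrix[i, 3 * e["codon"]:3 * e["codon"] + 3]
            decoded = "".join("ACGT-N"[c] for c in codon)
            assert decoded == e["stop"]

    def test_dropout_binomial(self):
        genes = self._genes(n=300)
        rules = CorruptionRules(dropout={"t3": 0.6})
        out, log = corrupt_fixture(genes, rules, seed=3)
        missing = sum("t3" not in a.taxa for a in out)
        # 3 sigma binomial window around 180 of 300
        assert abs(missing - 180) < 3 * np.sqrt(300 * 0.6 * 0.4)

    def test_determinism(self):
        genes = self._genes()
        rules = CorruptionRules(n_stop_genes=3, n_frameshift_genes=3)
        _, log1 = corrupt_fixture(genes, rules, seed=9)
        _, log2 = corrupt_fixture(genes, rules, seed=9)
        assert log1 == log2


def test_gene_rng_independent_of_order():
    a = gene_rng(5, "gene_x").random(3)
    _ = gene_rng(5, "gene_y").random(3)
    b = gene_rng(5, "gene_x").random(3)
    assert np.array_equal(a, b)


def test_remove_internal_stops_leaves_clean_cds(tree8, sub5):
    spec = ClockModelSpec("IR", 0.4, 0.3)
    r = simulate_branch_rates(tree8, spec, seed=11)
    a = remove_internal_stops(
        simulate_alignment(tree8, r, sub5, 200, seed=12))
    from cetdate.gene_qc import screen_premature_stops
    assert screen_premature_stops(a) == []
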