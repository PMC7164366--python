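"""Pruning likelihood, branch-length MLEs, Hessian and the quadratic
approximation."""

import numpy as np
import pytest
from scipy.linalg import expm

from cetdate.alignments import GeneAlignment
from cetdate.likelihood import (ApproxLikSurface, CachedLikelihood,
                                PhyloLikelihood, build_surface,
                                hessian_at_mle, mle_branch_lengths)
from cetdate.priors import ClockModelSpec
from cetdate.substitution import HkyModel, SubstitutionParams
from cetdate.synthetic_data import (simulate_alignment,
                                    simulate_branch_rates,
                                    simulate_timetree)
from cetdate.trees import TimeTree


def two_taxon_tree():
    return TimeTree(["t1", "t2"], np.array([2, 2, -1]),
                    np.array([0.0, 0.0, 1.0]))


def rooted_lengths_from(tree, rates):
    bl = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes):
        if v != tree.root:
            bl[v] = (tree.ages[tree.parent[v]] - tree.ages[v]) / 100.0 \
                * rates[v]
    return bl


class TestPruning:
    def test_two_taxon_single_site_matrix_exponential(self, sub1):
        aln = GeneAlignment.from_strings("g", {"t1": "A", "t2": "G"})
        lik = PhyloLikelihood(aln, two_taxon_tree(), sub1)
        model = HkyModel(sub1)
        for d in (0.05, 0.37, 1.4):
            P = expm(model.Q * d)
            want = np.log(model.pi[0] * P[0, 2])
            assert lik.loglik(np.array([d])) == pytest.approx(
                want, abs=1e-10)

    def test_zero_lengths_constant_site_gives_pi(self, sub1):
        aln = GeneAlignment.from_strings("g", {"t1": "C", "t2": "C"})
        lik = PhyloLikelihood(aln, two_taxon_tree(), sub1)
        assert lik.loglik(np.array([0.0])) == pytest.approx(
            np.log(sub1.base_freqs[1]))

    def test_root_position_irrelevant(self, sub1):
        # pulley principle: only the sum of the two root-adjacent branch
        # lengths matters for a reversible model
        parent = np.array([4, 4, 5, 5, 6, 6, -1])
        ages = np.array([0, 0, 0, 0, 10.0, 20.0, 30.0])
        tree = TimeTree(["a", "b", "c", "d"], parent, ages)
        aln = GeneAlignment.from_strings(
            "g", {"a": "ACGTAC", "b": "ACGTTC",
                  "c": "AGGTAC", "d": "ACGAAC"})
        lik = PhyloLikelihood(aln, tree, sub1)
        blen = np.array([0.1, 0.2, 0.15, 0.05, 0.3, 0.25, 0.0])
        ref = lik.loglik_rooted(blen)
        total = blen[4] + blen[5]
        for x in (0.0, 0.1, total):
            b2 = blen.copy()
            b2[4], b2[5] = x, total - x
            assert lik.loglik_rooted(b2) == pytest.approx(ref, abs=1e-8)

    def test_rerooting_same_unrooted_tree(self, sub1):
        # ((a,b),(c,d)) rooted on the internal edge vs (((a,b),c),d)
        # rooted on d's branch: same unrooted tree and lengths
        aln = GeneAlignment.from_strings(
            "g", {"a": "ACGTACGGTT", "b": "ACGTTCGGTA",
                  "c": "AGGTACGCTT", "d": "TCGAACGGTT"})
        t1 = TimeTree(["a", "b", "c", "d"],
                      np.array([4, 4, 5, 5, 6, 6, -1]),
                      np.array([0, 0, 0, 0, 10.0, 20.0, 30.0]))
        l_ab, l_a, l_b, l_c, l_d, l_int = 0.3, 0.1, 0.2, 0.15, 0.05, 0.3
        b1 = np.zeros(7)
        b1[[0, 1, 2, 3]] = [l_a, l_b, l_c, l_d]
        b1[4] = l_int          # ab-clade edge carries the internal edge
        b1[5] = 0.0
        lik1 = PhyloLikelihood(aln, t1, sub1)
        # rerooted: (((a,b),c),d); internal edge now above the (a,b) node
        t2 = TimeTree(["a", "b", "c", "d"],
                      np.array([4, 4, 5, 6, 5, 6, -1]),
                      np.array([0, 0, 0, 0, 10.0, 20.0, 30.0]))
        b2 = np.zeros(7)
        b2[[0, 1, 2, 3]] = [l_a, l_b, l_c, l_d]
        b2[4] = l_int
        b2[5] = 0.0
        lik2 = PhyloLikelihood(aln, t2, sub1)
        assert lik1.loglik_rooted(b1) == pytest.approx(
            lik2.loglik_rooted(b2), abs=1e-8)

    def test_unknown_taxon_rejected(self, sub1):
        aln = GeneAlignment.from_strings("g", {"t1": "A", "zz": "G"})
        with pytest.raises(KeyError):
            PhyloLikelihood(aln, two_taxon_tree(), sub1)

    def test_pattern_compression_equals_site_sum(self, sub1):
        # an alignment with repeated columns scores the repeat count
        # times the single-column log likelihood
        one = GeneAlignment.from_strings("g", {"t1": "A", "t2": "G"})
        rep = GeneAlignment.from_strings("g", {"t1": "AAAA",
                                               "t2": "GGGG"})
        tree = two_taxon_tree()
        b = np.array([0.3])
        l1 = PhyloLikelihood(one, tree, sub1).loglik(b)
        l4 = PhyloLikelihood(rep, tree, sub1).loglik(b)
        assert l4 == pytest.approx(4 * l1, rel=1e-12)

    def test_missing_data_marginalizes(self, sub1):
        # an all-N sequence contributes nothing: likelihood equals the
        # single-sequence stationary probability
        aln = GeneAlignment.from_strings("g", {"t1": "A", "t2": "N"})
        lik = PhyloLikelihood(aln, two_taxon_tree(), sub1)
        assert lik.loglik(np.array([0.7])) == pytest.approx(
            np.log(sub1.base_freqs[0]))

    def test_batch_matches_single(self, tree8, sub5):
        spec = ClockModelSpec("IR", 0.2, 0.3)
        r = simulate_branch_rates(tree8, spec, seed=1)
        aln = simulate_alignment(tree8, r, sub5, 100, seed=2)
        lik = PhyloLikelihood(aln, tree8, sub5)
        rng = np.random.default_rng(3)
        B = rng.uniform(0.001, 0.5, (7, lik.n_branches))
        batch = lik.loglik_batch(B)
        single = np.array([lik.loglik(b) for b in B])
        assert np.allclose(batch, single, rtol=1e-12)


class TestMle:
    def test_recovers_true_lengths(self, bd, sub5):
        tree = simulate_timetree(8, 100.0, bd, seed=10)
        spec = ClockModelSpec("STR", 0.3, 0.0)
        r = simulate_branch_rates(tree, spec, seed=11)
        aln = simulate_alignment(tree, r, sub5, 667, seed=12,
                                 cp_multipliers=(1, 1, 1))
        lik = PhyloLikelihood(aln, tree, sub5)
        b_hat, logl = mle_branch_lengths(lik)
        true_rooted = rooted_lengths_from(tree, r)
        true_b = true_rooted[lik.branch_nodes]
        other = lik.merged_other
        rep = lik.rep_index if hasattr(lik, "rep_index") else None
        idx = list(lik.branch_nodes).index(lik.merged_rep)
        true_b[idx] += true_rooted[other]
        # 2 kb sites: estimates should be close to the truth
        assert np.mean(np.abs(b_hat - true_b)) < 0.01
        assert np.corrcoef(b_hat, true_b)[0, 1] > 0.98

    def test_identical_sequences_zero_lengths(self, sub1):
        aln = GeneAlignment.from_strings(
            "g", {"t1": "ACGTACGTAC" * 10, "t2": "ACGTACGTAC" * 10})
        lik = PhyloLikelihood(aln, two_taxon_tree(), sub1)
        b_hat, logl = mle_branch_lengths(lik)
        assert b_hat[0] == 0.0

    def test_local_optimality(self, tree8, sub5):
        spec = ClockModelSpec("IR", 0.2, 0.2)
        r = simulate_branch_rates(tree8, spec, seed=20)
        aln = simulate_alignment(tree8, r, sub5, 300, seed=21,
                                 cp_multipliers=(1, 1, 1))
        lik = PhyloLikelihood(aln, tree8, sub5)
        b_hat, logl = mle_branch_lengths(lik)
        rng = np.random.default_rng(5)
        for _ in range(100):
            pert = b_hat * np.exp(0.1 * rng.standard_normal(b_hat.size))
            assert lik.loglik(pert) <= logl + 1e-7


class TestHessian:
    def test_one_branch_second_derivative(self, sub1):
        aln = GeneAlignment.from_strings(
            "g", {"t1": "ACGTACGTACGTACGTTGCA",
                  "t2": "ACGAACGTATGTACGTTGCA"})
        lik = PhyloLikelihood(aln, two_taxon_tree(), sub1)
        b_hat, logl = mle_branch_lengths(lik)
        g, H = hessian_at_mle(lik, b_hat, f0=logl)
        # high-order Richardson estimate as the independent oracle
        h = 1e-5
        f = lambda x: lik.loglik(np.array([x]))
        x = b_hat[0]
        d2 = (-f(x + 2 * h) + 16 * f(x + h) - 30 * f(x)
              + 16 * f(x - h) - f(x - 2 * h)) / (12 * h ** 2)
        assert H[0, 0] == pytest.approx(d2, rel=1e-3)
        assert abs(g[0]) < 1e-2

    def test_quadratic_function_recovered_exactly(self):
        rng = np.random.default_rng(7)
        m = 5
        A = rng.standard_normal((m, m))
        A = -(A @ A.T + np.eye(m))
        gv = rng.standard_normal(m)
        x0 = rng.uniform(0.5, 1.0, m)

        class Quad:
            def loglik(self, b):
                d = b - x0
                return float(gv @ d + 0.5 * d @ A @ d)

        g, H = hessian_at_mle(Quad(), x0)
        assert np.allclose(H, A, atol=1e-5)
        assert np.allclose(g, gv, atol=1e-7)

    def test_symmetry(self, tree8, sub5):
        spec = ClockModelSpec("STR", 0.2, 0.0)
        r = simulate_branch_rates(tree8, spec, seed=30)
        aln = simulate_alignment(tree8, r, sub5, 100, seed=31)
        lik = PhyloLikelihood(aln, tree8, sub5)
        b_hat, logl = mle_branch_lengths(lik)
        g, H = hessian_at_mle(lik, b_hat, f0=logl)
        assert np.max(np.abs(H - H.T)) < 1e-8


@pytest.fixture(scope="module")
def surface_case():
    from cetdate.priors import BdParams
    bd = BdParams()
    sub = SubstitutionParams(4.0, (0.3, 0.2, 0.2, 0.3), 0.8, 5)
    tree = simulate_timetree(16, 100.0, bd, seed=50)
    spec = ClockModelSpec("AR", 0.2, 0.2)
    r = simulate_branch_rates(tree, spec, seed=51)
    aln = simulate_alignment(tree, r, sub, 667, seed=52,
                             cp_multipliers=(1, 1, 1))
    lik = PhyloLikelihood(aln, tree, sub)
    surf = build_surface([aln], tree, sub)
    return lik, surf.partitions[0]


class TestApproxSurface:
    def test_exact_at_expansion_point(self, surface_case):
        lik, part = surface_case
        assert part.loglik(part.b_hat) == lik.loglik(part.b_hat)

    def test_error_within_half_log_unit_at_5pct(self, surface_case):
        lik, part = surface_case
        rng = np.random.default_rng(8)
        for _ in range(20):
            b = part.b_hat * (1 + 0.05 * (2 * rng.random(
                part.b_hat.size) - 1))
            err = abs(lik.loglik(b) - part.loglik(b))
            assert err <= 0.5

    def test_error_grows_with_perturbation(self, surface_case):
        lik, part = surface_case
        direction = np.where(part.b_hat > 0, 1.0, 0.0)
        errs = []
        for eps in (0.02, 0.04, 0.08, 0.16):
            b = part.b_hat * (1 + eps * direction)
            errs.append(abs(lik.loglik(b) - part.loglik(b)))
        assert errs[-1] >= errs[0]
        assert all(e2 >= e1 * 0.99 for e1, e2 in zip(errs, errs[1:]))

    def test_serialization_round_trip(self, surface_case, tmp_path):
        lik, part = surface_case
        surf = ApproxLikSurface([part])
        p = tmp_path / "surface.tsv"
        surf.save(p)
        back = ApproxLikSurface.load(p)
        b = part.b_hat * 1.03
        assert back.partitions[0].loglik(b) == pytest.approx(
            part.loglik(b), rel=1e-10)
        assert np.array_equal(back.partitions[0].branch_nodes,
                              part.branch_nodes)


class TestCachedLikelihood:
    def test_agrees_with_full_rebuild_after_mixed_moves(self, tree8,
                                                        sub5):
        spec = ClockModelSpec("IR", 0.25, 0.3)
        r = simulate_branch_rates(tree8, spec, seed=60)
        aln = simulate_alignment(tree8, r, sub5, 150, seed=61)
        lik = PhyloLikelihood(aln, tree8, sub5)
        bl = rooted_lengths_from(tree8, r)
        cache = CachedLikelihood(lik, bl)
        rng = np.random.default_rng(9)
        for _ in range(150):
            v = int(rng.integers(tree8.n_nodes))
            if v == tree8.root:
                continue
            b2 = cache.blen.copy()
            b2[v] *= np.exp(0.3 * rng.standard_normal())
            cache.propose(b2, [v])
            (cache.accept if rng.random() < 0.5 else cache.reject)()
        assert cache.loglik == pytest.approx(
            lik.loglik_rooted(cache.blen), abs=1e-8)
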