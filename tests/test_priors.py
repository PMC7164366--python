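"""Birth-death kernel, calibration densities and clock priors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from cetdate.priors import (BdParams, Calibration, CalibrationSet,
                            ClockModelSpec, TimePrior,
                            bd_kernel_cdf, bd_kernel_logdensity,
                            bd_kernel_quantile, branch_rate_logprior,
                            calibration_cdf, calibration_logdensity,
                            calibration_quantile, clock_logprior,
                            joint_time_logprior, rate_hyper_logprior)
from cetdate.synthetic_data import make_calibrations, simulate_timetree


class TestBdKernel:
    def test_equal_rates_closed_form(self, bd):
        # g(t) = (1 + rho*lam*t1) / (t1 (1 + rho*lam*t)^2)
        f = lambda t: math.exp(bd_kernel_logdensity(t, 1.0, bd))
        assert f(1e-12) == pytest.approx(1.1, abs=1e-9)
        assert f(1.0 - 1e-12) == pytest.approx(1.1 / 1.21, abs=1e-9)
        val, err = quad(f, 0, 1)
        assert abs(val - 1.0) < 1e-6

    def test_endpoint_density_ratio_near_uniform(self, bd):
        f = lambda t: math.exp(bd_kernel_logdensity(t, 1.0, bd))
        ratio = f(1e-12) / f(1.0 - 1e-12)
        assert ratio == pytest.approx((1 + 0.1 * 1.0 * 1.0) ** 2,
                                      abs=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_normalization_random_parameters(self, seed):
        rng = np.random.default_rng(seed)
        bdp = BdParams(rng.uniform(0.1, 3), rng.uniform(0.1, 3),
                       rng.uniform(0.05, 1.0))
        t1 = rng.uniform(0.5, 5)
        val, err = quad(
            lambda t: math.exp(bd_kernel_logdensity(t, t1, bdp)), 0, t1,
            limit=200)
        assert abs(val - 1.0) < 1e-6

    def test_high_sampling_concentrates_young(self):
        bdp = BdParams(5.0, 5.0, 1.0)
        ts = np.linspace(0.01, 0.99, 25)
        dens = bd_kernel_logdensity(ts, 1.0, bdp)
        assert np.all(np.diff(dens) < 0)  # monotone decreasing

    def test_quantile_inverts_cdf(self):
        bdp = BdParams(2.0, 0.7, 0.4)
        u = np.linspace(0.01, 0.99, 17)
        q = bd_kernel_quantile(u, 3.0, bdp)
        assert np.allclose(bd_kernel_cdf(q, 3.0, bdp), u, atol=1e-12)

    def test_domain_errors(self, bd):
        with pytest.raises(ValueError):
            bd_kernel_logdensity(1.5, 1.0, bd)
        with pytest.raises(ValueError):
            bd_kernel_logdensity(-0.1, 1.0, bd)


class TestCalibrationDensity:
    def setup_method(self):
        # the root calibration: hard minimum 52.40, soft maximum 164.6
        self.root_cal = Calibration(52.40, 164.6, 0.0, 0.025)

    def test_hard_minimum_excludes(self):
        assert calibration_logdensity(40.0, self.root_cal) == -np.inf

    def test_soft_upper_tail_mass(self):
        val, err = quad(
            lambda t: math.exp(calibration_logdensity(t, self.root_cal)),
            164.6, 5000, limit=300)
        assert val == pytest.approx(0.025, abs=1e-6)

    def test_total_mass_one(self):
        val, _ = quad(
            lambda t: math.exp(calibration_logdensity(t, self.root_cal)),
            0, 6000, limit=400)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_narrow_uniform_density(self):
        c = Calibration(0.999, 1.001, 0.0, 0.0)
        assert calibration_logdensity(1.0, c) == pytest.approx(
            math.log(500.0))
        assert calibration_logdensity(0.9989, c) == -np.inf
        assert calibration_logdensity(1.0011, c) == -np.inf

    def test_soft_lower_tail_mass_and_continuity(self):
        c = Calibration(10.0, 20.0, 0.025, 0.025)
        lower, _ = quad(lambda t: math.exp(calibration_logdensity(t, c)),
                        0, 10.0, limit=200)
        assert lower == pytest.approx(0.025, abs=1e-6)
        h = math.exp(calibration_logdensity(15.0, c))
        just_below = math.exp(calibration_logdensity(10.0 - 1e-9, c))
        assert just_below == pytest.approx(h, rel=1e-6)

    def test_quantile_inverts_cdf(self):
        c = Calibration(10.0, 20.0, 0.025, 0.05)
        q = np.linspace(0.001, 0.999, 31)
        t = calibration_quantile(q, c)
        assert np.allclose(calibration_cdf(t, c), q, atol=1e-10)

    def test_invalid_calibrations(self):
        with pytest.raises(ValueError):
            Calibration(20.0, 10.0)
        with pytest.raises(ValueError):
            Calibration(10.0, 20.0, 0.6, 0.0)
        with pytest.raises(ValueError):
            Calibration(10.0, None)


class TestCalibrationSet:
    def test_tsv_round_trip(self, tmp_path, tree8):
        cals = make_calibrations(tree8, [("root", "root"),
                                         tuple(sorted(
                                             tree8.clade_tips(
                                                 tree8.n_tips))[:2])],
                                 (0.1, 0.2))
        p = tmp_path / "cals.tsv"
        cals.to_tsv(p)
        back = CalibrationSet.from_tsv(p)
        assert len(back) == len(cals)
        for key, c in cals.items():
            b = back.entries[key]
            assert b.t_lower == pytest.approx(c.t_lower, rel=1e-5)
            assert b.t_upper == pytest.approx(c.t_upper, rel=1e-5)

    def test_bundled_fossil_table_loads(self):
        import importlib.resources
        ref = importlib.resources.files("cetdate.data") \
            / "calibrations_cetacea.tsv"
        with importlib.resources.as_file(ref) as p:
            cals = CalibrationSet.from_tsv(p)
        root = cals.entries[("root", "root")]
        assert root.t_lower == 52.40 and root.hard_lower
        assert root.t_upper == 164.6 and root.p_upper == 0.025
        cet = [c for (a, b), c in cals.items()
               if {a, b} == {"Balaenoptera_acutorostrata",
                             "Orcinus_orca"}][0]
        assert (cet.t_lower, cet.t_upper) == (36.40, 52.40)


class TestJointTimePrior:
    def test_ordering_violation_is_minus_inf(self, tree8, bd):
        cals = make_calibrations(tree8, [("root", "root")], (0.1, 0.1))
        tp = TimePrior(tree8, cals, bd)
        ages = tree8.ages.copy()
        assert np.isfinite(tp.logpdf(ages))
        v = tree8.internal_nodes[0]
        bad = ages.copy()
        bad[v] = ages[tree8.parent[v]] + 1.0
        assert tp.logpdf(bad) == -np.inf

    def test_hard_bound_support(self, tree8, bd):
        anchors = [("root", "root")]
        v = [n for n in tree8.internal_nodes if n != tree8.root][0]
        tips = sorted(tree8.clade_tips(v))
        anchors.append((tips[0], tips[-1]))
        cals = make_calibrations(tree8, anchors, (0.05, 0.05),
                                 (0.0, 0.0))
        tp = TimePrior(tree8, cals, bd)
        node_cal = dict(tp.cal_nodes)
        cal = node_cal[v]
        mid = 0.5 * (cal.t_lower + cal.t_upper)
        ages = tree8.ages.copy()
        ages[v] = mid
        assert np.isfinite(tp.logpdf(ages))
        ages[v] = cal.t_lower * 0.99
        assert tp.logpdf(ages) == -np.inf

    def test_root_calibration_required(self, tree8, bd):
        v = [n for n in tree8.internal_nodes if n != tree8.root][0]
        tips = sorted(tree8.clade_tips(v))
        cals = make_calibrations(tree8, [(tips[0], tips[-1])],
                                 (0.1, 0.1))
        with pytest.raises(ValueError):
            TimePrior(tree8, cals, bd)

    def test_uncalibrated_prior_equals_bd_sum(self, tree8, bd):
        cals = make_calibrations(tree8, [("root", "root")], (0.1, 0.1))
        total = joint_time_logprior(tree8, cals, bd)
        free = [v for v in tree8.internal_nodes if v != tree8.root]
        expected = calibration_logdensity(
            tree8.root_age, cals.entries[("root", "root")])
        expected += sum(bd_kernel_logdensity(tree8.ages[v],
                                             tree8.root_age, bd)
                        for v in free)
        assert total == pytest.approx(expected, rel=1e-12)


class TestClockPriors:
    def test_ir_matches_term_by_term_lognormal_sum(self, tree8):
        spec = ClockModelSpec("IR", 0.1, 0.3)
        rng = np.random.default_rng(0)
        rates = np.full(tree8.n_nodes, np.nan)
        nonroot = [v for v in range(tree8.n_nodes) if v != tree8.root]
        rates[nonroot] = rng.lognormal(-2.0, 0.5, len(nonroot))
        got = branch_rate_logprior(rates, spec, tree8, unit=100.0)
        s = math.sqrt(0.3)
        scale = 0.1 * math.exp(-0.3 / 2.0)
        want = sum(stats.lognorm.logpdf(rates[v], s, scale=scale)
                   for v in nonroot)
        assert got == pytest.approx(want, rel=1e-10)

    def test_ar_mode_at_constant_rates(self, tree8):
        spec = ClockModelSpec("AR", 0.1, 0.2)
        nonroot = [v for v in range(tree8.n_nodes) if v != tree8.root]
        at_mu = np.full(tree8.n_nodes, 0.1)
        perturbed = at_mu.copy()
        perturbed[nonroot[0]] = 0.4
        lp_mu = branch_rate_logprior(at_mu, spec, tree8, unit=100.0)
        lp_pert = branch_rate_logprior(perturbed, spec, tree8, unit=100.0)
        assert lp_mu > lp_pert

    def test_gamma_hyperprior_mean(self):
        # Gamma(2, 20) has mean 0.1 per 100-Ma unit
        spec = ClockModelSpec("IR", 0.1, 0.3)
        a, b = spec.mu_prior
        assert a / b == pytest.approx(0.1)
        assert stats.gamma.mean(a, scale=1 / b) == pytest.approx(0.1)

    def test_hyper_prior_single_partition_reduces_to_gamma(self):
        spec = ClockModelSpec("IR", 0.1, 0.3)
        got = rate_hyper_logprior([0.07], [0.5], spec)
        want = (stats.gamma.logpdf(0.07, 2, scale=1 / 20)
                + stats.gamma.logpdf(0.5, 2, scale=1 / 2))
        assert got == pytest.approx(want, rel=1e-12)

    def test_multi_partition_hyper_prior_normalized(self):
        # the gamma-Dirichlet density over two partition means
        # integrates to 1 (coarse 2-D grid; mass lives near mu_bar=0.1)
        spec = ClockModelSpec("IR", 0.1, 0.3)
        dx = 1.2 / 100
        xs = (np.arange(100) + 0.5) * dx  # midpoint rule
        grid = sum(
            math.exp(rate_hyper_logprior([m1, m2], [], spec))
            for m1 in xs for m2 in xs) * dx * dx
        assert grid == pytest.approx(1.0, abs=0.02)

    def test_str_has_no_rate_terms(self, tree8):
        spec = ClockModelSpec("STR", 0.1, 0.0)
        rates = np.full(tree8.n_nodes, 0.1)
        assert clock_logprior(rates, spec, tree8) == pytest.approx(
            stats.gamma.logpdf(0.1, 2, scale=1 / 20))


@settings(max_examples=50, deadline=None)
@given(t=st.floats(0.001, 0.999), lam=st.floats(0.1, 3.0),
       rho=st.floats(0.05, 1.0))
def test_bd_kernel_never_nan_on_support(t, lam, rho):
    bdp = BdParams(lam, lam, rho)
    v = bd_kernel_logdensity(t, 1.0, bdp)
    assert np.isfinite(v)


@settings(max_examples=50, deadline=None)
@given(t=st.floats(0.01, 400.0), pu=st.floats(0.0, 0.49))
def test_calibration_density_never_nan(t, pu):
    c = Calibration(52.40, 164.6, 0.0, pu)
    v = calibration_logdensity(t, c)
    assert not np.isnan(v)
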