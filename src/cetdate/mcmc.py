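"""Metropolis-Hastings sampler for fossil-calibrated divergence dating.

State: internal-node ages (in units of 100 Ma), per-partition mean rates,
diffusion parameters and branch rates (for the IR/AR relaxed clocks),
sampled against the exact pruning likelihood, the quadratic approximate
likelihood, or no likelihood at all (prior-only runs, also used as the
beta=0 stone of power posteriors).

Proposal kernels: bounded sliding windows on node ages, multiplier moves
on the root age, branch rates and hyperparameters, and a whole-tree mixing
move that scales all ages by c and divides all rates by c (likelihood
invariant because every branch length duration*rate is unchanged; the
Jacobian is accounted for).  Step sizes are tuned toward a 20-40%
acceptance window during burn-in only, keeping the post-burn-in chain
Markovian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignments import GeneAlignment
from .likelihood import (ApproxLikSurface, CachedLikelihood, PhyloLikelihood,
                         branch_lengths_from_times)
from .priors import (MA_PER_UNIT, BdParams, Calibration, CalibrationSet,
                     ClockModelSpec, TimePrior, calibration_quantile,
                     rate_hyper_logprior)
from .substitution import SubstitutionParams
from .trees import TimeTree

__all__ = ["McmcSettings", "McmcTrace", "DatingSampler", "run_mcmc",
           "ess", "summarize_posterior"]

LN2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class McmcSettings:
    """Sampler settings.  ``n_iter`` counts elementary parameter updates;
    defaults are desk-scale (the reference protocol this emulates ran
    10^7 iterations sampling every 500, twice)."""

    n_iter: int = 200_000
    sample_every: int = 20
    burnin_fraction: float = 0.5
    n_chains: int = 2
    seed: int = 0
    beta: float = 1.0
    tune: bool = True
    target_accept: tuple[float, float] = (0.2, 0.4)
    step_sizes: dict = field(default_factory=lambda: {
        "age": 0.5, "root": 0.3, "rate": 0.6, "mu": 0.4,
        "sigma2": 0.6, "mix": 0.1})

    def __post_init__(self):
        if self.n_iter < self.sample_every:
            raise ValueError("n_iter must be >= sample_every")
        if not 0 <= self.burnin_fraction < 1:
            raise ValueError("burnin_fraction must be in [0,1)")
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must be in [0,1]")


@dataclass
class McmcTrace:
    """Sampled chain with provenance; ages are reported in Ma."""

    df: pd.DataFrame
    settings: McmcSettings
    node_clades: dict[int, tuple[str, str]]
    seed: int

    def age_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("age_")]

    def post_burnin(self) -> pd.DataFrame:
        cut = int(len(self.df) * self.settings.burnin_fraction)
        return self.df.iloc[cut:]

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "state", np.arange(len(out))
                   * self.settings.sample_every)
        out.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------

def _scale_calibrations(cals: CalibrationSet, factor: float
                        ) -> CalibrationSet:
    entries = {}
    for key, c in cals.items():
        tL = None if c.t_lower is None else c.t_lower / factor
        entries[key] = Calibration(tL, c.t_upper / factor,
                                   c.p_lower, c.p_upper)
    return CalibrationSet(entries)


class _RatePrior:
    """Vectorized branch-rate log prior for one partition."""

    def __init__(self, tree: TimeTree):
        self.tree = tree
        self.nodes = np.array([v for v in range(tree.n_nodes)
                               if v != tree.root], dtype=np.int64)
        par = tree.parent[self.nodes]
        self.par = par
        self.from_root = par == tree.root
        # index into self.nodes of each node's parent branch (or -1)
        pos = {int(v): i for i, v in enumerate(self.nodes)}
        self.parent_branch = np.array(
            [-1 if f else pos[int(p)] for p, f in zip(par, self.from_root)],
            dtype=np.int64)

    def logpdf(self, rates: np.ndarray, mu: float, sigma2: float,
               ages_units: np.ndarray, model: str) -> float:
        return float(self.logpdf_all(rates[None, :], np.array([mu]),
                                     np.array([sigma2]), ages_units,
                                     model)[0])

    def logpdf_all(self, rates: np.ndarray, mus: np.ndarray,
                   sigma2s: np.ndarray, ages_units: np.ndarray,
                   model: str) -> np.ndarray:
        """Log prior per partition for a (P, n_nodes) rate matrix."""
        x = np.log(rates[:, self.nodes])                     # (P, m)
        if model == "IR":
            var = sigma2s[:, None]
            mean = np.log(mus)[:, None] - var / 2.0
            z = x - mean
            return np.sum(-0.5 * z * z / var
                          - 0.5 * (LN2PI + np.log(var)) - x, axis=1)
        # AR: gaps between branch midpoints, per unit
        mid = 0.5 * (ages_units[self.par] + ages_units[self.nodes])
        root_age = ages_units[self.tree.root]
        gap = np.where(self.from_root, root_age - mid,
                       mid[self.parent_branch] - mid)
        if np.any(gap <= 0):
            return np.full(len(mus), -np.inf)
        var = sigma2s[:, None] * gap[None, :]
        parent_log = np.where(self.from_root[None, :],
                              np.log(mus)[:, None],
                              x[:, self.parent_branch])
        mean = parent_log - var / 2.0
        z = x - mean
        return np.sum(-0.5 * z * z / var
                      - 0.5 * (LN2PI + np.log(var)) - x, axis=1)


class DatingSampler:
    """MH sampler over node ages, branch rates and hyperparameters.

    ``data`` may be a list of partition alignments (exact pruning
    likelihood), an :class:`ApproxLikSurface` (quadratic approximation) or
    None (prior-only).  Calibrations are in Ma; a root calibration is
    required.
    """

    def __init__(self, topology: TimeTree, calibrations: CalibrationSet,
                 bd: BdParams = BdParams(),
                 clock: str | ClockModelSpec = "AR",
                 data: Sequence[GeneAlignment] | ApproxLikSurface | None = None,
                 sub: SubstitutionParams | Sequence[SubstitutionParams]
                 = SubstitutionParams(),
                 settings: McmcSettings = McmcSettings()):
        self.topology = topology
        self.spec = (clock if isinstance(clock, ClockModelSpec)
                     else ClockModelSpec(clock, sigma2=0.0 if clock == "STR"
                                         else 0.1))
        self.model = self.spec.model
        self.settings = settings
        self.bd = bd
        self.cals_ma = calibrations
        cals_units = _scale_calibrations(calibrations, MA_PER_UNIT)
        self.time_prior = TimePrior(topology, cals_units, bd,
                                    require_root=True)
        self.mode = "none"
        self.surface: ApproxLikSurface | None = None
        self.alignments: list[GeneAlignment] | None = None
        if isinstance(data, ApproxLikSurface):
            self.mode = "approximate"
            self.surface = data
            self.n_partitions = len(data)
            parts = data.partitions
            nodes0 = parts[0].branch_nodes
            for p in parts[1:]:
                if not np.array_equal(p.branch_nodes, nodes0):
                    raise ValueError("partition surfaces disagree on the "
                                     "branch index map")
            self._ap_nodes = nodes0
            self._ap_par = topology.parent[nodes0]
            self._ap_rep = parts[0].rep_index
            self._ap_other = parts[0].merged_other
            self._ap_other_par = int(topology.parent[self._ap_other])
            self._ap_bhat = np.stack([p.b_hat for p in parts])
            self._ap_g = np.stack([p.gradient for p in parts])
            self._ap_H = np.stack([p.hessian for p in parts])
            self._ap_l0 = np.array([p.logl_hat for p in parts])
        elif data is not None:
            self.mode = "exact"
            self.alignments = list(data)
            self.n_partitions = len(self.alignments)
            if isinstance(sub, SubstitutionParams):
                sub = [sub] * self.n_partitions
            self.subs = list(sub)
            self.liks = [PhyloLikelihood(a, topology, s)
                         for a, s in zip(self.alignments, self.subs)]
        else:
            self.n_partitions = 1
        self.rate_prior = _RatePrior(topology)
        self._nonroot = self.rate_prior.nodes
        self._internal = np.array(
            [v for v in topology.internal_nodes], dtype=np.int64)
        self._free_internal = np.array(
            [v for v in self._internal if v != topology.root],
            dtype=np.int64)

    # ------------------------------------------------------------------
    def _init_state(self, rng: np.random.Generator):
        topo = self.topology
        node_cal = dict(self.time_prior.cal_nodes)
        root_cal = self.time_prior.root_cal
        # per-node age floor: the largest calibration lower bound in the
        # node's subtree (itself included) -- every valid state has the
        # node at least this old, so drawing above it keeps descendants
        # feasible in the top-down pass
        floor = np.zeros(topo.n_nodes)
        child_floor = np.zeros(topo.n_nodes)
        for v in topo.postorder:
            f = max((floor[c] for c in topo.children[v]), default=0.0)
            child_floor[v] = f
            own = node_cal.get(v)
            if own is not None and own.t_lower:
                f = max(f, own.t_lower)
            floor[v] = f
        for _ in range(500):
            ages = np.zeros(topo.n_nodes)
            root_lo = max(child_floor[topo.root],
                          root_cal.t_lower or 0.0)
            a = calibration_quantile(rng.uniform(0.2, 0.8), root_cal)
            ages[topo.root] = max(a, root_lo * 1.001)
            ok = True
            for v in topo.postorder[::-1]:
                if v < topo.n_tips or v == topo.root:
                    continue
                hi = ages[topo.parent[v]]
                lo = child_floor[v]
                cal = node_cal.get(v)
                if cal is not None:
                    lo = max(lo, cal.t_lower or 0.0)
                if hi <= lo:
                    ok = False
                    break
                if cal is not None:
                    a = calibration_quantile(rng.uniform(0.2, 0.8), cal)
                else:
                    a = lo + (hi - lo) * rng.uniform(0.2, 0.9)
                pad = 0.01 * (hi - lo)
                ages[v] = float(np.clip(a, lo + pad, hi - pad))
            if ok and np.isfinite(self.time_prior.logpdf(ages)):
                break
        else:
            raise RuntimeError("could not initialize ages from the prior")
        a_mu, b_mu = self.spec.mu_prior
        mus = np.full(self.n_partitions, a_mu / b_mu)
        a_s, b_s = self.spec.sigma2_prior
        sigma2s = np.full(self.n_partitions,
                          0.0 if self.model == "STR" else a_s / b_s / 2.0)
        rates = np.tile(mus[:, None], (1, topo.n_nodes))
        rates[:, topo.root] = 0.0
        return ages, mus, sigma2s, rates

    # -- likelihood plumbing -------------------------------------------
    def _rate_matrix(self, mus, rates) -> np.ndarray:
        if self.model != "STR":
            return rates
        r = np.tile(mus[:, None], (1, self.topology.n_nodes))
        r[:, self.topology.root] = 0.0
        return r

    def _approx_ll_all(self, ages, mus, rates) -> np.ndarray:
        """Quadratic log likelihood per partition, batched."""
        rmat = self._rate_matrix(mus, rates)
        dur = ages[self._ap_par] - ages[self._ap_nodes]
        b = dur[None, :] * rmat[:, self._ap_nodes]
        b[:, self._ap_rep] += ((ages[self._ap_other_par]
                                - ages[self._ap_other])
                               * rmat[:, self._ap_other])
        d = b - self._ap_bhat
        quad = np.einsum("pm,pmn,pn->p", d, self._ap_H, d)
        return self._ap_l0 + np.einsum("pm,pm->p", self._ap_g, d) \
            + 0.5 * quad

    def _rooted_blens(self, ages, mus, rates) -> list[np.ndarray]:
        topo = self.topology
        dur = np.zeros(topo.n_nodes)
        nr = self._nonroot
        dur[nr] = ages[topo.parent[nr]] - ages[nr]
        rmat = self._rate_matrix(mus, rates)
        return [dur * rmat[p] for p in range(self.n_partitions)]

    def _full_ll(self, ages, mus, rates) -> float:
        """Likelihood from scratch (used for prior-only recording)."""
        if self.mode == "none":
            return 0.0
        if self.mode == "approximate":
            return float(self._approx_ll_all(ages, mus, rates).sum())
        blens = self._rooted_blens(ages, mus, rates)
        return float(sum(lik.loglik_rooted(b)
                         for lik, b in zip(self.liks, blens)))

    def _rate_lp_all(self, ages, mus, sigma2s, rates) -> np.ndarray:
        if self.model == "STR":
            return np.zeros(self.n_partitions)
        return self.rate_prior.logpdf_all(rates, mus, sigma2s, ages,
                                          self.model)

    # ------------------------------------------------------------------
    def run(self, seed: int | None = None, record_loglik: bool = True
            ) -> McmcTrace:
        st = self.settings
        rng = np.random.default_rng(
            np.random.SeedSequence([st.seed if seed is None else seed, 77]))
        topo = self.topology
        beta = st.beta
        model = self.model
        ages, mus, sigma2s, rates = self._init_state(rng)

        lp_time = self.time_prior.logpdf(ages)
        lp_rates = self._rate_lp_all(ages, mus, sigma2s, rates)
        lp_hyper = rate_hyper_logprior(
            mus, sigma2s if model != "STR" else [], self.spec)

        use_lik = self.mode != "none" and (beta > 0 or record_loglik)
        live_lik = self.mode != "none" and beta > 0
        caches: list[CachedLikelihood] | None = None
        ll_parts = np.zeros(self.n_partitions)
        if live_lik and self.mode == "exact":
            blens = self._rooted_blens(ages, mus, rates)
            caches = [CachedLikelihood(lik, b)
                      for lik, b in zip(self.liks, blens)]
            ll_parts = np.array([c.loglik for c in caches])
        elif live_lik and self.mode == "approximate":
            ll_parts = self._approx_ll_all(ages, mus, rates)
        ll = float(ll_parts.sum())

        steps = dict(st.step_sizes)
        steps.setdefault("age_joint", 0.5)
        n_rate_params = (len(self._nonroot) * self.n_partitions
                         if model != "STR" else 0)
        weights = {
            "age": max(len(self._free_internal), 1),
            "age_joint": (3 * len(self._free_internal)
                          if (model != "STR" and live_lik) else 0),
            "root": 2,
            "rate": n_rate_params,
            "mu": self.n_partitions * 2,
            "sigma2": self.n_partitions * 2 if model != "STR" else 0,
            "mix": 2,
        }
        kinds = [k for k, w in weights.items() if w > 0]
        wvec = np.array([weights[k] for k in kinds], float)
        cum = np.cumsum(wvec / wvec.sum())
        attempts = {k: 0 for k in kinds}
        accepts = {k: 0 for k in kinds}
        burn_iters = int(st.n_iter * st.burnin_fraction)
        lo_acc, hi_acc = st.target_accept

        n_samples = st.n_iter // st.sample_every
        age_cols = [f"age_{v}" for v in self._internal]
        cols = (age_cols + [f"mu_{p+1}" for p in range(self.n_partitions)]
                + [f"sigma2_{p+1}" for p in range(self.n_partitions)]
                + ["lnL", "lnPrior", "lnPost"])
        out = np.empty((n_samples, len(cols)))
        row = 0

        n_scaled_rates = (self.n_partitions * (len(self._nonroot) + 1)
                          if model != "STR" else self.n_partitions)
        n_scaled_ages = len(self._internal)
        exact = self.mode == "exact"

        def propose_ll_ages(new_ages, new_rates, changed):
            """Likelihood after an age (and optional rate) change."""
            if not live_lik:
                return ll, ll_parts
            if self.mode == "approximate":
                parts = self._approx_ll_all(new_ages, mus,
                                            new_rates)
                return float(parts.sum()), parts
            parts = ll_parts.copy()
            rmat = self._rate_matrix(mus, new_rates)
            for p, cache in enumerate(caches):
                blen = cache.blen.copy()
                for c in changed:
                    blen[c] = (new_ages[topo.parent[c]]
                               - new_ages[c]) * rmat[p, c]
                parts[p] = cache.propose(blen, changed)
            return float(parts.sum()), parts

        def commit(accepted):
            if caches is None:
                return
            for c in caches:
                if c._pending is not None:
                    (c.accept if accepted else c.reject)()

        for it in range(st.n_iter):
            kind = kinds[int(np.searchsorted(cum, rng.random()))]
            attempts[kind] += 1
            accepted = False

            if kind in ("age", "age_joint"):
                v = int(self._free_internal[
                    rng.integers(len(self._free_internal))])
                lo = max(ages[c] for c in topo.children[v])
                hi = ages[topo.parent[v]]
                span = hi - lo
                if span <= 0:
                    continue
                w = steps[kind] * span
                xp = ages[v] + w * (rng.random() - 0.5)
                y = (xp - lo) % (2 * span)
                xp = lo + (y if y <= span else 2 * span - y)
                new_ages = ages.copy()
                new_ages[v] = xp
                log_hastings = 0.0
                changed = [c for c in [v] + list(topo.children[v])
                           if c != topo.root]
                if kind == "age_joint":
                    # rescale the three adjacent branch rates so branch
                    # lengths stay fixed: a likelihood-invariant move
                    new_rates = rates.copy()
                    for c in changed:
                        dur_old = ages[topo.parent[c]] - ages[c]
                        dur_new = new_ages[topo.parent[c]] - new_ages[c]
                        if dur_new <= 0 or dur_old <= 0:
                            dur_new = -1
                            break
                        f = dur_old / dur_new
                        new_rates[:, c] *= f
                        log_hastings += self.n_partitions * math.log(f)
                    if dur_new <= 0:
                        continue
                else:
                    new_rates = rates
                lp_time_n = self.time_prior.logpdf(new_ages)
                if np.isfinite(lp_time_n):
                    if model != "STR":
                        lp_rates_n = self._rate_lp_all(
                            new_ages, mus, sigma2s, new_rates)
                    else:
                        lp_rates_n = lp_rates
                    if kind == "age_joint":
                        ll_n, ll_parts_n = ll, ll_parts
                    else:
                        ll_n, ll_parts_n = propose_ll_ages(
                            new_ages, new_rates, changed)
                    dlp = ((lp_time_n - lp_time)
                           + (lp_rates_n.sum() - lp_rates.sum())
                           + beta * (ll_n - ll) + log_hastings)
                    if math.log(rng.random()) < dlp:
                        ages = new_ages
                        rates = new_rates
                        lp_time = lp_time_n
                        lp_rates = lp_rates_n
                        ll, ll_parts = ll_n, ll_parts_n
                        commit(True)
                        accepted = True
                    else:
                        commit(False)

            elif kind == "root":
                r0 = topo.root
                c = math.exp(steps["root"] * (rng.random() - 0.5))
                xp = ages[r0] * c
                if xp > max(ages[ch] for ch in topo.children[r0]):
                    new_ages = ages.copy()
                    new_ages[r0] = xp
                    lp_time_n = self.time_prior.logpdf(new_ages)
                    if np.isfinite(lp_time_n):
                        if model != "STR":
                            lp_rates_n = self._rate_lp_all(
                                new_ages, mus, sigma2s, rates)
                        else:
                            lp_rates_n = lp_rates
                        changed = list(topo.children[r0])
                        ll_n, ll_parts_n = propose_ll_ages(
                            new_ages, rates, changed)
                        dlp = ((lp_time_n - lp_time)
                               + (lp_rates_n.sum() - lp_rates.sum())
                               + beta * (ll_n - ll) + math.log(c))
                        if math.log(rng.random()) < dlp:
                            ages = new_ages
                            lp_time = lp_time_n
                            lp_rates = lp_rates_n
                            ll, ll_parts = ll_n, ll_parts_n
                            commit(True)
                            accepted = True
                        else:
                            commit(False)

            elif kind == "rate":
                p = int(rng.integers(self.n_partitions))
                v = int(self._nonroot[rng.integers(len(self._nonroot))])
                c = math.exp(steps["rate"] * (rng.random() - 0.5))
                new_rates = rates.copy()
                new_rates[p, v] *= c
                lp_rates_n = self._rate_lp_all(ages, mus, sigma2s,
                                               new_rates)
                if np.isfinite(lp_rates_n[p]):
                    if live_lik:
                        if self.mode == "approximate":
                            ll_parts_n = self._approx_ll_all(
                                ages, mus, new_rates)
                            ll_n = float(ll_parts_n.sum())
                        else:
                            blen = caches[p].blen.copy()
                            blen[v] = ((ages[topo.parent[v]] - ages[v])
                                       * new_rates[p, v])
                            ll_parts_n = ll_parts.copy()
                            ll_parts_n[p] = caches[p].propose(blen, [v])
                            ll_n = float(ll_parts_n.sum())
                    else:
                        ll_n, ll_parts_n = ll, ll_parts
                    dlp = ((lp_rates_n.sum() - lp_rates.sum())
                           + beta * (ll_n - ll) + math.log(c))
                    if math.log(rng.random()) < dlp:
                        rates = new_rates
                        lp_rates = lp_rates_n
                        ll, ll_parts = ll_n, ll_parts_n
                        if exact and caches is not None:
                            caches[p].accept()
                        accepted = True
                    elif exact and caches is not None \
                            and caches[p]._pending is not None:
                        caches[p].reject()

            elif kind == "mu":
                p = int(rng.integers(self.n_partitions))
                c = math.exp(steps["mu"] * (rng.random() - 0.5))
                new_mus = mus.copy()
                new_mus[p] *= c
                lp_hyper_n = rate_hyper_logprior(
                    new_mus, sigma2s if model != "STR" else [], self.spec)
                lp_rates_n = self._rate_lp_all(ages, new_mus, sigma2s,
                                               rates)
                ok = np.isfinite(lp_hyper_n) and np.isfinite(
                    lp_rates_n.sum())
                ll_n, ll_parts_n = ll, ll_parts
                if ok and model == "STR" and live_lik:
                    if self.mode == "approximate":
                        ll_parts_n = self._approx_ll_all(ages, new_mus,
                                                         rates)
                        ll_n = float(ll_parts_n.sum())
                    else:
                        blen = ((ages[topo.parent[self._nonroot]]
                                 - ages[self._nonroot]) * new_mus[p])
                        full = caches[p].blen.copy()
                        full[self._nonroot] = blen
                        ll_parts_n = ll_parts.copy()
                        ll_parts_n[p] = caches[p].propose(
                            full, list(self._nonroot))
                        ll_n = float(ll_parts_n.sum())
                if ok:
                    dlp = ((lp_hyper_n - lp_hyper)
                           + (lp_rates_n.sum() - lp_rates.sum())
                           + beta * (ll_n - ll) + math.log(c))
                    if math.log(rng.random()) < dlp:
                        mus = new_mus
                        lp_hyper = lp_hyper_n
                        lp_rates = lp_rates_n
                        ll, ll_parts = ll_n, ll_parts_n
                        if exact and caches is not None \
                                and caches[p]._pending is not None:
                            caches[p].accept()
                        accepted = True
                    elif exact and caches is not None \
                            and caches[p]._pending is not None:
                        caches[p].reject()

            elif kind == "sigma2":
                p = int(rng.integers(self.n_partitions))
                c = math.exp(steps["sigma2"] * (rng.random() - 0.5))
                new_s2 = sigma2s.copy()
                new_s2[p] *= c
                lp_hyper_n = rate_hyper_logprior(mus, new_s2, self.spec)
                lp_rates_n = self._rate_lp_all(ages, mus, new_s2, rates)
                if np.isfinite(lp_hyper_n) and np.isfinite(
                        lp_rates_n.sum()):
                    dlp = ((lp_hyper_n - lp_hyper)
                           + (lp_rates_n.sum() - lp_rates.sum())
                           + math.log(c))
                    if math.log(rng.random()) < dlp:
                        sigma2s = new_s2
                        lp_hyper = lp_hyper_n
                        lp_rates = lp_rates_n
                        accepted = True

            else:  # mix: scale ages by c, divide rates by c
                c = math.exp(steps["mix"] * (rng.random() - 0.5))
                new_ages = ages.copy()
                new_ages[self._internal] *= c
                new_mus = mus / c
                new_rates = rates / c if model != "STR" else rates
                lp_time_n = self.time_prior.logpdf(new_ages)
                lp_hyper_n = rate_hyper_logprior(
                    new_mus, sigma2s if model != "STR" else [], self.spec)
                if np.isfinite(lp_time_n) and np.isfinite(lp_hyper_n):
                    lp_rates_n = self._rate_lp_all(new_ages, new_mus,
                                                   sigma2s, new_rates)
                    logj = (n_scaled_ages - n_scaled_rates) * math.log(c)
                    dlp = ((lp_time_n - lp_time)
                           + (lp_rates_n.sum() - lp_rates.sum())
                           + (lp_hyper_n - lp_hyper) + logj)
                    if math.log(rng.random()) < dlp:
                        ages = new_ages
                        mus = new_mus
                        rates = new_rates
                        lp_time = lp_time_n
                        lp_hyper = lp_hyper_n
                        lp_rates = lp_rates_n
                        accepted = True
                        # branch lengths are unchanged: caches stay valid

            if accepted:
                accepts[kind] += 1
            if st.tune and it < burn_iters and attempts[kind] >= 50:
                acc = accepts[kind] / attempts[kind]
                if acc > hi_acc:
                    steps[kind] = min(steps[kind] * 1.4, 10.0)
                elif acc < lo_acc:
                    steps[kind] = max(steps[kind] / 1.4, 1e-3)
                attempts[kind] = accepts[kind] = 0

            if (it + 1) % st.sample_every == 0 and row < n_samples:
                if use_lik and not live_lik:
                    ll_rec = self._full_ll(ages, mus, rates)
                else:
                    ll_rec = ll
                lp = lp_time + lp_rates.sum() + lp_hyper
                out[row] = np.concatenate([
                    ages[self._internal] * MA_PER_UNIT, mus, sigma2s,
                    [ll_rec, lp, lp + beta * ll_rec]])
                row += 1

        df = pd.DataFrame(out[:row], columns=cols)
        node_clades = {int(v): tuple(sorted(topo.clade_tips(v))[:2])
                       for v in self._internal}
        return McmcTrace(df, st, node_clades, st.seed if seed is None
                         else seed)

    # ------------------------------------------------------------------
    def run_chains(self, n_chains: int | None = None) -> list[McmcTrace]:
        n = n_chains or self.settings.n_chains
        return [self.run(seed=self.settings.seed + 1000 * k)
                for k in range(n)]


def run_mcmc(topology: TimeTree, calibrations: CalibrationSet,
             data=None, clock="AR", bd: BdParams = BdParams(),
             sub: SubstitutionParams = SubstitutionParams(),
             settings: McmcSettings = McmcSettings()) -> McmcTrace:
    """One-call sampler: build a :class:`DatingSampler` and run one chain."""
    return DatingSampler(topology, calibrations, bd=bd, clock=clock,
                         data=data, sub=sub, settings=settings).run()


# ----------------------------------------------------------------------
# Trace diagnostics
# ----------------------------------------------------------------------

def ess(series) -> float:
    """Effective sample size: n / (1 + 2 sum of autocorrelations), the sum
    truncated by the initial-positive-sequence rule.  A constant series
    is degenerate and reports 0."""
    x = np.asarray(series, float)
    n = x.size
    if n < 10:
        raise ValueError("series too short for an ESS estimate")
    v = x.var()
    if v == 0 or not np.isfinite(v):
        return 0.0
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x - x.mean(), nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # Geyer initial positive sequence on paired sums
    s = 0.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        s += pair
        k += 2
    return float(n / (1.0 + 2.0 * s))


def summarize_posterior(trace: McmcTrace | pd.DataFrame,
                        burnin_fraction: float | None = None,
                        params: Sequence[str] | None = None,
                        ess_threshold: float = 100.0) -> pd.DataFrame:
    """Posterior table: mean, equal-tail 95% CI, CI width and ESS per
    parameter, with a flag for parameters below the ESS threshold."""
    if isinstance(trace, McmcTrace):
        bf = (trace.settings.burnin_fraction if burnin_fraction is None
              else burnin_fraction)
        df = trace.df
    else:
        bf = burnin_fraction or 0.0
        df = trace
    post = df.iloc[int(len(df) * bf):]
    if len(post) < 100:
        raise ValueError("fewer than 100 post-burn-in samples")
    if params is None:
        params = [c for c in post.columns
                  if c not in ("state", "lnL", "lnPrior", "lnPost")]
    rows = []
    for c in params:
        x = post[c].to_numpy()
        q025, q975 = np.quantile(x, [0.025, 0.975])
        e = ess(x)
        rows.append({"parameter": c, "mean": x.mean(), "q2.5": q025,
                     "q97.5": q975, "ci_width": q975 - q025, "ess": e,
                     "low_ess": bool(e < ess_threshold)})
    return pd.DataFrame(rows).set_index("parameter")
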