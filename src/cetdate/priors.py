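"""Joint prior for divergence dating.

Three ingredients:

* a birth-death kernel on non-root interior node ages, conditional on the
  root age (with sampling fraction ``rho``) -- for equal birth and death
  rates it reduces to the closed form
  ``g(t) = (1 + rho*lam*t1) / (t1 * (1 + rho*lam*t)**2)``;
* hard/soft fossil-calibration densities: a uniform core on ``[tL, tU]``
  carrying mass ``1 - pL - pU``, an exponential upper tail and a power-law
  lower tail, both matched continuously to the core height (hard bounds are
  true zero density outside);
* relaxed-clock priors on branch rates (strict, independent lognormal, or
  autocorrelated geometric Brownian motion) with gamma hyperpriors on the
  mean rate and the diffusion parameter, and a gamma-Dirichlet prior across
  partition mean rates.

Ages here are in the caller's time unit; the MCMC engine works in units of
100 Ma and converts at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


from .trees import TimeTree

__all__ = [
    "BdParams", "ClockModelSpec", "Calibration", "CalibrationSet",
    "bd_kernel_logdensity", "bd_kernel_cdf", "bd_kernel_quantile",
    "calibration_logdensity", "calibration_cdf", "calibration_quantile",
    "joint_time_logprior", "clock_logprior", "branch_rate_logprior",
    "rate_hyper_logprior", "TimePrior",
]

#: internal time unit used by the samplers (1 unit = 100 Ma)
MA_PER_UNIT = 100.0


@dataclass(frozen=True)
class BdParams:
    """Birth-death node-age prior parameters (birth, death, sampling)."""

    lam: float = 1.0
    mu_death: float = 1.0
    rho: float = 0.1

    def __post_init__(self):
        if self.lam < 0 or self.mu_death < 0:
            raise ValueError("rates must be nonnegative")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")


@dataclass(frozen=True)
class ClockModelSpec:
    """Relaxed-clock model: STR (strict), IR (independent lognormal) or AR
    (autocorrelated geometric Brownian motion on branch rates).

    ``mu`` is the mean rate in substitutions/site per time unit; ``sigma2``
    is the log-rate variance (IR) or diffusion rate per time unit (AR).
    ``mu_prior`` and ``sigma2_prior`` are (shape, rate) gamma hyperpriors.
    """

    model: str = "AR"
    mu: float = 0.1
    sigma2: float = 0.1
    mu_prior: tuple[float, float] = (2.0, 20.0)
    sigma2_prior: tuple[float, float] = (2.0, 2.0)

    def __post_init__(self):
        if self.model not in ("STR", "IR", "AR"):
            raise ValueError("model must be STR, IR or AR")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.model == "STR" and self.sigma2 != 0:
            raise ValueError("STR implies sigma2 = 0")


# ----------------------------------------------------------------------
# Birth-death node-age kernel, conditional on the root age
# ----------------------------------------------------------------------

def _bd_parts(t, bd: BdParams):
    lam, mu, rho = bd.lam, bd.mu_death, bd.rho
    t = np.asarray(t, float)
    if abs(lam - mu) < 1e-12:
        P = rho / (1.0 + rho * lam * t)
        E = np.ones_like(t)
    else:
        r = lam - mu
        a = lam * (1 - rho) - mu
        E = np.exp(-r * t)
        P = rho * r / (rho * lam + a * E)
    return P, E


def _bd_vt(t, bd: BdParams):
    lam, mu, rho = bd.lam, bd.mu_death, bd.rho
    P, E = _bd_parts(t, bd)
    return 1.0 - P * E / rho


def bd_kernel_logdensity(t, root_age: float, bd: BdParams):
    """Log density of a non-root interior node age given the root age."""
    t_arr = np.asarray(t, float)
    if root_age <= 0:
        raise ValueError("root_age must be > 0")
    out = np.full(t_arr.shape, -np.inf)
    ok = (t_arr > 0) & (t_arr < root_age)
    if np.isscalar(t) and not ok:
        raise ValueError("t must lie in (0, root_age)")
    P, E = _bd_parts(t_arr[ok], bd)
    p1 = P * P * E / bd.rho
    v1 = _bd_vt(np.array(root_age), bd)
    out[ok] = np.log(bd.lam * p1 / v1)
    return float(out) if np.isscalar(t) else out


def bd_kernel_cdf(t, root_age: float, bd: BdParams):
    t = np.clip(np.asarray(t, float), 0.0, root_age)
    return _bd_vt(t, bd) / _bd_vt(np.array(root_age), bd)


def bd_kernel_quantile(u, root_age: float, bd: BdParams):
    """Inverse CDF of the node-age kernel (closed form)."""
    u = np.asarray(u, float)
    lam, mu, rho = bd.lam, bd.mu_death, bd.rho
    v = u * _bd_vt(np.array(root_age), bd)
    if abs(lam - mu) < 1e-12:
        # v = rho*lam*t / (1 + rho*lam*t)
        return v / (rho * lam * (1.0 - v))
    r = lam - mu
    a = lam * (1 - rho) - mu
    # v_t = 1 - r E / (rho lam + a E)  =>  E = rho lam (1-v) / (a(v-1) + r)
    E = rho * lam * (1.0 - v) / (a * (v - 1.0) + r)
    return -np.log(E) / r


# ----------------------------------------------------------------------
# Fossil calibrations
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Calibration:
    """Age calibration for one node: bounds in Ma with tail probabilities.

    ``p_lower``/``p_upper`` are the prior probabilities of violating the
    minimum/maximum; 0 makes the bound hard (zero density beyond it).
    """

    t_lower: float | None
    t_upper: float | None
    p_lower: float = 0.0
    p_upper: float = 0.025

    def __post_init__(self):
        if self.t_upper is None:
            raise ValueError("a maximum bound is required "
                             "(minimum-only calibrations unsupported)")
        tL = 0.0 if self.t_lower is None else self.t_lower
        if not tL < self.t_upper:
            raise ValueError("t_lower must be < t_upper")
        for p in (self.p_lower, self.p_upper):
            if not 0 <= p < 0.5:
                raise ValueError("tail probabilities must be in [0, 0.5)")
        if self.t_lower is None and self.p_lower > 0:
            raise ValueError("soft lower tail needs a finite t_lower")

    @property
    def hard_lower(self) -> bool:
        return self.p_lower == 0.0

    @property
    def hard_upper(self) -> bool:
        return self.p_upper == 0.0

    def _core_height(self) -> float:
        tL = 0.0 if self.t_lower is None else self.t_lower
        return (1.0 - self.p_lower - self.p_upper) / (self.t_upper - tL)


def calibration_logdensity(t, cal: Calibration):
    """Log prior density of a calibrated node age (vectorized)."""
    t = np.asarray(t, float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    tL = 0.0 if cal.t_lower is None else cal.t_lower
    tU = cal.t_upper
    h = cal._core_height()
    out = np.full(t.shape, -np.inf)
    core = (t >= tL) & (t <= tU)
    out[core] = math.log(h)
    above = t > tU
    if cal.p_upper > 0:
        # exponential tail: h * exp(-(h/pU) (t - tU)) integrates to pU
        rate = h / cal.p_upper
        out[above] = math.log(h) - rate * (t[above] - tU)
    below = (t < tL) & (t > 0)
    if cal.p_lower > 0:
        # power tail: h * (t/tL)^theta with integral pL over (0, tL)
        theta = h * tL / cal.p_lower - 1.0
        out[below] = math.log(h) + theta * (np.log(t[below]) - math.log(tL))
    return float(out[0]) if scalar else out


def calibration_cdf(t, cal: Calibration):
    t = np.atleast_1d(np.asarray(t, float))
    tL = 0.0 if cal.t_lower is None else cal.t_lower
    tU = cal.t_upper
    h = cal._core_height()
    out = np.zeros(t.shape)
    below = (t < tL) & (t > 0)
    if cal.p_lower > 0:
        theta = h * tL / cal.p_lower - 1.0
        out[below] = cal.p_lower * (t[below] / tL) ** (theta + 1.0)
    core = (t >= tL) & (t <= tU)
    out[core] = cal.p_lower + h * (t[core] - tL)
    above = t > tU
    if cal.p_upper > 0:
        rate = h / cal.p_upper
        out[above] = 1.0 - cal.p_upper * np.exp(-rate * (t[above] - tU))
    else:
        out[above] = 1.0
    return out if out.size > 1 else float(out[0])


def calibration_quantile(q, cal: Calibration):
    """Inverse CDF of the calibration density (piecewise closed form)."""
    q = np.atleast_1d(np.asarray(q, float))
    tL = 0.0 if cal.t_lower is None else cal.t_lower
    tU = cal.t_upper
    h = cal._core_height()
    out = np.empty(q.shape)
    lo = q < cal.p_lower
    if cal.p_lower > 0:
        theta = h * tL / cal.p_lower - 1.0
        out[lo] = tL * (q[lo] / cal.p_lower) ** (1.0 / (theta + 1.0))
    core = (q >= cal.p_lower) & (q <= 1.0 - cal.p_upper)
    out[core] = tL + (q[core] - cal.p_lower) / h
    hi = q > 1.0 - cal.p_upper
    if cal.p_upper > 0:
        rate = h / cal.p_upper
        out[hi] = tU - np.log((1.0 - q[hi]) / cal.p_upper) / rate
    else:
        out[hi] = tU
    return out if out.size > 1 else float(out[0])


class CalibrationSet:
    """Mapping from node anchors (tip pairs) to calibrations.

    The anchor ``(tip_a, tip_b)`` designates the MRCA of the two tips in
    whatever tree the set is resolved against; ``("root", "root")`` or a
    pair spanning the root both designate the root.
    """

    def __init__(self, entries: Mapping[tuple[str, str], Calibration]):
        self.entries = dict(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def items(self):
        return self.entries.items()

    def resolve(self, tree: TimeTree) -> dict[int, Calibration]:
        """Node-index -> calibration for a concrete tree."""
        out: dict[int, Calibration] = {}
        for (a, b), cal in self.entries.items():
            if a == "root" and b == "root":
                node = tree.root
            else:
                node = tree.mrca(a, b)
            if node in out:
                raise ValueError(f"node {node} calibrated twice")
            out[node] = cal
        return out

    # ------------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path) -> "CalibrationSet":
        """Read the calibration table (tip_a, tip_b, t_min_Ma, min_type,
        t_max_Ma, max_type, pL, pU); 'NA' marks an absent minimum."""
        import pandas as pd
        df = pd.read_csv(path, sep="\t", comment="#")
        entries = {}
        for _, r in df.iterrows():
            tmin = None if str(r["t_min_Ma"]) in ("NA", "nan") \
                else float(r["t_min_Ma"])
            pL = float(r["pL"]) if str(r["min_type"]).lower() == "soft" else 0.0
            pU = float(r["pU"]) if str(r["max_type"]).lower() == "soft" else 0.0
            entries[(str(r["tip_a"]), str(r["tip_b"]))] = Calibration(
                tmin, float(r["t_max_Ma"]), pL, pU)
        return cls(entries)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("tip_a\ttip_b\tt_min_Ma\tmin_type\tt_max_Ma\t"
                     "max_type\tpL\tpU\n")
            for (a, b), c in self.entries.items():
                tmin = "NA" if c.t_lower is None else f"{c.t_lower:g}"
                mint = "hard" if c.hard_lower else "soft"
                maxt = "hard" if c.hard_upper else "soft"
                fh.write(f"{a}\t{b}\t{tmin}\t{mint}\t{c.t_upper:g}\t{maxt}\t"
                         f"{c.p_lower:g}\t{c.p_upper:g}\n")


# ----------------------------------------------------------------------
# Joint prior over node ages
# ----------------------------------------------------------------------

class TimePrior:
    """Precompiled joint log prior over internal node ages of a fixed tree.

    Calibrated nodes replace (not multiply) the birth-death kernel term;
    everything is conditioned on the root age, whose own density comes from
    its calibration.  Truncation by the parent>child ordering is implicit:
    states violating it get probability zero.
    """

    def __init__(self, tree: TimeTree, cals: CalibrationSet, bd: BdParams,
                 require_root: bool = True):
        self.tree = tree
        self.bd = bd
        node_cal = cals.resolve(tree)
        if require_root and tree.root not in node_cal:
            raise ValueError("a root calibration is required")
        self.root_cal = node_cal.get(tree.root)
        self.cal_nodes = [(n, c) for n, c in node_cal.items()
                          if n != tree.root]
        ncal = {n for n, _ in self.cal_nodes}
        self.free_nodes = np.array(
            [n for n in tree.internal_nodes
             if n != tree.root and n not in ncal], dtype=np.int64)
        self._par = tree.parent
        self._internal = tree.internal_nodes
        self._nonroot = np.array([v for v in range(tree.n_nodes)
                                  if v != tree.root], dtype=np.int64)
        self._nonroot_par = tree.parent[self._nonroot]

    def logpdf(self, ages: np.ndarray) -> float:
        """Log prior of a full node-age vector (tips must be 0)."""
        t_root = ages[self.tree.root]
        if t_root <= 0:
            return -np.inf
        if np.any(ages[self._nonroot] >= ages[self._nonroot_par]):
            return -np.inf
        total = 0.0
        if self.root_cal is not None:
            total += calibration_logdensity(t_root, self.root_cal)
        if not np.isfinite(total):
            return -np.inf
        for n, c in self.cal_nodes:
            total += calibration_logdensity(ages[n], c)
            if not np.isfinite(total):
                return -np.inf
        if self.free_nodes.size:
            t = ages[self.free_nodes]
            if np.any(t <= 0):
                return -np.inf
            total += float(np.sum(
                bd_kernel_logdensity(t, t_root, self.bd)))
        return total


def joint_time_logprior(tree: TimeTree, cals: CalibrationSet,
                        bd: BdParams) -> float:
    """Log prior of the tree's current node ages (convenience wrapper)."""
    return TimePrior(tree, cals, bd).logpdf(tree.ages)


# ----------------------------------------------------------------------
# Clock-model priors on branch rates and hyperparameters
# ----------------------------------------------------------------------

def _branch_midpoint_gaps(tree: TimeTree, unit: float = 1.0):
    """(child branch, parent branch or -1, midpoint gap) per non-root node.

    The gap is the time between branch midpoints (root children use the
    distance from the root), in the same unit as the tree's ages divided
    by ``unit``.
    """
    out = []
    mid = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p != -1:
            mid[v] = 0.5 * (tree.ages[p] + tree.ages[v])
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p == -1:
            continue
        if p == tree.root:
            gap = tree.root_age - mid[v]
            out.append((v, -1, gap / unit))
        else:
            out.append((v, p, (mid[p] - mid[v]) / unit))
    return out


def branch_rate_logprior(rates: Mapping[int, float] | np.ndarray,
                         spec: ClockModelSpec, tree: TimeTree,
                         unit: float = 1.0) -> float:
    """Log density of branch rates given (mu, sigma2) under the clock model.

    ``rates`` is indexed by child node (the branch above it); the root has
    no branch.  Tree ages may be in Ma with ``unit=100`` to express the
    diffusion per 100-Ma unit, or already in units with ``unit=1``.
    """
    r = np.asarray(rates, float) if not isinstance(rates, Mapping) else None
    get = (lambda v: rates[v]) if isinstance(rates, Mapping) else \
        (lambda v: r[v])
    nonroot = [v for v in range(tree.n_nodes) if tree.parent[v] != -1]
    vals = np.array([get(v) for v in nonroot])
    if np.any(vals <= 0):
        return -np.inf
    mu, s2 = spec.mu, spec.sigma2
    if spec.model == "STR":
        return 0.0  # rates are deterministic at mu; no free parameters
    if spec.model == "IR":
        s = math.sqrt(s2)
        return float(np.sum(stats.norm.logpdf(
            np.log(vals), math.log(mu) - s2 / 2.0, s) - np.log(vals)))
    total = 0.0
    for v, pb, gap in _branch_midpoint_gaps(tree, unit=unit):
        x = math.log(get(v))
        if pb == -1:
            var = s2 * gap
            mean = math.log(mu) - var / 2.0
        else:
            var = s2 * gap
            mean = math.log(get(pb)) - var / 2.0
        if var <= 0:
            return -np.inf if abs(x - mean) > 1e-12 else 0.0
        total += stats.norm.logpdf(x, mean, math.sqrt(var)) - x
    return float(total)


def rate_hyper_logprior(mus: Sequence[float], sigma2s: Sequence[float],
                        spec: ClockModelSpec,
                        dirichlet_conc: float = 1.0) -> float:
    """Gamma hyperpriors with a gamma-Dirichlet spread across partitions.

    The average of the per-partition mean rates gets the gamma prior
    (default Gamma(2, 20), mean 0.1/unit); their proportions get a
    symmetric Dirichlet.  sigma2 values are i.i.d. gamma (default
    Gamma(2, 2)) -- omitted entirely for the strict clock.
    """
    mus = np.asarray(mus, float)
    if np.any(mus <= 0):
        return -np.inf
    g = len(mus)
    a_mu, b_mu = spec.mu_prior
    s = mus.sum()
    total = stats.gamma.logpdf(s / g, a_mu, scale=1.0 / b_mu)
    if g > 1:
        z = mus / s
        alpha = np.full(g, dirichlet_conc)
        total += stats.dirichlet.logpdf(np.clip(z, 1e-300, 1.0) /
                                        z.sum(), alpha)
        total += -math.log(g) - (g - 1) * math.log(s)
    if spec.model != "STR":
        s2 = np.asarray(sigma2s, float)
        if np.any(s2 <= 0):
            return -np.inf
        a_s, b_s = spec.sigma2_prior
        total += float(np.sum(stats.gamma.logpdf(s2, a_s, scale=1.0 / b_s)))
    return float(total)


def clock_logprior(rates, spec: ClockModelSpec, tree: TimeTree,
                   unit: float = 1.0) -> float:
    """Branch-rate prior plus hyperpriors for a single partition."""
    total = rate_hyper_logprior([spec.mu],
                                [spec.sigma2] if spec.model != "STR" else [],
                                spec)
    if spec.model != "STR":
        total += branch_rate_logprior(rates, spec, tree, unit=unit)
    return total
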