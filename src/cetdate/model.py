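"""Model / Results interface for fossil-calibrated divergence dating.

:class:`DivergenceTimeModel` bundles a fixed rooted topology, partitioned
alignments (or a prebuilt approximate-likelihood surface), fossil
calibrations and a relaxed-clock choice; ``fit()`` runs the MCMC and
returns a :class:`DivergenceTimeResults` carrying traces, posterior node
ages with credibility intervals, convergence diagnostics and the
infinite-sites regression.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .alignments import GeneAlignment
from .diagnostics import InfiniteSitesFit, infinite_sites_fit
from .likelihood import ApproxLikSurface, build_surface
from .mcmc import (DatingSampler, McmcSettings, McmcTrace, ess,
                   summarize_posterior)
from .priors import BdParams, CalibrationSet, ClockModelSpec
from .substitution import SubstitutionParams
from .trees import TimeTree

__all__ = ["DivergenceTimeModel", "DivergenceTimeResults"]


class DivergenceTimeModel:
    """Bayesian divergence-time model on a fixed topology.

    Parameters
    ----------
    topology : fixed rooted binary species tree (ages ignored).
    calibrations : fossil calibrations in Ma; a root calibration is
        required.
    data : list of partition alignments, an ApproxLikSurface, or None
        (prior-only model).
    clock : "STR" | "IR" | "AR" or a full ClockModelSpec.
    bd : birth-death node-age prior parameters.
    sub : substitution model (shared or per partition).
    """

    def __init__(self, topology: TimeTree, calibrations: CalibrationSet,
                 data=None, clock="AR", bd: BdParams = BdParams(),
                 sub: SubstitutionParams = SubstitutionParams()):
        self.topology = topology
        self.calibrations = calibrations
        self.data = data
        self.clock = clock
        self.bd = bd
        self.sub = sub

    @classmethod
    def from_alignments(cls, alignments: Sequence[GeneAlignment],
                        topology: TimeTree,
                        calibrations: CalibrationSet,
                        clock="AR", bd: BdParams = BdParams(),
                        sub: SubstitutionParams = SubstitutionParams(),
                        approximate: bool = True) -> "DivergenceTimeModel":
        """Build the model from partition alignments; with
        ``approximate=True`` the branch-length MLE/Hessian surface is
        computed here so that fit() runs the fast quadratic likelihood."""
        data = (build_surface(list(alignments), topology, sub)
                if approximate else list(alignments))
        return cls(topology, calibrations, data=data, clock=clock, bd=bd,
                   sub=sub)

    def fit(self, settings: McmcSettings = McmcSettings(),
            seed: int | None = None,
            n_chains: int | None = None) -> "DivergenceTimeResults":
        """Run the dating MCMC (one or more chains)."""
        if seed is not None:
            settings = replace(settings, seed=seed)
        sampler = DatingSampler(self.topology, self.calibrations,
                                bd=self.bd, clock=self.clock,
                                data=self.data, sub=self.sub,
                                settings=settings)
        traces = sampler.run_chains(n_chains)
        return DivergenceTimeResults(self, traces)

    def fit_prior(self, settings: McmcSettings = McmcSettings(),
                  seed: int | None = None) -> "DivergenceTimeResults":
        """Prior-only run (likelihood off): shows the effective joint
        prior on node ages, which interaction of calibrations, the
        birth-death kernel and the ordering constraint can shift away
        from the specified marginals.  Recommended before every dating
        run."""
        if seed is not None:
            settings = replace(settings, seed=seed)
        sampler = DatingSampler(self.topology, self.calibrations,
                                bd=self.bd, clock=self.clock, data=None,
                                settings=settings)
        traces = sampler.run_chains(1)
        return DivergenceTimeResults(self, traces, prior_only=True)


class DivergenceTimeResults:
    """Posterior dating results: traces, node-age table, diagnostics."""

    def __init__(self, model: DivergenceTimeModel,
                 traces: list[McmcTrace], prior_only: bool = False):
        self.model = model
        self.traces = traces
        self.prior_only = prior_only
        self._combined = pd.concat(
            [t.post_burnin() for t in traces], ignore_index=True)

    @property
    def trace(self) -> McmcTrace:
        return self.traces[0]

    def summary(self, ess_threshold: float = 100.0) -> pd.DataFrame:
        """Posterior table (mean, 95% CI, CI width, ESS) over node ages
        and rate hyperparameters, pooled across chains after burn-in."""
        return summarize_posterior(self._combined, burnin_fraction=0.0,
                                   ess_threshold=ess_threshold)

    def node_ages(self) -> pd.DataFrame:
        """Summary restricted to node ages (Ma), annotated with the two
        alphabetically first tips of each clade."""
        s = self.summary()
        s = s[s.index.str.startswith("age_")].copy()
        clades = self.traces[0].node_clades
        anchors = []
        for name in s.index:
            v = int(name.split("_")[1])
            anchors.append("|".join(clades.get(v, ("?",))))
        s["clade"] = anchors
        return s

    def convergence(self) -> pd.DataFrame:
        """Between-chain agreement: per-parameter posterior means of each
        chain and their maximum spread relative to the root age."""
        means = pd.DataFrame({
            f"chain{i+1}": t.post_burnin().mean()
            for i, t in enumerate(self.traces)})
        age_rows = means.index.str.startswith("age_")
        root_age = float(means[age_rows].max().max())
        spread = means.max(axis=1) - means.min(axis=1)
        out = means.copy()
        out["spread"] = spread
        out["spread_rel_root"] = spread / root_age if root_age else np.nan
        return out

    def dated_tree(self) -> TimeTree:
        """Topology with node ages set to posterior means."""
        tree = self.model.topology.copy()
        s = self.summary()
        for name, row in s.iterrows():
            if str(name).startswith("age_"):
                tree.ages[int(str(name).split("_")[1])] = row["mean"]
        tree.validate()
        return tree

    def annotated_newick(self) -> str:
        """Newick with posterior mean ages; 95% CIs in comment blocks."""
        tree = self.dated_tree()
        s = self.summary()

        def rec(v):
            if v < tree.n_tips:
                lab = tree.labels[v]
            else:
                lab = "(" + ",".join(rec(c) for c in tree.children[v]) + ")"
                key = f"age_{v}"
                if key in s.index:
                    r = s.loc[key]
                    lab += (f"[&age={r['mean']:.2f},95%CI="
                            f"{{{r['q2.5']:.2f},{r['q97.5']:.2f}}}]")
            p = tree.parent[v]
            if p != -1:
                lab += f":{tree.ages[p] - tree.ages[v]:.4f}"
            return lab

        return rec(tree.root) + ";"

    def infinite_sites(self, include_root: bool = True
                       ) -> InfiniteSitesFit:
        """Infinite-sites regression (CI width on mean age) for this run."""
        return infinite_sites_fit(self.summary(), include_root=include_root)

    def __repr__(self):  # pragma: no cover
        kind = "prior-only" if self.prior_only else "posterior"
        na = self.node_ages()
        root = na["mean"].max()
        return (f"<DivergenceTimeResults {kind}: {len(self.traces)} "
                f"chain(s), {len(na)} dated nodes, root "
                f"{root:.2f} Ma>")
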