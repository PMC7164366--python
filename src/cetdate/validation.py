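"""Synthetic validation experiments for the dating workflow.

Each function runs one self-contained study at desk scale -- small trees,
short alignments and short chains chosen so the whole battery completes
on one CPU in minutes -- and returns plain numbers.  They back both the
acceptance-style tests and the reproduction script, so the figures those
two report always come from the same code paths.
"""

from __future__ import annotations

import math


import numpy as np
from scipy import stats
from scipy.integrate import quad

from .diagnostics import compare_datasets, infinite_sites_fit
from .gene_qc import filter_genes, screen_premature_stops
from .likelihood import PhyloLikelihood, build_surface
from .mcmc import DatingSampler, McmcSettings
from .model import DivergenceTimeModel
from .model_select import (StoneSettings, beta_schedule,
                           load_reference_logml, model_posterior_probs,
                           select_clock_model, stepping_stone_logml)
from .priors import (BdParams, Calibration, CalibrationSet, ClockModelSpec,
                     bd_kernel_logdensity, calibration_quantile)
from .rate_partition import (GeneRateTable, bin_genes, gene_rate_table,
                             partition_alignments, rank_clocklike,
                             split_codon_positions)
from .substitution import SubstitutionParams
from .synthetic_data import (CorruptionRules, corrupt_fixture,
                             gene_tree_newick, make_calibrations,
                             random_coding_alignment, simulate_alignment,
                             simulate_branch_rates, simulate_gene_set,
                             simulate_timetree)

__all__ = [
    "reference_model_probabilities", "bd_prior_check",
    "stepping_stone_validation", "clock_model_recovery",
    "approx_likelihood_fidelity", "coverage_experiment",
    "prior_quantile_check", "reduced_dataset_experiment", "qc_exactness",
]

_SUB = SubstitutionParams(kappa=4.0, base_freqs=(0.3, 0.2, 0.2, 0.3),
                          gamma_shape=0.8, n_categories=5)


def reference_model_probabilities() -> dict[str, dict[str, float]]:
    """Posterior clock-model probabilities recomputed from the published
    log marginal likelihoods (equal model priors), per data subset."""
    from .model_select import MarginalLikelihoodEstimate
    ref = load_reference_logml()
    sched = tuple(beta_schedule(4, 0.5))
    out: dict[str, dict[str, float]] = {}
    for label, grp in ref.groupby("data", sort=False):
        ests = [MarginalLikelihoodEstimate(m, v, s, 4, 100, sched)
                for m, v, s in zip(grp["model"], grp["log_ml"],
                                   grp["se"])]
        out[label] = model_posterior_probs(ests)
    return out


def bd_prior_check() -> dict[str, float]:
    """Normalization and near-uniformity of the birth-death node-age
    kernel at the study parameters (lam = mu = 1, rho = 0.1, root 1)."""
    bd = BdParams(1.0, 1.0, 0.1)
    integral, _ = quad(
        lambda t: math.exp(bd_kernel_logdensity(t, 1.0, bd)), 0.0, 1.0)
    ratio = math.exp(bd_kernel_logdensity(1e-12, 1.0, bd)
                     - bd_kernel_logdensity(1.0 - 1e-12, 1.0, bd))
    return {"integral": float(integral), "endpoint_ratio": float(ratio)}


def stepping_stone_validation(seed: int = 0,
                              n_per_stone: int = 2000
                              ) -> dict[str, float]:
    """Stepping-stone estimator vs the analytic normal-normal evidence.

    Data y_i ~ N(theta, 1) with theta ~ N(0, 1) admit exact power
    posteriors (conjugate) and a closed-form marginal likelihood; the
    estimator should land within a few standard errors.  Also checks the
    constant-likelihood identity, which holds exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
    y = rng.standard_normal(20) + 0.4
    n = len(y)
    sched = beta_schedule(8, 0.3)
    stones = []
    for b in sched[:-1]:
        prec = 1.0 + b * n
        theta = (b * y.sum() / prec
                 + rng.standard_normal(n_per_stone) / math.sqrt(prec))
        ll = -0.5 * ((y[None, :] - theta[:, None]) ** 2).sum(axis=1) \
            - 0.5 * n * math.log(2 * math.pi)
        stones.append(ll)
    est = stepping_stone_logml(stones, sched)
    cov = np.eye(n) + np.ones((n, n))
    truth = float(stats.multivariate_normal.logpdf(y, np.zeros(n), cov))
    const = stepping_stone_logml(
        [np.full(100, -55.5)] * 4, beta_schedule(4, 0.5))
    return {
        "log_ml": est.log_ml, "analytic": truth, "se": est.se,
        "error_in_se_units": abs(est.log_ml - truth) / max(est.se, 1e-9),
        "constant_identity_error": abs(const.log_ml + 55.5),
    }


def clock_model_recovery(generating: str, n_replicates: int = 10,
                         seed: int = 0) -> dict[str, object]:
    """Generating-model recovery on 20-taxon, 1-gene, 1-kb data.

    Data are simulated under ``generating`` (STR or IR with sigma2=0.5)
    and the three clock models compared by exact-likelihood stepping
    stones.  Success means STR wins on STR data; on IR data, success
    means a relaxed clock (IR or AR) beats STR.
    """
    wins = 0
    best = []
    for rep in range(n_replicates):
        s = seed + 1000 * rep
        tree = simulate_timetree(20, 100.0, BdParams(), seed=s + 1)
        spec = ClockModelSpec(generating, 0.25,
                              0.0 if generating == "STR" else 0.5)
        r = simulate_branch_rates(tree, spec, seed=s + 2)
        aln = simulate_alignment(tree, r, _SUB, 333, seed=s + 3,
                                 cp_multipliers=(1, 1, 1))
        sel = select_clock_model(
            [aln], tree, sub=_SUB,
            stones=StoneSettings(n_stones=5, a=0.3, n_iter=3200,
                                 sample_every=10, seed=s + 4),
            data_label=f"{generating}-rep{rep}")
        best.append(sel.best_model)
        if generating == "STR":
            wins += sel.best_model == "STR"
        else:
            wins += sel.best_model in ("IR", "AR")
    return {"wins": wins, "n": n_replicates, "best_models": best}


def approx_likelihood_fidelity(seed: int = 0) -> dict[str, float]:
    """Quadratic-surface error on a 16-taxon, 2-kb simulated gene under
    +-5% branch-length perturbation, plus expansion-point exactness."""
    tree = simulate_timetree(16, 100.0, BdParams(), seed=seed + 50)
    spec = ClockModelSpec("AR", 0.2, 0.2)
    r = simulate_branch_rates(tree, spec, seed=seed + 51)
    aln = simulate_alignment(tree, r, _SUB, 667, seed=seed + 52,
                             cp_multipliers=(1, 1, 1))
    lik = PhyloLikelihood(aln, tree, _SUB)
    part = build_surface([aln], tree, _SUB).partitions[0]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    errs = []
    for _ in range(20):
        b = part.b_hat * (1 + 0.05 * (2 * rng.random(part.b_hat.size)
                                      - 1))
        errs.append(abs(lik.loglik(b) - part.loglik(b)))
    return {
        "max_abs_error": float(max(errs)),
        "expansion_point_error": abs(lik.loglik(part.b_hat)
                                     - part.loglik(part.b_hat)),
    }


def coverage_experiment(n_datasets: int = 20, seed: int = 0
                        ) -> dict[str, float]:
    """95% CI coverage of true node ages over synthetic AR datasets
    (16 taxa, 3 partitions, fossil-style calibrations bracketing the
    truth)."""
    bd = BdParams()
    covered = total = 0
    for i in range(n_datasets):
        s = seed + 300 * i
        tree = simulate_timetree(16, 100.0, bd, seed=s + 1)
        parts = []
        # each partition gets its own branch-rate realization, matching
        # the fitted model's independent per-partition rate processes
        for j, m in enumerate((0.6, 1.0, 1.6)):
            spec = ClockModelSpec("AR", 0.2 * m, 0.2)
            r = simulate_branch_rates(tree, spec, seed=s + 20 + j)
            parts.append(simulate_alignment(tree, r, _SUB, 200,
                                            seed=s + 3 + j,
                                            cp_multipliers=(1, 1, 1),
                                            gene_id=f"p{j}"))
        surf = build_surface(parts, tree, _SUB)
        anchors = [("root", "root")]
        inner = [v for v in tree.internal_nodes if v != tree.root]
        for v in inner[:3]:
            tips = sorted(tree.clade_tips(v))
            anchors.append((tips[0], tips[-1]))
        cals = make_calibrations(tree, anchors, (0.08, 0.08))
        model = DivergenceTimeModel(tree, cals, data=surf, clock="AR",
                                    bd=bd, sub=_SUB)
        res = model.fit(McmcSettings(n_iter=100_000, sample_every=25,
                                     n_chains=1, seed=s + 9))
        na = res.summary()
        for name, row in na.iterrows():
            if not str(name).startswith("age_"):
                continue
            v = int(str(name).split("_")[1])
            total += 1
            covered += row["q2.5"] <= tree.ages[v] <= row["q97.5"]
    return {"coverage": covered / total, "covered": covered,
            "n_nodes": total}


def prior_quantile_check(seed: int = 0) -> dict[str, float]:
    """Prior-only MCMC reproduces the root-calibration quantiles (hard
    minimum 52.40 Ma, soft maximum 164.6 Ma with 2.5% tail)."""
    bd = BdParams()
    tree = simulate_timetree(8, 100.0, bd, seed=seed + 60)
    cal = Calibration(52.40, 164.6, 0.0, 0.025)
    cals = CalibrationSet({("root", "root"): cal})
    st = McmcSettings(n_iter=200_000, sample_every=10,
                      burnin_fraction=0.25, seed=seed + 61)
    trace = DatingSampler(tree, cals, bd=bd, clock="STR", data=None,
                          settings=st).run()
    root = trace.post_burnin()[f"age_{tree.root}"].to_numpy()
    out = {}
    worst = 0.0
    for q in (0.025, 0.5, 0.975):
        want = calibration_quantile(q, cal)
        got = float(np.quantile(root, q))
        rel = abs(got - want) / want
        out[f"q{q}"] = got
        out[f"q{q}_expected"] = float(want)
        worst = max(worst, rel)
    out["worst_relative_error"] = worst
    return out


def reduced_dataset_experiment(n_replicates: int = 10, seed: int = 0
                               ) -> dict[str, object]:
    """Complete vs clocklike-reduced dating, and the partition trend.

    Per replicate: 60 genes on an 8-taxon tree (AR clock, gene-rate
    spread, codon-position rate structure); the full set is dated at 3,
    6 and 10 partitions and the 10 most clocklike genes at 3 partitions.
    Reports, per replicate, the mean CI-width ratio (reduced/full, 3
    partitions) and whether the infinite-sites slope is non-increasing
    across 3 -> 6 -> 10 partitions.
    """
    bd = BdParams()
    ratios = []
    monotone = []
    slopes_all = []
    for rep in range(n_replicates):
        s = seed + 500 * rep
        tree = simulate_timetree(8, 100.0, bd, seed=s + 1)
        spec = ClockModelSpec("AR", 0.2, 0.3)
        genes, mults, rates = simulate_gene_set(
            tree, spec, _SUB, 60, 60, gene_rate_log_sd=0.6, seed=s + 2)
        table = gene_rate_table(list(genes.values()),
                                (tree.labels[0], tree.labels[-1]),
                                tree.labels[1:-1])
        schemes = {"3p": bin_genes(table, 3),
                   "6p": split_codon_positions(bin_genes(table, 3)),
                   "10p": bin_genes(table, 10)}
        gtrees = {g: gene_tree_newick(tree, rates, mults[g])
                  for g in genes}
        ranked, _ = rank_clocklike(gtrees, tree, 10)
        red = GeneRateTable({g: table.rates[g]
                             for g in (x.gene_id for x in ranked)
                             if g in table.rates})
        schemes["red"] = bin_genes(red, min(3, len(red.rates)))
        cals = make_calibrations(tree, [("root", "root")], (0.08, 0.08))
        summaries = {}
        for name, sch in schemes.items():
            parts = partition_alignments(genes, sch,
                                         taxa=list(tree.labels))
            surf = build_surface(parts, tree, _SUB)
            model = DivergenceTimeModel(tree, cals, data=surf,
                                        clock="AR", bd=bd, sub=_SUB)
            summaries[name] = model.fit(
                McmcSettings(n_iter=50_000, sample_every=20,
                             n_chains=1, seed=s + 9)).summary()
        cmp = compare_datasets(summaries["3p"], summaries["red"])
        ratios.append(cmp.mean_width_ratio)
        sl = [infinite_sites_fit(summaries[n]).slope
              for n in ("3p", "6p", "10p")]
        slopes_all.append(sl)
        monotone.append(sl[0] >= sl[1] >= sl[2])
    return {
        "width_ratios": ratios,
        "ratio_wins": int(sum(r > 1.0 for r in ratios)),
        "slopes": slopes_all,
        "monotone_wins": int(sum(monotone)),
        "n": n_replicates,
    }


def qc_exactness(seed: int = 0) -> dict[str, object]:
    """Pseudogene screening against the corruption ground truth at the
    full study scale: 3191 genes, 95 corrupted, 3096 retained."""
    taxa = [f"t{i}" for i in range(6)]
    genes = [random_coding_alignment(f"g{i:04d}", taxa, 30,
                                     seed=seed + i)
             for i in range(3191)]
    rules = CorruptionRules(n_stop_genes=60, n_frameshift_genes=35)
    out, log = corrupt_fixture(genes, rules, seed=seed + 17)
    kept, reports = filter_genes(out)
    want_stops = {(e["gene"], e["taxon"], e["codon"])
                  for e in log if e["kind"] == "stop"}
    got_stops = set()
    for aln in out:
        for f in screen_premature_stops(aln):
            got_stops.add((aln.gene_id, f.taxon, f.position))
    return {
        "n_input": len(genes),
        "n_corrupted": len({e["gene"] for e in log}),
        "n_retained": len(kept),
        "stop_flags_match_log": got_stops == want_stops,
    }
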