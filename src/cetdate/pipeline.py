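"""End-to-end orchestration: simulate -> QC -> rate binning -> surface ->
dating -> diagnostics, with hash-stamped, resumable artifacts.

The pipeline is driven by a flat key=value config (see DEFAULT_CONFIG for
the documented keys) and writes TSV/Newick/FASTA artifacts into an output
directory.  Completed stages are skipped on re-invocation when their
stamp matches the config hash, so reruns are cheap and byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping


import pandas as pd

from .alignments import GeneAlignment, write_fasta_alignment
from .diagnostics import compare_datasets, infinite_sites_fit
from .gene_qc import filter_genes, reports_to_tsv
from .likelihood import ApproxLikSurface, build_surface
from .mcmc import McmcSettings
from .model import DivergenceTimeModel
from .model_select import StoneSettings, select_clock_model
from .priors import BdParams, ClockModelSpec
from .rate_partition import (GeneRateTable, bin_genes, gene_rate_table,
                             partition_alignments, rank_clocklike,
                             split_codon_positions)
from .substitution import SubstitutionParams
from .synthetic_data import (CorruptionRules, corrupt_fixture,
                             gene_tree_newick, make_calibrations,
                             simulate_gene_set, simulate_timetree)
from .trees import TimeTree

__all__ = ["DEFAULT_CONFIG", "read_config", "run_pipeline", "tiny_config"]

DEFAULT_CONFIG: dict[str, str] = {
    # randomness and bookkeeping
    "seed": "1",
    # synthetic data
    "n_taxa": "8",
    "n_genes": "12",
    "n_codons": "300",
    "root_age_ma": "100",
    "clock_sim": "AR",            # generating clock model
    "mu": "0.15",                 # subs/site per 100 Ma
    "sigma2": "0.2",
    "gene_rate_log_sd": "0.7",
    "kappa": "4.0",
    "gamma_shape": "0.8",
    "corrupt_stop_genes": "1",
    "corrupt_frameshift_genes": "1",
    # partitioning
    "scheme": "3p",               # 3p | 6p | 10p | <k>p
    # dating
    "clock_fit": "AR",
    "n_iter": "40000",
    "sample_every": "20",
    "n_chains": "2",
    "cal_offsets": "0.08,0.08",
    "cal_anchors": "2",           # internal calibrations beyond the root
    # optional stages
    "select_model": "0",
    "n_clocklike": "0",           # >0: reduced-dataset comparison
}


def read_config(path) -> dict[str, str]:
    cfg = dict(DEFAULT_CONFIG)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in DEFAULT_CONFIG:
                raise KeyError(f"unknown config key {key!r}")
            cfg[key] = val.strip()
    return cfg


def tiny_config() -> dict[str, str]:
    """Bundled desk-scale configuration (8 taxa, 12 genes, 300 codons)."""
    return dict(DEFAULT_CONFIG)


def _config_hash(cfg: Mapping[str, str]) -> str:
    blob = json.dumps(dict(sorted(cfg.items()))).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class _Stages:
    def __init__(self, outdir: Path, cfg_hash: str, log_path: Path):
        self.outdir = outdir
        self.hash = cfg_hash
        self.log_path = log_path

    def done(self, stage: str) -> bool:
        stamp = self.outdir / f".{stage}.done"
        return stamp.exists() and stamp.read_text().strip() == self.hash

    def mark(self, stage: str) -> None:
        (self.outdir / f".{stage}.done").write_text(self.hash + "\n")

    def fail(self, stage: str, err: Exception):
        self.log_path.write_text(json.dumps(
            {"stage": stage, "error": str(err),
             "type": type(err).__name__}) + "\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") \
            from err


def run_pipeline(config: Mapping[str, str] | str | Path,
                 outdir: str | Path) -> dict[str, Path]:
    """Run the synthetic end-to-end study; returns artifact paths."""
    cfg = read_config(config) if isinstance(config, (str, Path)) \
        else {**DEFAULT_CONFIG, **dict(config)}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = _config_hash(cfg)
    stages = _Stages(outdir, h, outdir / "error.json")
    seed = int(cfg["seed"])
    artifacts: dict[str, Path] = {}
    (outdir / "config_used.txt").write_text(
        "\n".join(f"{k}={v}" for k, v in sorted(cfg.items()))
        + f"\n# config_hash={h}\n")

    sub = SubstitutionParams(float(cfg["kappa"]),
                             (0.3, 0.2, 0.2, 0.3),
                             float(cfg["gamma_shape"]), 5)
    spec = ClockModelSpec(cfg["clock_sim"], float(cfg["mu"]),
                          0.0 if cfg["clock_sim"] == "STR"
                          else float(cfg["sigma2"]))
    bd = BdParams()

    # ---------------- simulate ----------------
    tree = simulate_timetree(int(cfg["n_taxa"]), float(cfg["root_age_ma"]),
                             bd, seed=seed)
    try:
        genes, mults, rates = simulate_gene_set(
            tree, spec, sub, int(cfg["n_genes"]), int(cfg["n_codons"]),
            gene_rate_log_sd=float(cfg["gene_rate_log_sd"]), seed=seed)
        corrupted, log = corrupt_fixture(
            list(genes.values()),
            CorruptionRules(
                n_stop_genes=int(cfg["corrupt_stop_genes"]),
                n_frameshift_genes=int(cfg["corrupt_frameshift_genes"])),
            seed=seed)
        if not stages.done("simulate"):
            simdir = outdir / "simulated"
            simdir.mkdir(exist_ok=True)
            (simdir / "true_tree.nwk").write_text(tree.to_newick() + "\n")
            pd.DataFrame(log).to_csv(simdir / "corruption_log.tsv",
                                     sep="\t", index=False)
            for aln in corrupted:
                write_fasta_alignment(aln, simdir / f"{aln.gene_id}.fasta",
                                      header=f"seed={seed} hash={h}")
            stages.mark("simulate")
        artifacts["simulated"] = outdir / "simulated"
    except Exception as e:          # pragma: no cover
        stages.fail("simulate", e)

    # ---------------- qc ----------------
    try:
        kept, reports = filter_genes(corrupted)
        if not stages.done("qc"):
            reports_to_tsv(reports, outdir / "qc_report.tsv")
            stages.mark("qc")
        artifacts["qc_report"] = outdir / "qc_report.tsv"
    except Exception as e:          # pragma: no cover
        stages.fail("qc", e)

    # ---------------- partition ----------------
    try:
        pair = (tree.labels[0], tree.labels[-1])
        fallbacks = tree.labels[1:-1]
        table = gene_rate_table(kept, pair, fallbacks)
        k = int(cfg["scheme"].rstrip("p"))
        if cfg["scheme"] == "6p":
            scheme = split_codon_positions(bin_genes(table, 3))
        else:
            scheme = bin_genes(table, k)
        gene_map = {a.gene_id: a for a in kept}
        parts = partition_alignments(gene_map, scheme,
                                     taxa=list(tree.labels))
        if not stages.done("partition"):
            table.to_tsv(outdir / "gene_rates.tsv")
            scheme.to_tsv(outdir / "partitions.tsv")
            stages.mark("partition")
        artifacts["partitions"] = outdir / "partitions.tsv"
    except Exception as e:          # pragma: no cover
        stages.fail("partition", e)

    # ---------------- surface ----------------
    try:
        surf_path = outdir / "surface.tsv"
        if stages.done("surface") and surf_path.exists():
            surface = ApproxLikSurface.load(surf_path)
        else:
            surface = build_surface(parts, tree, sub)
            surface.save(surf_path)
            stages.mark("surface")
        artifacts["surface"] = surf_path
    except Exception as e:          # pragma: no cover
        stages.fail("surface", e)

    # ---------------- date ----------------
    try:
        below, above = (float(x) for x in cfg["cal_offsets"].split(","))
        anchors = [("root", "root")]
        inner = [v for v in tree.internal_nodes if v != tree.root]
        for v in inner[:int(cfg["cal_anchors"])]:
            tips = sorted(tree.clade_tips(v))
            anchors.append((tips[0], tips[-1]))
        cals = make_calibrations(tree, anchors, (below, above))
        settings = McmcSettings(n_iter=int(cfg["n_iter"]),
                                sample_every=int(cfg["sample_every"]),
                                n_chains=int(cfg["n_chains"]), seed=seed)
        model = DivergenceTimeModel(tree, cals, data=surface,
                                    clock=cfg["clock_fit"], bd=bd, sub=sub)
        res = model.fit(settings=settings)
        if not stages.done("date"):
            res.summary().to_csv(outdir / "posterior_summary.tsv",
                                 sep="\t")
            res.node_ages().to_csv(outdir / "node_ages.tsv", sep="\t")
            for i, tr in enumerate(res.traces):
                tr.to_tsv(outdir / f"trace_chain{i+1}.tsv")
            (outdir / "dated_tree.nwk").write_text(
                res.annotated_newick() + "\n")
            stages.mark("date")
        artifacts["node_ages"] = outdir / "node_ages.tsv"
        artifacts["dated_tree"] = outdir / "dated_tree.nwk"
    except Exception as e:          # pragma: no cover
        stages.fail("date", e)

    # ---------------- diagnostics ----------------
    try:
        fits = [res.infinite_sites(True), res.infinite_sites(False)]
        if not stages.done("diagnose"):
            with open(outdir / "infinite_sites.tsv", "w") as fh:
                fh.write("variant\tslope\tintercept\tr2\tn_nodes\n")
                for f in fits:
                    fh.write(f"{f.variant}\t{f.slope:.3f}\t"
                             f"{f.intercept:.3f}\t{f.r2:.3f}\t"
                             f"{len(f.points)}\n")
            stages.mark("diagnose")
        artifacts["infinite_sites"] = outdir / "infinite_sites.tsv"
    except Exception as e:          # pragma: no cover
        stages.fail("diagnose", e)

    # ---------------- optional: reduced comparison ----------------
    n_red = int(cfg["n_clocklike"])
    if n_red > 0:
        try:
            gtrees = {g: gene_tree_newick(tree, rates, mults[g])
                      for g in gene_map}
            ranked, _ = rank_clocklike(gtrees, tree, n_red)
            red_ids = [s.gene_id for s in ranked]
            red_table = {g: table.rates[g] for g in red_ids
                         if g in table.rates}
            red_scheme = bin_genes(GeneRateTable(red_table),
                                   min(3, len(red_table)))
            red_parts = partition_alignments(gene_map, red_scheme,
                                             taxa=list(tree.labels))
            red_surface = build_surface(red_parts, tree, sub)
            red_model = DivergenceTimeModel(tree, cals, data=red_surface,
                                            clock=cfg["clock_fit"],
                                            bd=bd, sub=sub)
            red_res = red_model.fit(settings=settings)
            cmp = compare_datasets(res.summary(), red_res.summary())
            if not stages.done("compare"):
                cmp.pairs.to_csv(outdir / "full_vs_reduced.tsv", sep="\t")
                with open(outdir / "comparison_stats.tsv", "w") as fh:
                    fh.write("mean_width_ratio\tslope_full\t"
                             "slope_reduced\n")
                    fh.write(f"{cmp.mean_width_ratio:.4f}\t"
                             f"{cmp.slope_full:.3f}\t"
                             f"{cmp.slope_reduced:.3f}\n")
                stages.mark("compare")
            artifacts["comparison"] = outdir / "comparison_stats.tsv"
        except Exception as e:      # pragma: no cover
            stages.fail("compare", e)

    # ---------------- optional: model selection ----------------
    if cfg["select_model"] == "1":
        try:
            one_gene = [kept[0]]
            sel = select_clock_model(
                one_gene, tree, sub=sub,
                stones=StoneSettings(n_stones=4, n_iter=3000,
                                     seed=seed),
                data_label="1g")
            if not stages.done("select"):
                sel.to_tsv(outdir / "model_selection.tsv")
                stages.mark("select")
            artifacts["model_selection"] = outdir / "model_selection.tsv"
        except Exception as e:      # pragma: no cover
            stages.fail("select", e)

    return artifacts
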