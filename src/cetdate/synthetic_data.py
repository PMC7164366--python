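"""Synthetic timetrees, branch rates, alignments and corrupted fixtures.

The generator emulates the statistical structure the dating analysis
assumes: node ages drawn from the birth-death kernel conditional on a fixed
root age (attached to a ranked random topology), branch rates under strict,
independent-lognormal or autocorrelated geometric-Brownian clocks, HKY85+G
sequence evolution with codon-position rate multipliers, and data artifacts
(internal stop codons, frameshift gaps, missing taxa) with a ground-truth
injection log.

Defaults follow the study conditions the package targets: birth-death
lam = mu_death = 1, rho = 0.1; rate hyperpriors Gamma(2, 20) per 100-Ma
unit; HKY85 with five gamma categories.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alignments import GeneAlignment, write_fasta_alignment
from .priors import (MA_PER_UNIT, BdParams, Calibration, CalibrationSet,
                     ClockModelSpec, bd_kernel_quantile)
from .substitution import HkyModel, SubstitutionParams
from .trees import TimeTree

__all__ = [
    "simulate_timetree", "simulate_branch_rates", "simulate_alignment",
    "simulate_gene_set", "gene_tree_newick", "make_calibrations",
    "corrupt_fixture", "CorruptionRules", "random_coding_alignment",
    "gene_rng", "write_synthetic_bundle",
]

STOP_CODONS = ("TAA", "TAG", "TGA")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def gene_rng(seed: int, gene_id: str) -> np.random.Generator:
    """Deterministic per-gene stream: hash of (seed, gene_id).

    Gene sets stay reproducible under reordering because each gene's
    stream depends only on the master seed and its own id.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(gene_id.encode())]))


# ----------------------------------------------------------------------
# Timetrees
# ----------------------------------------------------------------------

def simulate_timetree(n_tips: int, root_age: float,
                      bd: BdParams = BdParams(), seed: int = 0) -> TimeTree:
    """Random timetree with the given root age (Ma).

    Non-root interior ages are i.i.d. draws from the birth-death kernel
    conditional on the root age; the topology is built by ranked joining:
    walking through the ages youngest-first, each event joins two uniformly
    chosen active lineages (a valid labelled history).  ``root_age`` is in
    Ma; the birth-death rates are per 100-Ma time unit, so the kernel is
    evaluated on the unit scale and converted back.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if root_age <= 0:
        raise ValueError("root_age must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    labels = [f"t{i+1}" for i in range(n_tips)]
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    ages = np.zeros(n_nodes)
    if n_tips == 2:
        inner = np.array([root_age])
    else:
        u = rng.random(n_tips - 2)
        inner = np.sort(np.asarray(bd_kernel_quantile(
            u, root_age / MA_PER_UNIT, bd), float)) * MA_PER_UNIT
        inner = np.append(inner, root_age)
    active = list(range(n_tips))
    nxt = n_tips
    for age in inner:
        i = rng.integers(len(active))
        a = active.pop(i)
        j = rng.integers(len(active))
        b = active.pop(j)
        parent[a] = nxt
        parent[b] = nxt
        ages[nxt] = age
        active.append(nxt)
        nxt += 1
    return TimeTree(labels, parent, ages)


# ----------------------------------------------------------------------
# Branch rates
# ----------------------------------------------------------------------

def simulate_branch_rates(tree: TimeTree, spec: ClockModelSpec,
                          seed: int = 0) -> np.ndarray:
    """Substitution rates (per site per 100-Ma unit) on every branch.

    Returned as an array indexed by child node; the root entry is NaN
    (no branch).  STR: constant mu.  IR: i.i.d. lognormal with expectation
    mu.  AR: geometric Brownian motion on the log rate along lineages with
    mean-preserving drift -sigma2*dt/2, where dt is the gap between branch
    midpoints (per 100-Ma unit); the root's child branches diffuse from a
    lognormal with expectation mu over the gap from the root.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    n = tree.n_nodes
    rates = np.full(n, np.nan)
    nonroot = np.array([v for v in range(n) if v != tree.root])
    mu, s2 = spec.mu, spec.sigma2
    if spec.model == "STR":
        rates[nonroot] = mu
        return rates
    if spec.model == "IR":
        z = rng.standard_normal(nonroot.size)
        rates[nonroot] = np.exp(np.log(mu) - s2 / 2.0 + np.sqrt(s2) * z)
        return rates
    # AR: preorder walk, child log-rate ~ N(log parent - s2*dt/2, s2*dt)
    mid = np.zeros(n)
    for v in nonroot:
        mid[v] = 0.5 * (tree.ages[tree.parent[v]] + tree.ages[v])
    order = tree.postorder[::-1]  # preorder
    for v in order:
        p = tree.parent[v]
        if p == -1:
            continue
        if p == tree.root:
            dt = (tree.root_age - mid[v]) / MA_PER_UNIT
            mean = np.log(mu) - s2 * dt / 2.0
        else:
            dt = (mid[p] - mid[v]) / MA_PER_UNIT
            mean = np.log(rates[p]) - s2 * dt / 2.0
        sd = np.sqrt(max(s2 * dt, 0.0))
        rates[v] = np.exp(mean + sd * rng.standard_normal())
    return rates


# ----------------------------------------------------------------------
# Sequence evolution
# ----------------------------------------------------------------------

def simulate_alignment(tree: TimeTree, rates: np.ndarray,
                       sub: SubstitutionParams, n_codons: int,
                       cp_multipliers: Sequence[float] = (1.0, 0.5, 2.5),
                       seed: int = 0, gene_id: str = "gene",
                       rng: np.random.Generator | None = None
                       ) -> GeneAlignment:
    """Evolve an in-frame coding alignment down a timetree.

    Each site gets a gamma-category multiplier and a codon-position
    multiplier; the branch length seen by a site is
    duration/100Ma * branch rate * both multipliers.  No indels are
    produced here (gaps only enter via :func:`corrupt_fixture`).
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    cp = np.asarray(cp_multipliers, float)
    if cp.shape != (3,) or np.any(cp <= 0):
        raise ValueError("cp_multipliers must be 3 positive values")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    model = HkyModel(sub)
    n_sites = 3 * n_codons
    K = sub.n_categories
    cat = rng.integers(K, size=n_sites)
    cp_idx = np.arange(n_sites) % 3
    # state arrays per node; root drawn from the stationary distribution
    states = np.empty((tree.n_nodes, n_sites), dtype=np.uint8)
    pi = np.asarray(sub.base_freqs)
    states[tree.root] = rng.choice(4, size=n_sites, p=pi)
    groups = {}
    for c in range(K):
        for p in range(3):
            m = (cat == c) & (cp_idx == p)
            if m.any():
                groups[(c, p)] = np.nonzero(m)[0]
    for v in tree.postorder[::-1]:
        par = tree.parent[v]
        if par == -1:
            continue
        t_units = (tree.ages[par] - tree.ages[v]) / MA_PER_UNIT
        b = t_units * rates[v]
        for (c, p), idx in groups.items():
            bl = b * model.cat_rates[c] * cp[p]
            if bl <= 0:
                states[v, idx] = states[par, idx]
                continue
            P = model.transition_matrix(bl)
            cum = np.cumsum(P, axis=1)
            cum[:, -1] = 1.0
            u = rng.random(idx.size)
            states[v, idx] = (
                u[:, None] < cum[states[par, idx]]).argmax(axis=1)
    return GeneAlignment(gene_id, list(tree.labels),
                         states[:tree.n_tips], frame_offset=0)


def random_coding_alignment(gene_id: str, taxa: Sequence[str],
                            n_codons: int, seed: int = 0,
                            rng: np.random.Generator | None = None
                            ) -> GeneAlignment:
    """I.i.d. stop-free random coding sequences (QC fixture material)."""
    if rng is None:
        rng = gene_rng(seed, gene_id)
    sense = [c for c in ("".join(x) for x in __import__("itertools").product(
        "ACGT", repeat=3)) if c not in STOP_CODONS]
    codes = np.array([[_CODE[ch] for ch in c] for c in sense], dtype=np.uint8)
    picks = rng.integers(len(sense), size=(len(taxa), n_codons))
    mat = codes[picks].reshape(len(taxa), 3 * n_codons)
    return GeneAlignment(gene_id, list(taxa), mat, frame_offset=0)


def remove_internal_stops(aln: GeneAlignment) -> GeneAlignment:
    """Recode in-frame stop codons (third base -> C) so the alignment
    reads as a clean CDS.

    The nucleotide-level HKY simulator is codon-agnostic and will create
    occasional in-frame stops that a real functional gene would not carry;
    this in-place sanitation keeps simulated gene sets stop-free so that
    pseudogene screening has a clean baseline.
    """
    start = (3 - aln.frame_offset) % 3
    n_codons = (aln.n_sites - start) // 3
    if n_codons < 1:
        return aln
    m = aln.matrix
    for c in range(n_codons):
        s = start + 3 * c
        cod = m[:, s:s + 3]
        is_stop = (cod[:, 0] == 3) & (
            ((cod[:, 1] == 0) & ((cod[:, 2] == 0) | (cod[:, 2] == 2)))
            | ((cod[:, 1] == 2) & (cod[:, 2] == 0)))
        if is_stop.any():
            m[is_stop, s + 2] = 1  # third base -> C
    return aln


def simulate_gene_set(tree: TimeTree, spec: ClockModelSpec,
                      sub: SubstitutionParams, n_genes: int,
                      n_codons: int,
                      gene_rate_log_sd: float = 0.7,
                      cp_multipliers: Sequence[float] = (1.0, 0.5, 2.5),
                      seed: int = 0, shared_rates: bool = True
                      ) -> tuple[dict[str, GeneAlignment],
                                 dict[str, float], np.ndarray]:
    """Multi-gene alignments with slow-to-fast per-gene rate multipliers.

    Gene multipliers are lognormal (median 1, log-sd ``gene_rate_log_sd``),
    emulating the wide spread of relative gene rates that motivates rate
    binning.  With ``shared_rates`` all genes share one realization of the
    branch-rate process scaled per gene; otherwise each gene gets its own
    branch rates.  Returns (alignments by gene, multipliers, the shared
    branch rates or the last gene's).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    base_rates = simulate_branch_rates(tree, spec, seed=seed)
    alns: dict[str, GeneAlignment] = {}
    mults: dict[str, float] = {}
    for i in range(n_genes):
        gid = f"g{i+1:04d}"
        grng = gene_rng(seed, gid)
        m = float(np.exp(gene_rate_log_sd * grng.standard_normal()))
        if not shared_rates:
            base_rates = simulate_branch_rates(tree, spec,
                                               seed=seed + 7919 * (i + 1))
        alns[gid] = remove_internal_stops(
            simulate_alignment(tree, base_rates * m, sub, n_codons,
                               cp_multipliers=cp_multipliers,
                               gene_id=gid, rng=grng))
        mults[gid] = m
    return alns, mults, base_rates


def gene_tree_newick(tree: TimeTree, rates: np.ndarray,
                     multiplier: float = 1.0) -> str:
    """Newick of the gene tree implied by branch rates: branch length =
    duration/100Ma * rate * multiplier (substitutions/site)."""

    def rec(v: int) -> str:
        if v < tree.n_tips:
            s = tree.labels[v]
        else:
            s = "(" + ",".join(rec(c) for c in tree.children[v]) + ")"
        p = tree.parent[v]
        if p != -1:
            bl = (tree.ages[p] - tree.ages[v]) / MA_PER_UNIT \
                * rates[v] * multiplier
            s += f":{bl:.8f}"
        return s

    return rec(tree.root) + ";"


# ----------------------------------------------------------------------
# Calibrations from true node ages
# ----------------------------------------------------------------------

def make_calibrations(tree: TimeTree,
                      nodes: Sequence[tuple[str, str]],
                      rel_offsets: tuple[float, float] = (0.1, 0.1),
                      tails: tuple[float, float] = (0.0, 0.025)
                      ) -> CalibrationSet:
    """Bracket the true age of each anchored node by relative offsets.

    For a node of true age ``a``, the bounds are ``a*(1-below)`` and
    ``a*(1+above)``; zero-width bounds are rejected.
    """
    below, above = rel_offsets
    if below < 0 or above < 0:
        raise ValueError("offsets must be >= 0")
    entries = {}
    for pair in nodes:
        a, b = pair
        node = tree.root if pair == ("root", "root") else tree.mrca(a, b)
        age = tree.ages[node]
        tL, tU = age * (1.0 - below), age * (1.0 + above)
        if not tL < tU:
            raise ValueError(f"degenerate calibration for anchor {pair}")
        entries[pair] = Calibration(tL, tU, tails[0], tails[1])
    return CalibrationSet(entries)


# ----------------------------------------------------------------------
# Fixture corruption with a ground-truth log
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CorruptionRules:
    """What to inject: counts of genes with internal stops / frameshift
    gaps (and how many events each), plus per-taxon dropout fractions."""

    n_stop_genes: int = 0
    stops_per_gene: int = 1
    n_frameshift_genes: int = 0
    frameshifts_per_gene: int = 1
    frameshift_lengths: tuple[int, ...] = (1, 2, 4, 5)
    dropout: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for ln in self.frameshift_lengths:
            if ln % 3 == 0:
                raise ValueError("frameshift lengths must not be "
                                 "multiples of 3")
        for frac in self.dropout.values():
            if not 0 <= frac <= 1:
                raise ValueError("dropout fractions must be in [0, 1]")


def inject_stop(aln: GeneAlignment, taxon: str, codon_index: int,
                stop: str = "TAA") -> None:
    """Overwrite one in-frame codon with a stop codon (in place)."""
    i = aln.taxa.index(taxon)
    s = 3 * codon_index + (3 - aln.frame_offset) % 3
    aln.matrix[i, s:s + 3] = [_CODE[ch] for ch in stop]


def inject_frameshift(aln: GeneAlignment, taxon: str, site: int,
                      length: int) -> None:
    """Overwrite ``length`` sites with gap characters (in place)."""
    i = aln.taxa.index(taxon)
    aln.matrix[i, site:site + length] = 4


def corrupt_fixture(alignments: Sequence[GeneAlignment],
                    rules: CorruptionRules, seed: int = 0
                    ) -> tuple[list[GeneAlignment], list[dict]]:
    """Copy the alignments and inject artifacts; return (copies, log).

    The log records every event as a dict with keys ``kind`` (stop /
    frameshift / dropout), ``gene``, ``taxon`` and coordinates, so QC
    output can be checked against ground truth.  With empty rules the
    copies are bit-identical to the input.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    out = [a.copy() for a in alignments]
    log: list[dict] = []
    n_genes = len(out)
    idx_stop = rng.choice(n_genes, size=min(rules.n_stop_genes, n_genes),
                          replace=False) if rules.n_stop_genes else []
    remaining = [i for i in range(n_genes) if i not in set(np.atleast_1d(
        idx_stop).tolist())]
    if rules.n_frameshift_genes:
        idx_fs = rng.choice(remaining,
                            size=min(rules.n_frameshift_genes,
                                     len(remaining)), replace=False)
    else:
        idx_fs = []
    for gi in np.atleast_1d(idx_stop):
        aln = out[int(gi)]
        n_codons = aln.n_sites // 3
        for _ in range(rules.stops_per_gene):
            taxon = aln.taxa[rng.integers(aln.n_taxa)]
            codon = int(rng.integers(1, max(n_codons - 1, 2)))
            stop = STOP_CODONS[rng.integers(3)]
            inject_stop(aln, taxon, codon, stop)
            log.append({"kind": "stop", "gene": aln.gene_id,
                        "taxon": taxon, "codon": codon, "stop": stop})
    for gi in np.atleast_1d(idx_fs):
        aln = out[int(gi)]
        for _ in range(rules.frameshifts_per_gene):
            taxon = aln.taxa[rng.integers(aln.n_taxa)]
            length = int(rng.choice(rules.frameshift_lengths))
            site = int(rng.integers(0, max(aln.n_sites - length, 1)))
            inject_frameshift(aln, taxon, site, length)
            log.append({"kind": "frameshift", "gene": aln.gene_id,
                        "taxon": taxon, "site": site, "length": length})
    for taxon, frac in rules.dropout.items():
        for j, aln in enumerate(out):
            if taxon in aln.taxa and rng.random() < frac:
                keep = [i for i, t in enumerate(aln.taxa) if t != taxon]
                out[j] = GeneAlignment(aln.gene_id,
                                       [aln.taxa[i] for i in keep],
                                       aln.matrix[keep],
                                       aln.frame_offset, aln.codon_pos)
                log.append({"kind": "dropout", "gene": aln.gene_id,
                            "taxon": taxon})
    return out, log


# ----------------------------------------------------------------------
# Truth-table output
# ----------------------------------------------------------------------

def write_synthetic_bundle(outdir, tree: TimeTree, rates: np.ndarray,
                           alignments: Sequence[GeneAlignment],
                           seed: int, params: str = "") -> None:
    """FASTA per gene, true Newick tree (Ma) and TSV truth tables, each
    stamped with the seed and parameter string."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"seed={seed} {params}".strip()
    with open(outdir / "true_tree.nwk", "w") as fh:
        fh.write(f"[&{header}]\n{tree.to_newick()}\n")
    with open(outdir / "true_node_ages.tsv", "w") as fh:
        fh.write(f"# {header}\nnode\tage_Ma\tclade_tips\n")
        for v in tree.internal_nodes:
            tips = ",".join(sorted(tree.clade_tips(v))[:2])
            fh.write(f"{v}\t{tree.ages[v]:.6f}\t{tips}\n")
    with open(outdir / "true_branch_rates.tsv", "w") as fh:
        fh.write(f"# {header}\nbranch_child_node\trate_per_100Ma\n")
        for v in range(tree.n_nodes):
            if v != tree.root:
                fh.write(f"{v}\t{rates[v]:.8g}\n")
    for aln in alignments:
        write_fasta_alignment(aln, outdir / f"{aln.gene_id}.fasta",
                              header=header)
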