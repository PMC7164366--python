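"""Rate-binned gene partitioning and clocklike-gene ranking.

Per-gene relative rates are measured as the maximum-likelihood HKY85
distance between one odontocete-like and one mysticete-like reference
taxon (with fallbacks when the primary partner is missing), genes are
sorted and cut into k contiguous rate bins, and bins are optionally split
into first+second vs third codon-position classes.  A SortaDate-style
ranking orders genes by root-to-tip variance (clocklikeness), total tree
length (information) and bipartition agreement with the species tree for
reduced-dataset experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize

from .alignments import GeneAlignment
from .substitution import HkyModel, SubstitutionParams
from .trees import TimeTree

__all__ = ["HkyDistanceResult", "hky_distance", "GeneRateTable",
           "gene_rate_table", "Partition", "PartitionScheme", "bin_genes",
           "split_codon_positions", "partition_alignments",
           "GeneClockScore", "rank_clocklike"]

SATURATION_CAP = 10.0


@dataclass(frozen=True)
class HkyDistanceResult:
    distance: float
    kappa: float
    saturated: bool


def _count_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ok = (a < 4) & (b < 4)
    if not ok.any():
        raise ValueError("no shared ungapped sites")
    counts = np.zeros((4, 4))
    np.add.at(counts, (a[ok], b[ok]), 1.0)
    return counts


def hky_distance(seq_a: np.ndarray | str, seq_b: np.ndarray | str,
                 freqs: Sequence[float] | None = None,
                 kappa: float | None = None) -> HkyDistanceResult:
    """Two-sequence ML distance under HKY85.

    kappa is estimated jointly unless given; base frequencies are pooled
    empirical unless given.  Identical sequences give 0; if the optimum
    runs into the saturation cap (10 subs/site) the result is flagged.
    """
    if isinstance(seq_a, str):
        seq_a = GeneAlignment.from_strings("tmp", {"a": seq_a, "b": seq_b}
                                           ).matrix
        seq_a, seq_b = seq_a[0], seq_a[1]
    a = np.asarray(seq_a, np.uint8)
    b = np.asarray(seq_b, np.uint8)
    if a.shape != b.shape:
        raise ValueError("sequences differ in length")
    counts = _count_matrix(a, b)
    n = counts.sum()
    if freqs is None:
        pooled = counts.sum(axis=0) + counts.sum(axis=1)
        pooled = np.maximum(pooled, 1e-6)
        freqs = pooled / pooled.sum()
    freqs = np.asarray(freqs, float)
    if counts.trace() == n:
        return HkyDistanceResult(0.0, kappa if kappa else 1.0, False)
    mask = counts > 0

    def nll(x):
        d, k = math.exp(x[0]), (kappa if kappa is not None
                                else math.exp(x[1]))
        model = HkyModel(SubstitutionParams(k, tuple(freqs), 1.0, 1))
        P = model.transition_matrix(d)
        lik = freqs[:, None] * P
        with np.errstate(divide="ignore"):
            ll = np.where(mask, counts * np.log(np.maximum(lik, 1e-300)),
                          0.0).sum()
        return -ll

    p_dist = 1.0 - counts.trace() / n
    d0 = max(-0.75 * math.log(max(1 - 4 * p_dist / 3, 1e-6)), 1e-4)
    x0 = [math.log(d0)] if kappa is not None else [math.log(d0),
                                                   math.log(2.0)]
    bounds = [(math.log(1e-7), math.log(SATURATION_CAP))]
    if kappa is None:
        bounds.append((math.log(0.02), math.log(500.0)))
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    d_hat = math.exp(res.x[0])
    k_hat = kappa if kappa is not None else math.exp(res.x[1])
    saturated = d_hat > SATURATION_CAP * 0.999
    return HkyDistanceResult(float(min(d_hat, SATURATION_CAP)),
                             float(k_hat), bool(saturated))


# ----------------------------------------------------------------------

@dataclass
class GeneRateTable:
    """gene_id -> (HKY distance, taxon pair actually used)."""

    rates: dict[str, tuple[float, tuple[str, str]]]
    unratable: list[str] = field(default_factory=list)
    saturated: set[str] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene_id": g, "distance": d, "taxon_a": pair[0],
                 "taxon_b": pair[1], "saturated": g in self.saturated}
                for g, (d, pair) in self.rates.items()]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _usable(aln: GeneAlignment, x: str, y: str) -> bool:
    if x not in aln.taxa or y not in aln.taxa:
        return False
    a, b = aln.row(x), aln.row(y)
    return bool(np.any((a < 4) & (b < 4)))


def gene_rate_table(genes: Sequence[GeneAlignment],
                    primary_pair: tuple[str, str],
                    fallback_taxa: Sequence[str] = ()) -> GeneRateTable:
    """Per-gene HKY distances between the reference pair.

    When one primary taxon is absent (or shares no ungapped site), the
    first usable fallback substitutes for it; genes with no usable pair
    are logged as unratable and excluded.
    """
    pa, pb = primary_pair
    table = GeneRateTable({})
    for aln in genes:
        pair = None
        if _usable(aln, pa, pb):
            pair = (pa, pb)
        else:
            a_in = pa in aln.taxa
            b_in = pb in aln.taxa
            if a_in:
                for f in fallback_taxa:
                    if f != pa and _usable(aln, pa, f):
                        pair = (pa, f)
                        break
            if pair is None and b_in:
                for f in fallback_taxa:
                    if f != pb and _usable(aln, f, pb):
                        pair = (f, pb)
                        break
        if pair is None:
            table.unratable.append(aln.gene_id)
            continue
        res = hky_distance(aln.row(pair[0]), aln.row(pair[1]))
        table.rates[aln.gene_id] = (res.distance, pair)
        if res.saturated:
            table.saturated.add(aln.gene_id)
    return table


# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Partition:
    gene_ids: tuple[str, ...]
    codon_class: str = "all"      # all | 12 | 3

    def __post_init__(self):
        if self.codon_class not in ("all", "12", "3"):
            raise ValueError("codon_class must be all, 12 or 3")


@dataclass
class PartitionScheme:
    """Ordered, disjoint rate partitions covering the retained genes."""

    partitions: list[Partition]
    label: str

    def __post_init__(self):
        ids = [g for p in self.partitions for g in p.gene_ids]
        classes = {p.codon_class for p in self.partitions}
        if classes == {"all"} and len(set(ids)) != len(ids):
            raise ValueError("partitions must be disjoint")

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)

    def gene_ids(self) -> list[str]:
        out = []
        seen = set()
        for p in self.partitions:
            for g in p.gene_ids:
                if g not in seen:
                    seen.add(g)
                    out.append(g)
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("partition_id\tcodon_class\tgenes\n")
            for i, p in enumerate(self.partitions):
                fh.write(f"{self.label}.{i+1}\t{p.codon_class}\t"
                         + ",".join(p.gene_ids) + "\n")


def bin_genes(table: GeneRateTable, k: int,
              label: str | None = None) -> PartitionScheme:
    """Cut the rate-sorted gene list into k contiguous bins.

    Sizes differ by at most one, remainders go to the slowest bins first;
    saturated genes (capped distances) sort to the fastest bin.  The
    rate-ordering invariant (max distance in bin i <= min distance in bin
    i+1) is asserted before returning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    items = sorted(table.rates.items(), key=lambda kv: (kv[1][0], kv[0]))
    n = len(items)
    if n == 0:
        raise ValueError("empty rate table")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} ratable genes")
    base, rem = divmod(n, k)
    sizes = [base + 1 if i < rem else base for i in range(k)]
    parts = []
    pos = 0
    prev_max = -math.inf
    for s in sizes:
        chunk = items[pos:pos + s]
        pos += s
        dmin = chunk[0][1][0]
        dmax = chunk[-1][1][0]
        assert prev_max <= dmin, "rate-ordering invariant violated"
        prev_max = dmax
        parts.append(Partition(tuple(g for g, _ in chunk)))
    return PartitionScheme(parts, label or f"{k}p")


def split_codon_positions(scheme: PartitionScheme) -> PartitionScheme:
    """Duplicate each rate bin into 1st+2nd and 3rd codon-position
    classes (3 partitions -> 6, k -> 2k)."""
    if any(p.codon_class != "all" for p in scheme.partitions):
        raise ValueError("scheme is already split by codon position")
    parts = []
    for p in scheme.partitions:
        parts.append(Partition(p.gene_ids, "12"))
        parts.append(Partition(p.gene_ids, "3"))
    return PartitionScheme(parts, scheme.label + "x2cp")


def partition_alignments(genes: Mapping[str, GeneAlignment],
                         scheme: PartitionScheme,
                         taxa: Sequence[str] | None = None
                         ) -> list[GeneAlignment]:
    """Concatenated alignment per partition (N-padding absent taxa,
    selecting codon-position columns for split classes)."""
    from .gene_qc import concatenate_exons
    out = []
    for i, p in enumerate(scheme.partitions):
        cat, _ = concatenate_exons([genes[g] for g in p.gene_ids],
                                   f"{scheme.label}.{i+1}", taxa=taxa)
        if p.codon_class == "12":
            cat = cat.subset_sites(np.isin(cat.codon_pos, (1, 2)))
        elif p.codon_class == "3":
            cat = cat.subset_sites(cat.codon_pos == 3)
        out.append(cat)
    return out


# ----------------------------------------------------------------------
# SortaDate-style clocklike ranking
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GeneClockScore:
    gene_id: str
    clock_variance: float      # variance of root-to-tip path lengths
    tree_length: float
    agreement: float           # shared-bipartition fraction


def _parse_gene_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick")


def _tree_stats(dt: dendropy.Tree) -> tuple[float, float, dict]:
    depth: dict = {}
    total = 0.0
    tips = []
    for nd in dt.preorder_node_iter():
        el = nd.edge.length or 0.0
        if nd.parent_node is None:
            depth[id(nd)] = 0.0
        else:
            depth[id(nd)] = depth[id(nd.parent_node)] + el
            total += el
        if nd.is_leaf():
            tips.append(nd)
    r2t = np.array([depth[id(t)] for t in tips])
    return float(np.var(r2t)), total, {t.taxon.label for t in tips}


def _clades(dt: dendropy.Tree) -> set[frozenset[str]]:
    out = set()
    for nd in dt.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        tips = frozenset(l.taxon.label for l in nd.leaf_iter())
        if len(tips) > 1:
            out.add(tips)
    return out


def rank_clocklike(gene_trees: Mapping[str, object],
                   species_tree: TimeTree, n_select: int,
                   agreement_threshold: float = 0.3
                   ) -> tuple[list[GeneClockScore], list[str]]:
    """Rank genes for dating by clocklikeness, information content and
    topological agreement with the species tree.

    Genes are filtered to agreement >= threshold, then sorted by
    root-to-tip variance ascending with ties broken by total tree length
    descending; the top ``n_select`` are returned together with a log of
    excluded genes (< 4 tips or below the agreement threshold).
    """
    sp_clades_full = species_tree.bipartitions()
    scored = []
    excluded = []
    for gid in sorted(gene_trees):
        dt = _parse_gene_tree(gene_trees[gid])
        var, length, tips = _tree_stats(dt)
        if len(tips) < 4:
            excluded.append(f"{gid}: fewer than 4 tips")
            continue
        gclades = _clades(dt)
        sp_restricted = {c & frozenset(tips) for c in sp_clades_full}
        sp_restricted = {c for c in sp_restricted if len(c) > 1
                         and len(c) < len(tips)}
        gclades_nt = {c for c in gclades if len(c) < len(tips)}
        if gclades_nt:
            agree = len(gclades_nt & sp_restricted) / len(gclades_nt)
        else:
            agree = 1.0
        if agree < agreement_threshold:
            excluded.append(f"{gid}: agreement {agree:.2f} below "
                            f"threshold")
            continue
        scored.append(GeneClockScore(gid, var, length, agree))
    scored.sort(key=lambda s: (s.clock_variance, -s.tree_length,
                               s.gene_id))
    return scored[:n_select], excluded
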