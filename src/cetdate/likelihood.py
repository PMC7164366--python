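"""Exact HKY85+Gamma phylogenetic likelihood and its quadratic surrogate.

The exact likelihood uses Felsenstein pruning over compressed site
patterns.  Because the model is reversible, the likelihood depends only on
the unrooted branch lengths: the two branches meeting at the root are
merged into a single parameter (their sum), the standard identifiability
reduction.  ``mle_branch_lengths`` maximizes over those unrooted lengths,
``hessian_at_mle`` finite-differences the curvature there, and
``approx_loglik`` evaluates the second-order Taylor expansion used for
fast dating MCMC.
"""

from __future__ import annotations



from dataclasses import dataclass

from typing import Sequence

import numpy as np
from scipy import optimize

from .alignments import GeneAlignment

from .substitution import HkyModel, SubstitutionParams
from .trees import TimeTree

__all__ = ["PhyloLikelihood", "prune_loglik", "mle_branch_lengths",
           "hessian_at_mle", "ApproxPartitionSurface", "ApproxLikSurface",
           "build_surface", "approx_loglik", "branch_lengths_from_times"]

MAX_BRANCH_LENGTH = 10.0  # substitutions/site saturation cap


class PhyloLikelihood:
    """Pruning likelihood for one alignment on a fixed rooted topology.

    Branch lengths are supplied per call, either on the 2n-2 rooted
    branches (indexed by child node) or on the 2n-3 unrooted branches via
    :attr:`branch_nodes`.  Site patterns are compressed once at
    construction; tree tips absent from the alignment count as missing.
    """

    def __init__(self, aln: GeneAlignment, topology: TimeTree,
                 sub: SubstitutionParams):
        self.topology = topology
        self.sub = sub
        self.model = HkyModel(sub)
        for t in aln.taxa:
            topology.tip_index(t)  # raises for unknown taxa
        n = topology.n_tips
        full = np.full((n, aln.n_sites), 5, dtype=np.uint8)
        for i, t in enumerate(aln.taxa):
            full[topology.tip_index(t)] = aln.matrix[i]
        patterns, weights = np.unique(full, axis=1, return_counts=True)
        self.patterns = patterns
        self.weights = weights.astype(float)
        self.n_sites = aln.n_sites
        self.n_patterns = patterns.shape[1]
        # unrooted branch set: all non-root nodes minus one root child,
        # merged into its sibling (root children: prefer an internal
        # representative for stability)
        root = topology.root
        c1, c2 = topology.children[root]
        if c1 < topology.n_tips <= c2:
            c1, c2 = c2, c1
        self.merged_rep = c1      # carries the merged length
        self.merged_other = c2    # forced to zero in rooted evaluation
        self.branch_nodes = np.array(
            [v for v in range(topology.n_nodes)
             if v != root and v != c2], dtype=np.int64)
        self._ambig = patterns > 3
        self._states = np.minimum(patterns, 3)
        m = self.model
        self._ev_outer = np.outer(m.cat_rates, m.eigval)   # (K,4)
        self._right = m.right
        self._left = m.left

    @property
    def n_branches(self) -> int:
        return len(self.branch_nodes)

    def _pmats(self, t: float) -> np.ndarray:
        """Per-category transition matrices P(t*r_c): (K,4,4)."""
        lam = np.exp(self._ev_outer * t)
        P = (self._right[None, :, :] * lam[:, None, :]) @ self._left
        np.clip(P, 0.0, None, out=P)
        return P

    # ------------------------------------------------------------------
    def loglik_rooted(self, blen_by_node: np.ndarray) -> float:
        """Log likelihood with lengths (subs/site) on rooted branches,
        indexed by child node (root entry ignored)."""
        topo = self.topology
        npat = self.n_patterns
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(npat)
        for v in topo.postorder:
            if v < topo.n_tips:
                continue
            Lv = None
            for c in topo.children[v]:
                P = self._pmats(max(float(blen_by_node[c]), 0.0))
                if c < topo.n_tips:
                    contrib = P[:, :, self._states[c]]
                    if self._ambig[c].any():
                        contrib[:, :, self._ambig[c]] = 1.0
                else:
                    contrib = np.matmul(P, partial.pop(c))
                Lv = contrib if Lv is None else Lv * contrib
            scale = Lv.max(axis=(0, 1))
            if not scale.all():
                return -np.inf
            Lv /= scale
            logscale += np.log(scale)
            partial[v] = Lv
        Lroot = partial[topo.root]
        site = np.einsum("j,kjp->kp", self.model.pi, Lroot).mean(axis=0)
        return float(np.dot(np.log(site) + logscale, self.weights))

    # ------------------------------------------------------------------
    def loglik_batch(self, b_matrix: np.ndarray,
                     chunk: int = 64) -> np.ndarray:
        """Vectorized :meth:`loglik` over rows of ``b_matrix``
        (B, n_branches) -- used by the finite-difference machinery."""
        b_matrix = np.atleast_2d(b_matrix)
        out = np.empty(b_matrix.shape[0])
        for s in range(0, b_matrix.shape[0], chunk):
            out[s:s + chunk] = self._batch_chunk(b_matrix[s:s + chunk])
        return out

    def _batch_chunk(self, bm: np.ndarray) -> np.ndarray:
        topo = self.topology
        B = bm.shape[0]
        K = self._ev_outer.shape[0]
        npat = self.n_patterns
        blen = np.zeros((B, topo.n_nodes))
        blen[:, self.branch_nodes] = np.maximum(bm, 0.0)
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros((B, npat))
        for v in topo.postorder:
            if v < topo.n_tips:
                continue
            Lv = None
            for c in topo.children[v]:
                lam = np.exp(self._ev_outer[None, :, :]
                             * blen[:, c, None, None])       # (B,K,4)
                P = (self._right[None, None] * lam[:, :, None, :]) \
                    @ self._left                              # (B,K,4,4)
                np.clip(P, 0.0, None, out=P)
                if c < topo.n_tips:
                    contrib = P[:, :, :, self._states[c]]
                    if self._ambig[c].any():
                        contrib[:, :, :, self._ambig[c]] = 1.0
                else:
                    contrib = np.matmul(P, partial.pop(c))
                Lv = contrib if Lv is None else Lv * contrib
            scale = Lv.max(axis=(1, 2))                      # (B,npat)
            scale[scale <= 0] = np.nan
            Lv /= scale[:, None, None, :]
            logscale += np.log(scale)
            partial[v] = Lv
        Lroot = partial[topo.root]
        site = np.einsum("j,bkjp->bkp", self.model.pi, Lroot).mean(axis=1)
        res = np.einsum("bp,p->b", np.log(site) + logscale, self.weights)
        return np.where(np.isnan(res), -np.inf, res)

    def loglik(self, b_unrooted: np.ndarray) -> float:
        """Log likelihood from unrooted branch lengths (subs/site),
        ordered as :attr:`branch_nodes`."""
        blen = np.zeros(self.topology.n_nodes)
        blen[self.branch_nodes] = b_unrooted
        blen[self.merged_other] = 0.0
        return self.loglik_rooted(blen)


class CachedLikelihood:
    """Pruning likelihood with per-node caching for MCMC.

    Stores conditional likelihoods and per-branch contributions so that a
    proposal changing a few branch lengths only recomputes the path from
    those branches to the root.  Use :meth:`propose` /:meth:`accept` /
    :meth:`reject` in a Metropolis-Hastings loop; lengths are on rooted
    branches indexed by child node.
    """

    def __init__(self, lik: PhyloLikelihood, blen_by_node: np.ndarray):
        self.lik = lik
        topo = lik.topology
        self._order = [int(v) for v in topo.postorder if v >= topo.n_tips]
        self._pos = {v: k for k, v in enumerate(self._order)}
        self.blen = np.asarray(blen_by_node, float).copy()
        self._contrib: dict[int, np.ndarray] = {}
        self._partial: dict[int, np.ndarray] = {}
        self._slog: dict[int, np.ndarray] = {}
        self._pending: tuple | None = None
        self.loglik = self._full_rebuild()

    def _branch_contrib(self, c: int, blen: np.ndarray,
                        partial: dict) -> np.ndarray:
        lik = self.lik
        P = lik._pmats(max(float(blen[c]), 0.0))
        if c < lik.topology.n_tips:
            contrib = P[:, :, lik._states[c]]
            if lik._ambig[c].any():
                contrib[:, :, lik._ambig[c]] = 1.0
            return contrib
        return np.matmul(P, partial[c])

    def _node_update(self, v: int, blen, contrib, partial, slog) -> bool:
        Lv = None
        for c in self.lik.topology.children[v]:
            Lv = contrib[c] if Lv is None else Lv * contrib[c]
        scale = Lv.max(axis=(0, 1))
        if not scale.all():
            return False
        partial[v] = Lv / scale
        slog[v] = np.log(scale)
        return True

    def _root_loglik(self, partial, slog) -> float:
        lik = self.lik
        root = lik.topology.root
        site = np.einsum("j,kjp->kp", lik.model.pi,
                         partial[root]).mean(axis=0)
        tot = np.log(site)
        for v in self._order:
            tot = tot + slog[v]
        return float(np.dot(tot, lik.weights))

    def _full_rebuild(self) -> float:
        topo = self.lik.topology
        self._contrib.clear(); self._partial.clear(); self._slog.clear()
        for v in self._order:
            for c in topo.children[v]:
                self._contrib[c] = self._branch_contrib(
                    c, self.blen, self._partial)
            if not self._node_update(v, self.blen, self._contrib,
                                     self._partial, self._slog):
                return -np.inf
        return self._root_loglik(self._partial, self._slog)

    def propose(self, blen_new: np.ndarray,
                changed: Sequence[int]) -> float:
        """Log likelihood with updated branch lengths; call accept() or
        reject() before the next propose().  ``changed`` lists the child
        nodes whose branch length differs."""
        if self._pending is not None:
            raise RuntimeError("unresolved pending proposal")
        topo = self.lik.topology
        affected: set[int] = set()
        for c in changed:
            p = topo.parent[c]
            while p != -1 and p not in affected:
                affected.add(int(p))
                p = topo.parent[p]
        new_contrib: dict[int, np.ndarray] = {}
        new_partial: dict[int, np.ndarray] = {}
        new_slog: dict[int, np.ndarray] = {}
        changed_set = set(int(c) for c in changed)
        partial_view = _ChainMap2(new_partial, self._partial)
        ok = True
        for v in sorted(affected, key=self._pos.get):
            for c in topo.children[v]:
                if c in changed_set or c in affected:
                    new_contrib[c] = self._branch_contrib(
                        c, blen_new, partial_view)
            contrib_view = _ChainMap2(new_contrib, self._contrib)
            if not self._node_update(v, blen_new, contrib_view,
                                     new_partial, new_slog):
                ok = False
                break
        if ok:
            slog_view = _ChainMap2(new_slog, self._slog)
            partial_view = _ChainMap2(new_partial, self._partial)
            ll = self._root_loglik(partial_view, slog_view)
        else:
            ll = -np.inf
        self._pending = (np.asarray(blen_new, float).copy(), new_contrib,
                         new_partial, new_slog, ll)
        return ll

    def accept(self) -> None:
        blen, nc, npart, nsl, ll = self._pending
        self.blen = blen
        self._contrib.update(nc)
        self._partial.update(npart)
        self._slog.update(nsl)
        self.loglik = ll
        self._pending = None

    def reject(self) -> None:
        self._pending = None


class _ChainMap2:
    """Two-layer read-only dict view (first wins)."""

    __slots__ = ("a", "b")

    def __init__(self, a, b):
        self.a, self.b = a, b

    def __getitem__(self, k):
        try:
            return self.a[k]
        except KeyError:
            return self.b[k]


def prune_loglik(aln: GeneAlignment, tree: TimeTree,
                 sub: SubstitutionParams,
                 blen_by_node: np.ndarray) -> float:
    """One-shot pruning log likelihood (lengths on rooted branches)."""
    return PhyloLikelihood(aln, tree, sub).loglik_rooted(blen_by_node)


# ----------------------------------------------------------------------
# Branch-length MLEs
# ----------------------------------------------------------------------

def mle_branch_lengths(lik: PhyloLikelihood, x0: np.ndarray | None = None,
                       max_iter: int = 500) -> tuple[np.ndarray, float]:
    """Maximize the unrooted-branch-length likelihood (L-BFGS-B, numeric
    gradients, branches clamped at 0)."""
    m = lik.n_branches
    if x0 is None:
        x0 = np.full(m, 0.05)

    def neg_and_grad(b):
        # central-difference gradient, all stencil points in one batch
        h = 1e-5 * np.maximum(b, 1e-2)
        pts = np.vstack([b, b + np.diag(h), b - np.diag(h)])
        vals = lik.loglik_batch(pts)
        g = (vals[1:m + 1] - vals[m + 1:]) / (2.0 * h)
        return -vals[0], -g

    # optimize just inside the boundary (the likelihood can vanish at an
    # exact zero), then snap boundary solutions back to 0
    res = optimize.minimize(
        neg_and_grad, x0, method="L-BFGS-B", jac=True,
        bounds=[(1e-9, MAX_BRANCH_LENGTH)] * m,
        options={"maxiter": max_iter, "ftol": 1e-11,
                 "gtol": max(1e-8, 1e-6 * lik.n_sites)})
    if not res.success and "ROUND" not in str(res.message).upper():
        raise RuntimeError(
            f"branch-length optimization did not converge: {res.message}; "
            f"last iterate {res.x}")
    b_hat = np.where(res.x <= 2e-9, 0.0, res.x)
    return b_hat, float(lik.loglik(b_hat))


def hessian_at_mle(lik, b_hat: np.ndarray,
                   f0: float | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Gradient and Hessian of the log likelihood at ``b_hat``.

    Central finite differences with per-branch step
    ``h = max(1e-4, 1e-2 * b)``; coordinates at the zero boundary use
    one-sided stencils so the quadratic form still penalizes negative
    excursions.  ``lik`` may be any object with a ``loglik(b)`` method.
    """
    b = np.asarray(b_hat, float)
    m = b.size
    if f0 is None:
        f0 = lik.loglik(b)
    batch = getattr(lik, "loglik_batch", None)
    if batch is None:
        batch = lambda pts: np.array([lik.loglik(p) for p in pts])
    h = np.maximum(1e-4, 1e-2 * b)
    lo = np.where(b - h >= 0.0, b - h, b)      # one-sided at the boundary
    hi = b + h
    span = hi - lo
    # assemble every stencil point, evaluate in one batched sweep
    pts: list[np.ndarray] = []
    for i in range(m):
        bb = b.copy(); bb[i] = lo[i]; pts.append(bb.copy())
        bb[i] = hi[i]; pts.append(bb.copy())
        bb[i] = b[i] + 2 * h[i]; pts.append(bb.copy())
    pair_idx = [(i, j) for i in range(m) for j in range(i + 1, m)]
    for i, j in pair_idx:
        for xi in (hi[i], lo[i]):
            for xj in (hi[j], lo[j]):
                bb = b.copy(); bb[i], bb[j] = xi, xj
                pts.append(bb.copy())
    vals = batch(np.asarray(pts))
    f_lo = np.where(lo == b, f0, vals[0:3 * m:3])
    f_hi = vals[1:3 * m:3]
    f_2h = vals[2:3 * m:3]
    g = (f_hi - f_lo) / span
    H = np.empty((m, m))
    at_bound = lo == b
    H[np.diag_indices(m)] = np.where(
        at_bound, (f_2h - 2 * f_hi + f0) / h ** 2,
        (f_hi - 2 * f0 + f_lo) / h ** 2)
    off = vals[3 * m:]
    for k, (i, j) in enumerate(pair_idx):
        fpp, fpm, fmp, fmm = off[4 * k:4 * k + 4]
        if at_bound[i] and at_bound[j]:
            fmm = f0
        H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (span[i] * span[j])
    H = (H + H.T) / 2.0
    return g, H


# ----------------------------------------------------------------------
# Quadratic approximate-likelihood surface
# ----------------------------------------------------------------------

SURFACE_FORMAT_VERSION = 1


@dataclass
class ApproxPartitionSurface:
    """Second-order expansion of one partition's log likelihood around the
    branch-length MLEs (unrooted branches, substitutions/site)."""

    partition_id: str
    branch_nodes: np.ndarray      # representative child-node per branch
    merged_rep: int
    merged_other: int
    b_hat: np.ndarray
    logl_hat: float
    gradient: np.ndarray
    hessian: np.ndarray

    def __post_init__(self):
        m = len(self.branch_nodes)
        if not (self.b_hat.shape == self.gradient.shape == (m,)
                and self.hessian.shape == (m, m)):
            raise ValueError("surface dimensions inconsistent")
        if np.max(np.abs(self.hessian - self.hessian.T)) > 1e-8:
            raise ValueError("Hessian not symmetric")
        self.rep_index = int(np.nonzero(
            self.branch_nodes == self.merged_rep)[0][0])

    def loglik(self, b: np.ndarray) -> float:
        d = np.asarray(b, float) - self.b_hat
        return float(self.logl_hat + self.gradient @ d
                     + 0.5 * d @ self.hessian @ d)


class ApproxLikSurface:
    """Per-partition quadratic log-likelihood surfaces on a shared tree."""

    def __init__(self, partitions: Sequence[ApproxPartitionSurface]):
        if not partitions:
            raise ValueError("need at least one partition surface")
        self.partitions = list(partitions)

    def __len__(self):
        return len(self.partitions)

    def __iter__(self):
        return iter(self.partitions)

    # -- serialization (versioned TSV bundle, one block per partition) --
    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#cetdate-surface\tversion={SURFACE_FORMAT_VERSION}\t"
                     f"n_partitions={len(self.partitions)}\n")
            for p in self.partitions:
                m = len(p.branch_nodes)
                fh.write(f">partition\t{p.partition_id}\t{m}\t"
                         f"{p.merged_rep}\t{p.merged_other}\t"
                         f"{p.logl_hat:.17g}\n")
                fh.write("branch_nodes\t" + "\t".join(
                    map(str, p.branch_nodes)) + "\n")
                fh.write("b_hat\t" + "\t".join(
                    f"{x:.17g}" for x in p.b_hat) + "\n")
                fh.write("gradient\t" + "\t".join(
                    f"{x:.17g}" for x in p.gradient) + "\n")
                for row in p.hessian:
                    fh.write("H\t" + "\t".join(
                        f"{x:.17g}" for x in row) + "\n")

    @classmethod
    def load(cls, path) -> "ApproxLikSurface":
        parts = []
        with open(path) as fh:
            header = fh.readline()
            if "cetdate-surface" not in header:
                raise ValueError("not a surface bundle")
            cur = None
            rows: list[list[float]] = []
            for line in fh:
                cells = line.rstrip("\n").split("\t")
                if cells[0] == ">partition":
                    if cur is not None:
                        cur["hessian"] = np.array(rows)
                        parts.append(ApproxPartitionSurface(**cur))
                        rows = []
                    cur = {"partition_id": cells[1],
                           "merged_rep": int(cells[3]),
                           "merged_other": int(cells[4]),
                           "logl_hat": float(cells[5])}
                elif cells[0] == "branch_nodes":
                    cur["branch_nodes"] = np.array(cells[1:], dtype=np.int64)
                elif cells[0] == "b_hat":
                    cur["b_hat"] = np.array(cells[1:], dtype=float)
                elif cells[0] == "gradient":
                    cur["gradient"] = np.array(cells[1:], dtype=float)
                elif cells[0] == "H":
                    rows.append([float(x) for x in cells[1:]])
            if cur is not None:
                cur["hessian"] = np.array(rows)
                parts.append(ApproxPartitionSurface(**cur))
        return cls(parts)


def build_surface(partition_alignments: Sequence[GeneAlignment],
                  topology: TimeTree,
                  subs: SubstitutionParams | Sequence[SubstitutionParams],
                  partition_ids: Sequence[str] | None = None
                  ) -> ApproxLikSurface:
    """MLE + Hessian surfaces for each partition alignment on a shared
    topology (the dating analogue of a baseml "in.BV" computation)."""
    if isinstance(subs, SubstitutionParams):
        subs = [subs] * len(partition_alignments)
    parts = []
    x0 = None
    for k, (aln, sub) in enumerate(zip(partition_alignments, subs)):
        lik = PhyloLikelihood(aln, topology, sub)
        b_hat, logl = mle_branch_lengths(lik, x0=x0)
        x0 = np.maximum(b_hat, 1e-6)  # warm start for the next partition
        g, H = hessian_at_mle(lik, b_hat, f0=logl)
        pid = partition_ids[k] if partition_ids else f"p{k+1}"
        parts.append(ApproxPartitionSurface(
            pid, lik.branch_nodes, lik.merged_rep, lik.merged_other,
            b_hat, logl, g, H))
    return ApproxLikSurface(parts)


def branch_lengths_from_times(surface_part: ApproxPartitionSurface,
                              ages_units: np.ndarray,
                              rates: np.ndarray,
                              parent: np.ndarray) -> np.ndarray:
    """Map node ages (time units) and branch rates to unrooted branch
    lengths: b = duration * rate, with the two root-adjacent branches
    summed onto their merged representative."""
    nodes = surface_part.branch_nodes
    dur = ages_units[parent[nodes]] - ages_units[nodes]
    b = dur * rates[nodes]
    other = surface_part.merged_other
    rep_idx = surface_part.rep_index
    b[rep_idx] += (ages_units[parent[other]] - ages_units[other]) * rates[other]
    return b


def approx_loglik(surface: ApproxLikSurface | ApproxPartitionSurface,
                  ages_units: np.ndarray,
                  rates_per_partition: Sequence[np.ndarray] | np.ndarray,
                  parent: np.ndarray) -> float:
    """Taylor-approximate log likelihood at node ages (units) and branch
    rates (per unit), summed over partitions."""
    if isinstance(surface, ApproxPartitionSurface):
        surface = ApproxLikSurface([surface])
        rates_per_partition = [np.asarray(rates_per_partition)]
    total = 0.0
    for part, rates in zip(surface, rates_per_partition):
        b = branch_lengths_from_times(part, ages_units, rates, parent)
        total += part.loglik(b)
    return total
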