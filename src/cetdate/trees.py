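"""Rooted binary timetrees with node ages.

A :class:`TimeTree` stores a rooted binary topology over named tips together
with node ages in Ma (tips at age 0, every parent strictly older than its
children).  Nodes are integer-indexed: tips ``0..n-1`` (in label order of
construction), internal nodes ``n..2n-2``; each non-root node identifies the
branch to its parent, so "branch i" means the edge above node i throughout
the package.
"""

from __future__ import annotations


from typing import Sequence

import dendropy
import numpy as np

__all__ = ["TimeTree"]


class TimeTree:
    """Rooted binary tree over named tips with node ages in Ma."""

    __slots__ = ("labels", "parent", "children", "ages", "root", "n_tips",
                 "_postorder", "_tip_index")

    def __init__(self, labels: Sequence[str], parent: np.ndarray,
                 ages: np.ndarray | None = None, validate: bool = True):
        self.labels = list(labels)
        self.n_tips = len(self.labels)
        n = self.n_tips
        self.parent = np.asarray(parent, dtype=np.int64).copy()
        if self.parent.shape != (2 * n - 1,):
            raise ValueError(f"parent array must have length {2*n-1}")
        self.children: list[list[int]] = [[] for _ in range(2 * n - 1)]
        root = -1
        for i, p in enumerate(self.parent):
            if p == -1:
                if root != -1:
                    raise ValueError("multiple roots")
                root = i
            else:
                self.children[p].append(i)
        self.root = root
        if ages is None:
            self.ages = np.zeros(2 * n - 1)
        else:
            self.ages = np.asarray(ages, dtype=float).copy()
        self._tip_index = {lab: i for i, lab in enumerate(self.labels)}
        self._postorder = self._compute_postorder()
        if validate:
            self.validate()

    # ------------------------------------------------------------------
    def _compute_postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return np.asarray(order, dtype=np.int64)

    def validate(self) -> None:
        n = self.n_tips
        if n < 2:
            raise ValueError("a tree needs at least 2 tips")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate tip labels")
        for i in range(n):
            if self.children[i]:
                raise ValueError(f"tip {i} has children")
        for i in range(n, 2 * n - 1):
            if len(self.children[i]) != 2:
                raise ValueError(f"internal node {i} is not binary")
        if np.any(self.ages[:n] != 0.0):
            raise ValueError("tip ages must all be 0")
        for i in range(2 * n - 1):
            p = self.parent[i]
            if p != -1 and not self.ages[p] > self.ages[i]:
                raise ValueError(
                    f"node {i} (age {self.ages[i]}) not younger than parent "
                    f"{p} (age {self.ages[p]})")

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    @property
    def postorder(self) -> np.ndarray:
        """Node indices in postorder (children before parents)."""
        return self._postorder

    @property
    def internal_nodes(self) -> np.ndarray:
        return np.arange(self.n_tips, self.n_nodes)

    def tip_index(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise KeyError(f"tip label {label!r} not in tree") from None

    def branch_duration(self, node: int) -> float:
        """Duration in Ma of the branch above ``node``."""
        p = self.parent[node]
        if p == -1:
            raise ValueError("root has no branch")
        return float(self.ages[p] - self.ages[node])

    def durations(self) -> np.ndarray:
        """Branch durations (Ma) indexed by child node; root entry is 0."""
        d = np.zeros(self.n_nodes)
        has_par = self.parent >= 0
        d[has_par] = self.ages[self.parent[has_par]] - self.ages[has_par]
        return d

    def mrca(self, label_a: str, label_b: str) -> int:
        """Most recent common ancestor node of two tips."""
        a, b = self.tip_index(label_a), self.tip_index(label_b)
        anc = set()
        while a != -1:
            anc.add(a)
            a = self.parent[a]
        while b not in anc:
            b = self.parent[b]
        return int(b)

    def clade_tips(self, node: int) -> frozenset[str]:
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n_tips:
                out.append(self.labels[v])
            else:
                stack.extend(self.children[v])
        return frozenset(out)

    def copy(self) -> "TimeTree":
        return TimeTree(self.labels, self.parent, self.ages, validate=False)

    # ------------------------------------------------------------------
    # Newick I/O (dendropy-backed parsing)
    # ------------------------------------------------------------------
    def to_newick(self, digits: int = 6) -> str:
        """Newick string with branch lengths in Ma."""

        def rec(v: int) -> str:
            if v < self.n_tips:
                s = self.labels[v]
            else:
                s = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            p = self.parent[v]
            if p != -1:
                s += f":{self.ages[p] - self.ages[v]:.{digits}f}"
            return s

        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 100))
        try:
            return rec(self.root) + ";"
        finally:
            sys.setrecursionlimit(old)

    @classmethod
    def from_newick(cls, newick: str, ultrametric: bool = True,
                    tol: float = 1e-6) -> "TimeTree":
        """Build from a rooted binary Newick string.

        With ``ultrametric=True`` branch lengths are read as Ma and node ages
        recovered as heights above the tips (checked to tolerance ``tol``
        relative to the root age).  With ``ultrametric=False`` only the
        topology is kept and all ages are set to zero (useful for fixed input
        topologies whose ages the sampler will estimate).
        """
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               suppress_internal_node_taxa=True)
        dnodes = [nd for nd in dt.preorder_node_iter()]
        tips = [nd for nd in dnodes if nd.is_leaf()]
        internals = [nd for nd in dnodes if not nd.is_leaf()]
        for nd in internals:
            if len(nd.child_nodes()) != 2:
                raise ValueError("tree must be strictly binary and rooted")
        labels = [t.taxon.label for t in tips]
        index = {id(nd): i for i, nd in enumerate(tips)}
        for j, nd in enumerate(internals):
            index[id(nd)] = len(tips) + j
        n_all = len(tips) + len(internals)
        parent = np.full(n_all, -1, dtype=np.int64)
        for nd in dnodes:
            if nd.parent_node is not None:
                parent[index[id(nd)]] = index[id(nd.parent_node)]
        ages = np.zeros(n_all)
        if ultrametric:
            # age = max root-to-tip distance minus depth
            depth = {id(dt.seed_node): 0.0}
            for nd in dt.preorder_node_iter():
                if nd.parent_node is not None:
                    el = nd.edge.length or 0.0
                    depth[id(nd)] = depth[id(nd.parent_node)] + el
            h = max(depth[id(t)] for t in tips)
            for nd in dnodes:
                a = h - depth[id(nd)]
                if nd.is_leaf():
                    if abs(a) > tol * max(h, 1.0):
                        raise ValueError("tree is not ultrametric")
                    a = 0.0
                ages[index[id(nd)]] = a
        return cls(labels, parent, ages)

    # ------------------------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions as tip-label sets (rooted clades,
        excluding the root and individual tips)."""
        out: set[frozenset[str]] = set()
        for v in range(self.n_tips, self.n_nodes):
            if v == self.root:
                continue
            out.add(self.clade_tips(v))
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<TimeTree n_tips={self.n_tips} root_age="
                f"{self.root_age:.3f} Ma>")
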