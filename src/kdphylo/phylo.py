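"""Rooted time trees with contemporaneous tips.

The package works in years BP throughout: every tip sits at age 0 and node
ages increase into the past, so a branch length is simply ``age(parent) -
age(child)``.  The container is deliberately array-based (parent pointers +
an age vector) because the MCMC samplers edit node ages in place millions of
times; Newick reading and writing is delegated to dendropy.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["TimeTree"]


class TimeTree:
    """A rooted binary tree with node ages in years before present.

    Parameters
    ----------
    parent
        Integer array of parent indices, ``-1`` for the root.
    ages
        Node ages in years BP.  Tips must be (numerically) contemporaneous
        at age 0; every parent must be older than its children.
    labels
        Per-node labels; internal nodes may be ``None``.
    """

    def __init__(self, parent: Sequence[int], ages: Sequence[float],
                 labels: Sequence[str | None]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.ages = np.asarray(ages, dtype=float).copy()
        self.labels = list(labels)
        if not (len(self.parent) == len(self.ages) == len(self.labels)):
            raise ValueError("parent, ages and labels must have equal length")
        self._rebuild_topology_caches()
        self._validate()

    # ------------------------------------------------------------------ #
    # construction / validation
    # ------------------------------------------------------------------ #
    def _rebuild_topology_caches(self) -> None:
        n = len(self.parent)
        children: list[list[int]] = [[] for _ in range(n)]
        root = -1
        for i, p in enumerate(self.parent):
            if p < 0:
                root = i
            else:
                children[p].append(i)
        if root < 0:
            raise ValueError("tree has no root")
        self.root = root
        self.children = children
        # postorder: children before parents
        post: list[int] = []
        stack = [root]
        while stack:
            node = stack.pop()
            post.append(node)
            stack.extend(children[node])
        post.reverse()
        self.postorder = np.asarray(post, dtype=np.int64)
        self.tips = np.asarray([i for i in range(n) if not children[i]],
                               dtype=np.int64)
        self.is_binary = all(len(c) in (0, 2) for c in children)

    def _validate(self) -> None:
        for i, p in enumerate(self.parent):
            if p >= 0 and self.ages[p] < self.ages[i] - 1e-9:
                raise ValueError(
                    f"node {i} (age {self.ages[i]}) is older than its "
                    f"parent {p} (age {self.ages[p]})")
        for t in self.tips:
            if self.labels[t] is None:
                raise ValueError(f"tip {t} has no label")
        names = [self.labels[t] for t in self.tips]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tip labels")

    # ------------------------------------------------------------------ #
    # basic queries
    # ------------------------------------------------------------------ #
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[t] for t in self.tips]

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        return 0.0 if p < 0 else float(self.ages[p] - self.ages[node])

    def branch_lengths(self) -> np.ndarray:
        """Branch lengths in years (0 for the root)."""
        bl = np.zeros(self.n_nodes)
        mask = self.parent >= 0
        bl[mask] = self.ages[self.parent[mask]] - self.ages[np.where(mask)[0]]
        return bl

    def internal_nodes(self) -> np.ndarray:
        return np.asarray([i for i in range(self.n_nodes) if self.children[i]],
                          dtype=np.int64)

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        return bool(np.all(np.abs(self.ages[self.tips]) <= tol))

    def copy(self) -> "TimeTree":
        """Fast copy sharing no mutable state (skips re-validation)."""
        new = TimeTree.__new__(TimeTree)
        new.parent = self.parent.copy()
        new.ages = self.ages.copy()
        new.labels = list(self.labels)
        new.root = self.root
        new.children = [list(c) for c in self.children]
        new.postorder = self.postorder
        new.tips = self.tips
        new.is_binary = self.is_binary
        return new

    # ------------------------------------------------------------------ #
    # clades
    # ------------------------------------------------------------------ #
    def clade_bitmasks(self) -> np.ndarray:
        """Per-node bitmask over tips (bit k = k-th tip in sorted label order)."""
        order = {lab: k for k, lab in enumerate(sorted(self.tip_labels))}
        masks = np.zeros(self.n_nodes, dtype=object)
        for node in self.postorder:
            if not self.children[node]:
                masks[node] = 1 << order[self.labels[node]]
            else:
                m = 0
                for c in self.children[node]:
                    m |= masks[c]
                masks[node] = m
        return masks

    def mrca(self, taxa: Iterable[str]) -> int:
        """Index of the most recent common ancestor of a set of tip labels."""
        want = set(taxa)
        missing = want - set(self.tip_labels)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        if len(want) < 2:
            raise ValueError("mrca needs at least 2 taxa")
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        for node in self.postorder:
            if not self.children[node]:
                counts[node] = 1 if self.labels[node] in want else 0
            else:
                counts[node] = sum(counts[c] for c in self.children[node])
            if counts[node] == len(want):
                return int(node)
        raise RuntimeError("unreachable")  # pragma: no cover

    def descendant_tips(self, node: int) -> set[str]:
        out: set[str] = set()
        stack = [node]
        while stack:
            v = stack.pop()
            if self.children[v]:
                stack.extend(self.children[v])
            else:
                out.add(self.labels[v])
        return out

    # ------------------------------------------------------------------ #
    # newick I/O (via dendropy)
    # ------------------------------------------------------------------ #
    def to_newick(self) -> str:
        def rec(node: int) -> str:
            if not self.children[node]:
                return f"{self.labels[node]}:{self.branch_length(node):.10g}"
            inner = ",".join(rec(c) for c in self.children[node])
            return f"({inner}):{self.branch_length(node):.10g}"
        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               suppress_internal_node_taxa=True)
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree) -> "TimeTree":
        nodes = list(dt.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, depth, labels = [], [], []
        for nd in nodes:
            if nd.parent_node is None:
                parent.append(-1)
                depth.append(0.0)
            else:
                p = index[id(nd.parent_node)]
                parent.append(p)
                depth.append(depth[p] + (nd.edge.length or 0.0))
            labels.append(nd.taxon.label if nd.taxon is not None else None)
        depth = np.asarray(depth)
        height = depth.max()
        ages = height - depth
        # snap near-contemporaneous tips to exactly 0
        ages[np.abs(ages) < 1e-6 * max(height, 1.0)] = np.maximum(
            ages[np.abs(ages) < 1e-6 * max(height, 1.0)], 0.0)
        return cls(parent, ages, labels)

    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None
                    ) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                 taxon_namespace=taxon_namespace)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<TimeTree n_tips={self.n_tips} "
                f"root_age={self.root_age:.1f} BP>")


def write_newick_list(trees: Iterable[TimeTree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


def read_newick_list(path) -> list[TimeTree]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(TimeTree.from_newick(line))
    return out
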