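"""Agglomerative WPGMA/UPGMA clustering into an ultrametric dendrogram.

WPGMA (Weighted Pair Group Method with Arithmetic mean) repeatedly
merges the closest pair of clusters at height ``d/2`` and replaces their
distances to every other cluster by the *simple* average

    d(i∪j, k) = (d(i,k) + d(j,k)) / 2

independent of cluster sizes ("weighted" because earlier members end up
down-weighted).  UPGMA uses the size-weighted average instead.  Both
updates are reducible, so merge heights never decrease and the result is
a proper ultrametric tree: the cophenetic distance between two leaves is
twice the height of their lowest common ancestor.

Ties in the minimum distance are broken deterministically by the
lexicographically smallest leaf label contained in each candidate
cluster (smaller first, then the partner), so a given matrix always
yields the same tree regardless of input order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import MarkerdivError, ValidationError
from .io_formats import newick_string
from .similarity import DistanceMatrix


@dataclass
class Node:
    """One dendrogram node; a leaf iff it has no children."""

    height: float
    label: str | None = None
    children: tuple["Node", "Node"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        """Leaf labels below this node, left to right."""
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        return [l for c in self.children for l in c.leaves()]


@dataclass
class Merge:
    """Record of one agglomeration step."""

    order: int
    height: float
    members_a: frozenset[str]
    members_b: frozenset[str]


@dataclass
class Dendrogram:
    """Rooted binary ultrametric merge tree over genotype leaves."""

    root: Node
    genotype_ids: list[str]
    merges: list[Merge] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.genotype_ids)

    @property
    def height(self) -> float:
        return self.root.height

    def to_newick(self) -> str:
        return newick_string(self)


@dataclass
class ClusterAssignment:
    """A k-way partition of the genotypes from cutting a dendrogram."""

    k: int
    assignment: dict[str, int]

    def clusters(self) -> list[frozenset[str]]:
        """Member sets, indexed by cluster number."""
        out: dict[int, set[str]] = {}
        for g, c in self.assignment.items():
            out.setdefault(c, set()).add(g)
        return [frozenset(out[i]) for i in sorted(out)]

    def as_partition(self) -> frozenset[frozenset[str]]:
        """Order-free view, convenient for comparing partitions."""
        return frozenset(self.clusters())


def wpgma(d: DistanceMatrix, method: str = "wpgma") -> Dendrogram:
    """Cluster a distance matrix into an ultrametric dendrogram.

    Parameters
    ----------
    d
        Validated symmetric non-negative distances, >= 2 genotypes.
    method
        ``"wpgma"`` (simple average update, default) or ``"upgma"``
        (size-weighted average).

    The pair merged at each step is the one with minimal current
    distance; ties are broken by each cluster's lexicographically
    smallest leaf label.
    """
    if method not in ("wpgma", "upgma"):
        raise ValidationError(f"unknown linkage {method!r}; use 'wpgma' or 'upgma'")
    ids = list(d.genotype_ids)
    n = len(ids)
    if n < 2:
        raise ValidationError("clustering needs at least 2 genotypes")

    # cluster state: key -> (Node, min leaf label, size)
    clusters: dict[int, tuple[Node, str, int]] = {
        i: (Node(0.0, label=g), g, 1) for i, g in enumerate(ids)
    }
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): float(d.values[i, j])
        for i, j in itertools.combinations(range(n), 2)
    }
    merges: list[Merge] = []
    next_key = n
    for step in range(n - 1):
        # minimal distance, ties by (smaller min-label, larger min-label)
        def sort_key(pair: frozenset[int]) -> tuple[float, str, str]:
            i, j = sorted(pair, key=lambda k: clusters[k][1])
            return (dist[pair], clusters[i][1], clusters[j][1])

        best = min(dist, key=sort_key)
        dmin = dist[best]
        i, j = sorted(best, key=lambda k: clusters[k][1])
        node_i, lab_i, size_i = clusters[i]
        node_j, lab_j, size_j = clusters[j]
        new_node = Node(height=dmin / 2.0, children=(node_i, node_j))
        merges.append(
            Merge(
                order=step,
                height=dmin / 2.0,
                members_a=frozenset(node_i.leaves()),
                members_b=frozenset(node_j.leaves()),
            )
        )
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            if method == "wpgma":
                dnew = (dik + djk) / 2.0
            else:
                dnew = (size_i * dik + size_j * djk) / (size_i + size_j)
            dist[frozenset((next_key, k))] = dnew
        del dist[best]
        del clusters[i], clusters[j]
        clusters[next_key] = (new_node, min(lab_i, lab_j), size_i + size_j)
        next_key += 1

    (root, _, _), = clusters.values()
    return Dendrogram(root=root, genotype_ids=ids, merges=merges)


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Size-weighted (UPGMA) variant of :func:`wpgma`."""
    return wpgma(d, method="upgma")


def cophenetic(t: Dendrogram) -> DistanceMatrix:
    """Cophenetic distances: 2 x height of each leaf pair's LCA."""
    ids = t.genotype_ids
    index = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    out = np.zeros((n, n))

    def visit(node: Node) -> list[str]:
        if node.is_leaf:
            return [node.label]  # type: ignore[list-item]
        left = visit(node.children[0])
        right = visit(node.children[1])
        for a in left:
            for b in right:
                out[index[a], index[b]] = out[index[b], index[a]] = 2.0 * node.height
        return left + right

    visit(t.root)
    return DistanceMatrix(list(ids), out, method="cophenetic")


def cut_tree(t: Dendrogram, k: int) -> ClusterAssignment:
    """Extract k clusters by removing the k-1 highest merges.

    Height ties are resolved by removing later merges first, which for a
    monotone merge sequence is equivalent to keeping only the first
    ``n - k`` merges.
    """
    n = t.n_leaves
    if not 1 <= k <= n:
        raise MarkerdivError(f"k must be in [1, {n}], got {k}")
    if not t.merges:
        raise ValidationError("dendrogram carries no merge history; cannot cut")
    keep = sorted(t.merges, key=lambda m: (m.height, m.order))[: n - k]
    parent: dict[str, str] = {g: g for g in t.genotype_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in keep:
        ra, rb = find(min(m.members_a)), find(min(m.members_b))
        parent[rb] = ra
    roots: dict[str, int] = {}
    assignment: dict[str, int] = {}
    for g in t.genotype_ids:
        r = find(g)
        assignment[g] = roots.setdefault(r, len(roots))
    return ClusterAssignment(k=k, assignment=assignment)
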