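"""Neighbor-Joining inference and topological tree comparison.

Trees are stored as undirected weighted graphs with labelled leaves and an
optional root (used only for Newick serialization and simulation).  The
Robinson-Foulds metric is normalized by the total number of internal
bipartitions of both trees, so two maximally different binary trees score
1.  The quartet distance is the fraction of 4-leaf subsets whose induced
unrooted topology differs; a quartet unresolved in one tree only never
agrees, while quartets unresolved in both do.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidMatrixError, LeafSetError, ParseError
from .distance import DistanceMatrix

__all__ = [
    "PhyloTree",
    "neighbor_joining",
    "rf_normalized",
    "quartet_distance",
]


@dataclass
class PhyloTree:
    """Unrooted (optionally rooted) tree with labelled leaves."""

    adj: dict[int, dict[int, float]] = field(default_factory=dict)
    leaf_labels: dict[int, str] = field(default_factory=dict)
    root: int | None = None

    # -- construction -----------------------------------------------------
    def add_edge(self, u: int, v: int, length: float = 0.0) -> None:
        self.adj.setdefault(u, {})[v] = float(length)
        self.adj.setdefault(v, {})[u] = float(length)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.leaf_labels.values()))

    @property
    def leaves(self) -> dict[str, int]:
        return {lab: node for node, lab in self.leaf_labels.items()}

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            {u: dict(nb) for u, nb in self.adj.items()},
            dict(self.leaf_labels),
            self.root,
        )

    # -- Newick -----------------------------------------------------------
    def to_newick(self) -> str:
        if not self.adj:
            raise ValueError("empty tree")
        root = self.root
        if root is None or root not in self.adj:
            internals = [u for u in self.adj if u not in self.leaf_labels]
            root = internals[0] if internals else next(iter(self.adj))

        def render(u, parent):
            children = [v for v in self.adj[u] if v != parent]
            if not children:
                return self.leaf_labels.get(u, "")
            inner = ",".join(
                f"{render(v, u)}:{self.adj[u][v]:.10g}" for v in children
            )
            return f"({inner}){self.leaf_labels.get(u, '')}"

        return render(root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        import dendropy

        try:
            dtree = dendropy.Tree.get(data=text, schema="newick")
        except Exception as exc:  # dendropy raises various subclasses
            raise ParseError(f"invalid Newick: {exc}") from None
        tree = cls()
        ids: dict = {}

        def nid(node):
            if node not in ids:
                ids[node] = len(ids)
            return ids[node]

        for edge in dtree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            ln = edge.length if edge.length is not None else 0.0
            tree.add_edge(nid(edge.tail_node), nid(edge.head_node), ln)
        for leaf in dtree.leaf_node_iter():
            tree.leaf_labels[nid(leaf)] = leaf.taxon.label.replace(" ", "_")
        tree.root = nid(dtree.seed_node)
        # a seed node of degree 1 whose child is internal is a stray rooting
        return tree

    # -- topology views ----------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Internal bipartitions, each canonicalized as the side not
        containing the lexicographically smallest leaf."""
        labels = self.labels
        if not labels:
            return set()
        anchor = labels[0]
        splits: set[frozenset[str]] = set()
        for u in self.adj:
            for v in self.adj[u]:
                if u > v:
                    continue
                side = self._leaves_beyond(u, v)
                if anchor in side:
                    side = frozenset(set(labels) - side)
                if 2 <= len(side) <= len(labels) - 2:
                    splits.add(frozenset(side))
        return splits

    def _leaves_beyond(self, u: int, v: int) -> frozenset[str]:
        """Leaf labels on v's side of the edge (u, v)."""
        out = set()
        stack = [(v, u)]
        while stack:
            node, parent = stack.pop()
            if node in self.leaf_labels:
                out.add(self.leaf_labels[node])
            for w in self.adj[node]:
                if w != parent:
                    stack.append((w, node))
        return frozenset(out)

    def topological_leaf_distances(self) -> tuple[tuple[str, ...], np.ndarray]:
        """Edge-count distances between all leaf pairs (degree-2 nodes,
        e.g. a root, are suppressed for path counting)."""
        adj = {u: set(nb) for u, nb in self.adj.items()}
        # suppress degree-2 non-leaf nodes so rooting does not affect counts
        for u in list(adj):
            if u not in self.leaf_labels and len(adj[u]) == 2:
                a, b = adj[u]
                adj[a].discard(u)
                adj[b].discard(u)
                adj[a].add(b)
                adj[b].add(a)
                del adj[u]
        labels = self.labels
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        D = np.zeros((n, n), dtype=np.int64)
        for lab, start in self.leaves.items():
            dist = {start: 0}
            stack = [start]
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if y not in dist:
                        dist[y] = dist[x] + 1
                        stack.append(y)
            for other, node in self.leaves.items():
                D[index[lab], index[other]] = dist[node]
        return labels, D


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Standard Neighbor-Joining (Studier-Keppler criterion).

    Consistent: on an additive matrix it returns the generating topology
    and branch lengths.  Negative estimated branch lengths are clamped to
    zero.
    """
    D = np.asarray(dm.values, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InvalidMatrixError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise InvalidMatrixError("distance matrix must be symmetric")
    k = D.shape[0]
    if k < 3:
        raise InvalidMatrixError("need at least 3 taxa")

    tree = PhyloTree()
    next_id = 0
    active: list[int] = []
    for label in dm.labels:
        tree.adj.setdefault(next_id, {})
        tree.leaf_labels[next_id] = label
        active.append(next_id)
        next_id += 1
    D = D.copy()

    while len(active) > 2:
        r = len(active)
        totals = D.sum(axis=1)
        Q = (r - 2) * D - totals[:, None] - totals[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2 * (r - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = next_id
        next_id += 1
        tree.add_edge(new, active[i], li)
        tree.add_edge(new, active[j], lj)
        drow = 0.5 * (D[i] + D[j] - dij)
        keep = [t for t in range(r) if t not in (i, j)]
        D = np.vstack([D[keep][:, keep], drow[keep]])
        D = np.hstack([D, np.append(drow[keep], 0.0)[:, None]])
        active = [active[t] for t in keep] + [new]

    u, v = active
    # join the last two nodes by a single edge
    d_uv = max(D[0, 1], 0.0)
    tree.add_edge(u, v, d_uv)
    return tree


def _check_leafsets(t1: PhyloTree, t2: PhyloTree, min_leaves: int) -> None:
    if t1.labels != t2.labels:
        raise LeafSetError(
            f"leaf sets differ: {t1.labels} vs {t2.labels}"
        )
    if len(t1.labels) < min_leaves:
        raise LeafSetError(f"need at least {min_leaves} shared leaves")


def rf_normalized(t1: PhyloTree, t2: PhyloTree) -> float:
    """Robinson-Foulds distance normalized to [0, 1]."""
    _check_leafsets(t1, t2, 4)
    s1 = t1.bipartitions()
    s2 = t2.bipartitions()
    total = len(s1) + len(s2)
    if total == 0:
        return 0.0
    return len(s1 ^ s2) / total


def _quartet_topology(D, a, b, c, d):
    """0 = unresolved, else 1/2/3 encoding which pairing is the split."""
    s_ab = D[a, b] + D[c, d]
    s_ac = D[a, c] + D[b, d]
    s_ad = D[a, d] + D[b, c]
    sums = (s_ab, s_ac, s_ad)
    m = min(sums)
    if sums.count(m) != 1:
        return 0
    return sums.index(m) + 1


def quartet_distance(t1: PhyloTree, t2: PhyloTree) -> float:
    """Fraction of leaf quartets with different induced topologies,
    computed by explicit enumeration of all 4-subsets."""
    _check_leafsets(t1, t2, 4)
    labels1, D1 = t1.topological_leaf_distances()
    labels2, D2 = t2.topological_leaf_distances()
    remap = [labels2.index(lab) for lab in labels1]
    n = len(labels1)
    disagree = 0
    total = 0
    for a, b, c, d in itertools.combinations(range(n), 4):
        q1 = _quartet_topology(D1, a, b, c, d)
        q2 = _quartet_topology(D2, remap[a], remap[b], remap[c], remap[d])
        if q1 != q2:
            disagree += 1
        total += 1
    return disagree / total
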