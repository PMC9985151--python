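"""Rank and rank-indel distances, three independent routes.

* :func:`rank_distance_bfs` — linear-time component scoring on the two
  adjacency vectors.
* :func:`rank_distance_formula` / :func:`rank_indel_from_stats` — closed
  forms ``2n - 2c - p0 -/+ pAB`` on classified breakpoint-graph statistics.
* :func:`exact_rank` — exact integer rank of the matrix difference
  (fraction-free Bareiss elimination, no floating point).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .bpgraph import ComponentStats, build_bg, classify_components, stats
from .errors import (
    DimensionError,
    DuplicateLabelError,
    InvalidGenomeError,
)
from .genome import Genome, to_matrix

__all__ = [
    "rank_distance_bfs",
    "rank_distance_formula",
    "rank_indel_from_stats",
    "rank_distance",
    "rank_indel_distance",
    "exact_rank",
    "rank_distance_exact",
    "DistanceMatrix",
    "distance_matrix",
]

Metric = Literal["rank", "rank_indel"]


def _check_involution(vec: Sequence[int], name: str) -> None:
    size = len(vec) - 1
    for i in range(1, size + 1):
        v = vec[i]
        if v == 0:
            continue
        if not (1 <= v <= size) or vec[v] != i:
            raise InvalidGenomeError(
                f"vector {name} is not an involution at index {i}"
            )


def rank_distance_bfs(avec: Sequence[int], bvec: Sequence[int]) -> int:
    """Rank distance from two adjacency vectors (index 0 unused), in O(n).

    Traverses the breakpoint graph, scoring each component by the number of
    A-null minus B-null extremities in it; a zero score decrements the
    distance by 1 for a path and by 2 for a cycle, starting from 2n.
    """
    if len(avec) != len(bvec):
        raise DimensionError(
            f"vector lengths differ: {len(avec)} vs {len(bvec)}"
        )
    if len(avec) % 2 != 1:  # index 0 unused => odd list length
        raise DimensionError("adjacency vector must have length 2n + 1")
    _check_involution(avec, "A")
    _check_involution(bvec, "B")
    size = len(avec) - 1
    d = size
    seen = [False] * (size + 1)
    for start in range(1, size + 1):
        if seen[start]:
            continue
        nodes = []
        stack = [start]
        seen[start] = True
        while stack:
            x = stack.pop()
            nodes.append(x)
            for v in (avec[x], bvec[x]):
                if v not in (0, x) and not seen[v]:
                    seen[v] = True
                    stack.append(v)
        score = 0
        degree_sum = 0
        for x in nodes:
            if avec[x] == 0:
                score += 1
            elif avec[x] != x:
                degree_sum += 1
            if bvec[x] == 0:
                score -= 1
            elif bvec[x] != x:
                degree_sum += 1
        n_edges = degree_sum // 2
        if score == 0:
            d -= 2 if n_edges == len(nodes) and n_edges > 0 else 1
    return d


def rank_distance_formula(st: ComponentStats) -> int:
    """Closed form ``2n - 2c - p0 - pAB``."""
    return 2 * st.n - 2 * st.c - st.p0 - st.pAB


def rank_indel_from_stats(st: ComponentStats) -> int:
    """Closed form ``2n - 2c - p0 + pAB``."""
    return 2 * st.n - 2 * st.c - st.p0 + st.pAB


def _pair_stats(A: Genome, B: Genome) -> ComponentStats:
    return stats(classify_components(build_bg(A, B)), A.universe)


def rank_distance(A: Genome, B: Genome) -> int:
    """Rank distance of two genomes (linear-time route)."""
    build_bg(A, B)  # universe check
    return rank_distance_bfs(A.adjacency_vector(), B.adjacency_vector())


def rank_indel_distance(A: Genome, B: Genome) -> int:
    """Rank-indel distance; defined for whole-marker genomes only."""
    if not A.whole_marker or not B.whole_marker:
        raise InvalidGenomeError(
            "rank-indel distance requires whole-marker genomes"
        )
    return rank_indel_from_stats(_pair_stats(A, B))


def exact_rank(M) -> int:
    """Exact rank of an integer matrix over the rationals.

    Fraction-free Bareiss elimination with full pivoting on Python ints;
    intermediate entries are subdeterminants, so no tolerance is involved.
    """
    A = [[int(v) for v in row] for row in np.atleast_2d(np.asarray(M))]
    if not A or not A[0]:
        return 0
    nrows, ncols = len(A), len(A[0])
    prev = 1
    r = 0
    while r < min(nrows, ncols):
        # find a pivot anywhere in the remaining submatrix
        pr = pc = -1
        for i in range(r, nrows):
            for j in range(r, ncols):
                if A[i][j] != 0:
                    pr, pc = i, j
                    break
            if pr >= 0:
                break
        if pr < 0:
            break
        A[r], A[pr] = A[pr], A[r]
        if pc != r:
            for row in A:
                row[r], row[pc] = row[pc], row[r]
        piv = A[r][r]
        for i in range(r + 1, nrows):
            air = A[i][r]
            Ai, Ar = A[i], A[r]
            for j in range(r + 1, ncols):
                Ai[j] = (Ai[j] * piv - air * Ar[j]) // prev
            Ai[r] = 0
        prev = piv
        r += 1
    return r


def rank_distance_exact(A: Genome, B: Genome) -> int:
    """Oracle route: exact rank of ``B - A`` as genomic matrices."""
    build_bg(A, B)  # universe check
    return exact_rank(to_matrix(B) - to_matrix(A))


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values)
        if vals.shape != (len(self.labels), len(self.labels)):
            raise DimensionError("matrix shape does not match labels")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, pair: tuple[str, str]):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return self.values[i, j]

    def to_phylip(self, strict: bool = False) -> str:
        """PHYLIP square matrix; ``strict`` pads labels to 10 characters."""
        lines = [f"{len(self.labels)}"]
        for label, row in zip(self.labels, self.values):
            name = f"{label[:10]:<10}" if strict else label
            vals = " ".join(_fmt_num(v) for v in row)
            lines.append(f"{name} {vals}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_phylip(cls, text: str) -> "DistanceMatrix":
        rows = [ln for ln in text.splitlines() if ln.strip()]
        n = int(rows[0].split()[0])
        labels = []
        values = np.zeros((n, n))
        for i, ln in enumerate(rows[1 : n + 1]):
            parts = ln.split()
            labels.append(parts[0])
            values[i] = [float(v) for v in parts[1 : n + 1]]
        return cls(tuple(labels), values)


def _fmt_num(v) -> str:
    f = float(v)
    return str(int(f)) if f.is_integer() else f"{f:.6f}"


def distance_matrix(
    genomes: Sequence[tuple[str, Genome]], metric: Metric = "rank"
) -> DistanceMatrix:
    """Pairwise distance matrix over labelled genomes sharing a universe."""
    labels = [label for label, _ in genomes]
    if len(set(labels)) != len(labels):
        raise DuplicateLabelError("duplicate genome labels")
    if metric not in ("rank", "rank_indel"):
        raise ValueError(f"unknown metric {metric!r}")
    fn = rank_distance if metric == "rank" else rank_indel_distance
    k = len(genomes)
    values = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(i + 1, k):
            d = fn(genomes[i][1], genomes[j][1])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(tuple(labels), values)
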