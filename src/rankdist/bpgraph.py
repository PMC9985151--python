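"""Augmented breakpoint graph of two genomes over one marker universe.

The graph has one node per extremity of the *universe* (including
extremities absent from both genomes), a black edge per adjacency of the
first genome and a gray edge per adjacency of the second.  Every node has
at most one black and one gray edge, so components are paths and cycles;
a shared adjacency contributes a parallel black+gray pair, kept as a
2-cycle.  Path components are classified by the status of their endpoints:

==========  =====================================================
kind        endpoints
==========  =====================================================
proper      two free ends (also: isolated node null in both)
A_null      one free end, one node absent from A
B_null      one free end, one node absent from B
AA_null     two nodes absent from A
BB_null     two nodes absent from B
AB_null     one node absent from A, one absent from B
==========  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UniverseMismatchError
from .genome import Genome, MarkerUniverse

__all__ = [
    "BreakpointGraph",
    "Component",
    "ComponentStats",
    "build_bg",
    "classify_components",
    "stats",
    "bg_to_dot",
]

# endpoint statuses
FREE = "free"
A_NULL = "A_null"
B_NULL = "B_null"

PATH_KINDS = ("proper", "A_null", "B_null", "AA_null", "BB_null", "AB_null")


@dataclass(frozen=True)
class BreakpointGraph:
    universe: MarkerUniverse
    avec: tuple[int, ...]  # adjacency vector of A, index 0 unused
    bvec: tuple[int, ...]

    @property
    def black_edges(self) -> frozenset[tuple[int, int]]:
        return frozenset(
            (x, self.avec[x])
            for x in range(1, len(self.avec))
            if self.avec[x] not in (0, x) and x < self.avec[x]
        )

    @property
    def gray_edges(self) -> frozenset[tuple[int, int]]:
        return frozenset(
            (x, self.bvec[x])
            for x in range(1, len(self.bvec))
            if self.bvec[x] not in (0, x) and x < self.bvec[x]
        )


@dataclass(frozen=True)
class Component:
    """One path or cycle of the breakpoint graph.

    ``nodes`` is the traversal order: for a cycle it starts at the smallest
    node and its first edge (nodes[0]-nodes[1]) is black; for a path it runs
    endpoint to endpoint starting at the smaller endpoint.  ``score`` is
    (#A-null nodes) - (#B-null nodes), which is zero exactly for the kinds
    that decrement the distance (cycles, proper and AB-null paths).
    """

    nodes: tuple[int, ...]
    n_edges: int
    kind: str
    score: int
    endpoint_status: tuple[str, str] | None  # None for cycles

    @property
    def is_cycle(self) -> bool:
        return self.kind == "cycle"


@dataclass(frozen=True)
class ComponentStats:
    n: int
    c: int
    p: int
    p0: int
    pA: int
    pB: int
    pAA: int
    pBB: int
    pAB: int


def build_bg(A: Genome, B: Genome) -> BreakpointGraph:
    """Breakpoint graph of two genomes sharing a universe."""
    if A.universe.markers != B.universe.markers:
        raise UniverseMismatchError(
            "genomes are defined over different marker universes"
        )
    return BreakpointGraph(
        A.universe,
        tuple(A.adjacency_vector()),
        tuple(B.adjacency_vector()),
    )


def _classify_path(avec, bvec, nodes) -> tuple[str, tuple[str, str]]:
    """Kind and endpoint statuses of a path component."""
    if len(nodes) == 1:
        x = nodes[0]
        sa = FREE if avec[x] == x else A_NULL
        sb = FREE if bvec[x] == x else B_NULL
        if sa == FREE and sb == FREE:
            return "proper", (sa, sb)
        if sa == FREE:  # B-null node
            return "B_null", (sa, sb)
        if sb == FREE:  # A-null node
            return "A_null", (sa, sb)
        # null in both: proper by convention
        return "proper", (sa, sb)
    statuses = []
    for x in (nodes[0], nodes[-1]):
        has_black = avec[x] not in (0, x)
        if has_black:  # endpoint lacks a gray edge
            statuses.append(FREE if bvec[x] == x else B_NULL)
        else:
            statuses.append(FREE if avec[x] == x else A_NULL)
    s0, s1 = statuses
    kinds = {
        (FREE, FREE): "proper",
        (FREE, A_NULL): "A_null",
        (A_NULL, FREE): "A_null",
        (FREE, B_NULL): "B_null",
        (B_NULL, FREE): "B_null",
        (A_NULL, A_NULL): "AA_null",
        (B_NULL, B_NULL): "BB_null",
        (A_NULL, B_NULL): "AB_null",
        (B_NULL, A_NULL): "AB_null",
    }
    return kinds[(s0, s1)], (s0, s1)


def classify_components(bg: BreakpointGraph) -> list[Component]:
    """Partition all universe extremities into classified components."""
    avec, bvec = bg.avec, bg.bvec
    size = bg.universe.size
    seen = [False] * (size + 1)
    components: list[Component] = []

    def neighbours(x):
        out = []
        if avec[x] not in (0, x):
            out.append((avec[x], "black"))
        if bvec[x] not in (0, x):
            out.append((bvec[x], "gray"))
        return out

    for start in range(1, size + 1):
        if seen[start]:
            continue
        # collect the component
        comp = {start}
        stack = [start]
        seen[start] = True
        while stack:
            x = stack.pop()
            for y, _ in neighbours(x):
                if not seen[y]:
                    seen[y] = True
                    comp.add(y)
                    stack.append(y)
        # each endpoint of each edge contributes one neighbour entry, so a
        # shared adjacency (parallel black+gray pair) counts as two edges
        n_edges = sum(len(neighbours(x)) for x in comp) // 2
        is_cycle = n_edges == len(comp) and n_edges > 0
        if is_cycle:
            first = min(comp)
            order = [first, avec[first]]
            while True:
                prev, cur = order[-2], order[-1]
                nxt = bvec[cur] if avec[cur] == prev else avec[cur]
                # 2-cycle: black and gray connect the same two nodes
                if len(comp) == 2:
                    break
                if nxt == first:
                    break
                order.append(nxt)
            nodes = tuple(order)
            score = 0
            components.append(Component(nodes, n_edges, "cycle", score, None))
            continue
        # path: order from its smaller endpoint
        endpoints = sorted(x for x in comp if len(neighbours(x)) <= 1)
        startp = endpoints[0]
        order = [startp]
        prev = None
        cur = startp
        while len(order) < len(comp):
            nbrs = [y for y, _ in neighbours(cur) if y != prev]
            prev, cur = cur, nbrs[0]
            order.append(cur)
        nodes = tuple(order)
        kind, status = _classify_path(avec, bvec, nodes)
        score = sum(1 for s in status if s == A_NULL) - sum(
            1 for s in status if s == B_NULL
        )
        components.append(Component(nodes, n_edges, kind, score, status))
    components.sort(key=lambda c: min(c.nodes))
    return components


def stats(components: list[Component], universe: MarkerUniverse) -> ComponentStats:
    """Component counts feeding the two distance formulas."""
    counts = {k: 0 for k in PATH_KINDS}
    c = 0
    for comp in components:
        if comp.kind == "cycle":
            c += 1
        else:
            counts[comp.kind] += 1
    p = sum(counts.values())
    return ComponentStats(
        n=universe.n,
        c=c,
        p=p,
        p0=counts["proper"],
        pA=counts["A_null"],
        pB=counts["B_null"],
        pAA=counts["AA_null"],
        pBB=counts["BB_null"],
        pAB=counts["AB_null"],
    )


def bg_to_dot(bg: BreakpointGraph) -> str:
    """DOT export: black solid edges from A, gray dashed edges from B."""
    lines = ["graph BG {"]
    u = bg.universe
    for x in range(1, u.size + 1):
        in_a = bg.avec[x] != 0
        in_b = bg.bvec[x] != 0
        fill = "white" if (in_a and in_b) else "black"
        lines.append(
            f'  n{x} [label="{u.label(x)}", style=filled, fillcolor={fill}];'
        )
    for x, y in sorted(bg.black_edges):
        lines.append(f"  n{x} -- n{y} [color=black];")
    for x, y in sorted(bg.gray_edges):
        lines.append(f"  n{x} -- n{y} [color=gray, style=dashed];")
    lines.append("}")
    return "\n".join(lines)
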