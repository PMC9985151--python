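"""Weighted basic operations and optimal sorting scenarios.

Six operation kinds transform genomes:

* ``cut`` / ``join`` — remove / create one adjacency (weight 1);
* ``double_swap`` — replace two disjoint adjacencies by a different perfect
  matching on the same four extremities (weight 2);
* ``chrom_deletion`` / ``chrom_insertion`` — remove / add a whole
  chromosome or semi-chromosome, weight = number of extremities;
* ``extremity_substitution`` — replace one present extremity by an absent
  one, in place (weight 2); its products are relaxed genomes.

Every operation has a matrix form ``X`` with ``apply(op, A) == A + X`` and
``rank(X) == weight``.  :func:`sort_rank` builds a scenario of total weight
equal to the rank distance using all six kinds; :func:`sort_rank_indel`
uses only the first five and keeps every intermediate whole-marker, with
total weight equal to the rank-indel distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bpgraph import build_bg, classify_components, stats
from .distance import rank_distance_formula, rank_indel_from_stats, exact_rank
from .errors import (
    InvalidGenomeError,
    InvalidOperationError,
    NotApplicableError,
)
from .genome import (
    Chromosome,
    Genome,
    MarkerUniverse,
    chromosome_support,
    genome_to_chromosomes,
    make_universe,
)

__all__ = [
    "Operation",
    "Scenario",
    "operation_matrix",
    "is_applicable",
    "apply_op",
    "sort_rank",
    "sort_rank_indel",
    "block_substitution_weight",
]

Pair = tuple[int, int]


def _norm(pair) -> Pair:
    x, y = pair
    if x == y:
        raise InvalidOperationError(f"degenerate pair {pair}")
    return (x, y) if x < y else (y, x)


@dataclass(frozen=True)
class Operation:
    kind: str
    adjacency: Pair | None = None
    removed: tuple[Pair, Pair] | None = None
    added: tuple[Pair, Pair] | None = None
    segment: Chromosome | None = None
    old: int | None = None
    new: int | None = None
    attached: int | None = None

    # -- constructors -----------------------------------------------------
    @classmethod
    def cut(cls, pair) -> "Operation":
        return cls("cut", adjacency=_norm(pair))

    @classmethod
    def join(cls, pair) -> "Operation":
        return cls("join", adjacency=_norm(pair))

    @classmethod
    def double_swap(cls, removed, added) -> "Operation":
        rem = tuple(sorted(_norm(p) for p in removed))
        add = tuple(sorted(_norm(p) for p in added))
        if len(rem) != 2 or len(add) != 2:
            raise InvalidOperationError("double swap needs two pairs each way")
        ext_rem = {x for p in rem for x in p}
        ext_add = {x for p in add for x in p}
        if len(ext_rem) != 4 or ext_rem != ext_add:
            raise InvalidOperationError(
                "double swap must rematch the same four extremities"
            )
        if rem == add:
            raise InvalidOperationError("double swap must change the matching")
        return cls("double_swap", removed=rem, added=add)

    @classmethod
    def deletion(cls, chrom: Chromosome) -> "Operation":
        return cls("chrom_deletion", segment=chrom)

    @classmethod
    def insertion(cls, chrom: Chromosome) -> "Operation":
        return cls("chrom_insertion", segment=chrom)

    @classmethod
    def substitution(cls, old: int, new: int, attached: int | None = None) -> "Operation":
        if old == new:
            raise InvalidOperationError("substitution must change the extremity")
        if attached in (old, new):
            raise InvalidOperationError("substitution context clashes")
        return cls("extremity_substitution", old=old, new=new, attached=attached)

    # -- weight -----------------------------------------------------------
    @property
    def weight(self) -> int:
        if self.kind in ("cut", "join"):
            return 1
        if self.kind in ("double_swap", "extremity_substitution"):
            return 2
        # indel: number of extremities inserted/deleted
        chrom = self.segment
        w = 2 * len(chrom.content)
        w -= 0 if chrom.left_complete else 1
        w -= 0 if chrom.right_complete else 1
        return w

    def describe(self, universe: MarkerUniverse) -> str:
        lab = universe.label
        if self.kind in ("cut", "join"):
            x, y = self.adjacency
            return f"{{{lab(x)},{lab(y)}}}"
        if self.kind == "double_swap":
            rem = " ".join(f"{{{lab(x)},{lab(y)}}}" for x, y in self.removed)
            add = " ".join(f"{{{lab(x)},{lab(y)}}}" for x, y in self.added)
            return f"{rem} -> {add}"
        if self.kind == "extremity_substitution":
            return f"{lab(self.old)} -> {lab(self.new)}"
        parts = []
        for name, sign in self.segment.content:
            parts.append(name if sign > 0 else f"-{name}")
        deco = {"linear": "$", "circular": ")", "semi": "!"}[self.segment.kind]
        return " ".join(parts) + " " + deco


def operation_matrix(op: Operation, universe: MarkerUniverse) -> np.ndarray:
    """Matrix ``X`` with ``apply(op, A) = A + X`` (0-based array indices)."""
    size = universe.size
    X = np.zeros((size, size), dtype=np.int64)

    def adj(x, y, val):
        X[x - 1, y - 1] += val
        X[y - 1, x - 1] += val

    def diag(x, val):
        X[x - 1, x - 1] += val

    if op.kind == "cut":
        x, y = op.adjacency
        adj(x, y, -1)
        diag(x, +1)
        diag(y, +1)
    elif op.kind == "join":
        x, y = op.adjacency
        adj(x, y, +1)
        diag(x, -1)
        diag(y, -1)
    elif op.kind == "double_swap":
        for x, y in op.removed:
            adj(x, y, -1)
        for x, y in op.added:
            adj(x, y, +1)
    elif op.kind in ("chrom_deletion", "chrom_insertion"):
        sign = -1 if op.kind == "chrom_deletion" else +1
        present, adjacencies = chromosome_support(op.segment, universe)
        matched = {x for p in adjacencies for x in p}
        for x, y in adjacencies:
            adj(x, y, sign)
        for x in present - matched:
            diag(x, sign)
    elif op.kind == "extremity_substitution":
        if op.attached is None:
            diag(op.old, -1)
            diag(op.new, +1)
        else:
            adj(op.old, op.attached, -1)
            adj(op.new, op.attached, +1)
    else:
        raise InvalidOperationError(f"unknown operation kind {op.kind!r}")
    return X


def is_applicable(genome: Genome, op: Operation) -> bool:
    """Symbolic applicability test (equivalent to the matrix-level one)."""
    vec = genome.adjacency_vector()

    def status(x):  # partner, x (free) or 0 (absent)
        return vec[x]

    if op.kind == "cut":
        return op.adjacency in genome.adjacencies
    if op.kind == "join":
        x, y = op.adjacency
        return status(x) == x and status(y) == y
    if op.kind == "double_swap":
        return all(p in genome.adjacencies for p in op.removed)
    if op.kind == "chrom_deletion":
        present, adjacencies = chromosome_support(op.segment, genome.universe)
        matched = {x for p in adjacencies for x in p}
        for x, y in adjacencies:
            if status(x) != y:
                return False
        for x in present - matched:
            if status(x) != x:
                return False
        return True
    if op.kind == "chrom_insertion":
        present, _ = chromosome_support(op.segment, genome.universe)
        return all(status(x) == 0 for x in present)
    if op.kind == "extremity_substitution":
        if status(op.old) == 0 or status(op.new) != 0:
            return False
        expected = op.old if op.attached is None else op.attached
        return status(op.old) == expected
    raise InvalidOperationError(f"unknown operation kind {op.kind!r}")


def apply_op(genome: Genome, op: Operation) -> Genome:
    """Apply an operation; equals the matrix-sum route ``A + X``."""
    if not is_applicable(genome, op):
        raise NotApplicableError(
            f"{op.kind} {op.describe(genome.universe)} not applicable"
        )
    present = set(genome.present)
    adjacencies = set(genome.adjacencies)
    relaxed = genome.relaxed
    if op.kind == "cut":
        adjacencies.discard(op.adjacency)
    elif op.kind == "join":
        adjacencies.add(op.adjacency)
    elif op.kind == "double_swap":
        for p in op.removed:
            adjacencies.discard(p)
        for p in op.added:
            adjacencies.add(p)
    elif op.kind == "chrom_deletion":
        seg_present, seg_adj = chromosome_support(op.segment, genome.universe)
        present -= seg_present
        adjacencies -= seg_adj
    elif op.kind == "chrom_insertion":
        seg_present, seg_adj = chromosome_support(op.segment, genome.universe)
        present |= seg_present
        adjacencies |= seg_adj
    else:  # extremity_substitution
        present.discard(op.old)
        present.add(op.new)
        if op.attached is not None:
            adjacencies.discard(_norm((op.old, op.attached)))
            adjacencies.add(_norm((op.new, op.attached)))
        relaxed = True
    return Genome(
        genome.universe, frozenset(present), frozenset(adjacencies), relaxed
    )


@dataclass(frozen=True)
class Scenario:
    """A sequence of operations, each applicable to its running genome."""

    source: Genome
    steps: tuple[Operation, ...]

    @property
    def total_weight(self) -> int:
        return sum(op.weight for op in self.steps)

    def replay(self) -> Genome:
        """Apply all steps in order; raises if any step is not applicable."""
        cur = self.source
        for op in self.steps:
            cur = apply_op(cur, op)
        return cur

    def intermediates(self):
        """Yield every genome along the scenario, source first."""
        cur = self.source
        yield cur
        for op in self.steps:
            cur = apply_op(cur, op)
            yield cur

    def to_tsv(self, source_label: str = "A", target_label: str = "B") -> str:
        u = self.source.universe
        lines = [
            f"# scenario\t{source_label}\t{target_label}"
            f"\ttotal_weight={self.total_weight}"
        ]
        for op in self.steps:
            lines.append(f"{op.kind}\t{op.describe(u)}\t{op.weight}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# sorting
# ---------------------------------------------------------------------------


def _close_cycle(seq) -> list[Operation]:
    """Swaps turning current edges (seq[2i],seq[2i+1]) into the targets
    (seq[2i+1],seq[2i+2]) on a cyclic alternating sequence; the last link
    created coincides with the final target edge."""
    j = len(seq) // 2
    ops = []
    link = (seq[0], seq[1])
    for i in range(1, j):
        removed = (link, (seq[2 * i], seq[2 * i + 1]))
        added = ((seq[2 * i - 1], seq[2 * i]), (seq[0], seq[2 * i + 1]))
        ops.append(Operation.double_swap(removed, added))
        link = (seq[0], seq[2 * i + 1])
    return ops


def _chain_bb(seq) -> list[Operation]:
    """Swaps on a BB-null path: create its gray edges while chaining the
    two to-be-deleted endpoints into one adjacency (the surviving link)."""
    g = (len(seq) - 2) // 2
    ops = []
    link = (seq[0], seq[1])
    for i in range(1, g + 1):
        removed = (link, (seq[2 * i], seq[2 * i + 1]))
        added = ((seq[2 * i - 1], seq[2 * i]), (seq[0], seq[2 * i + 1]))
        ops.append(Operation.double_swap(removed, added))
        link = (seq[0], seq[2 * i + 1])
    return ops


def _weave_aa(seq) -> list[Operation]:
    """Swaps on an AA-null path: consume the pre-inserted link between the
    two new endpoints while creating the path's gray edges."""
    b = (len(seq) - 2) // 2
    ops = []
    link = (seq[0], seq[-1])
    for i in range(1, b + 1):
        removed = (link, (seq[2 * i - 1], seq[2 * i]))
        added = ((seq[2 * i - 2], seq[2 * i - 1]), (seq[2 * i], seq[-1]))
        ops.append(Operation.double_swap(removed, added))
        link = (seq[2 * i], seq[-1])
    return ops


def _sort(A: Genome, B: Genome, mode: str) -> Scenario:
    bg = build_bg(A, B)
    comps = classify_components(bg)
    avec, bvec = bg.avec, bg.bvec
    universe = A.universe

    cuts: list[Operation] = []
    chain_ops: list[Operation] = []
    sub_ops: list[Operation] = []
    pre_links: list[Pair] = []
    weave_ops: list[Operation] = []
    joins: list[Operation] = []
    subbed_old: set[int] = set()
    subbed_new: set[int] = set()

    for comp in comps:
        nodes = comp.nodes
        if comp.kind == "cycle":
            if comp.n_edges > 2:
                chain_ops.extend(_close_cycle(nodes))
            continue
        if comp.kind in ("proper", "A_null", "B_null") or (
            comp.kind == "AB_null" and mode == "indel"
        ):
            for x, y in zip(nodes, nodes[1:]):
                if avec[x] == y:
                    cuts.append(Operation.cut((x, y)))
                else:
                    joins.append(Operation.join((x, y)))
        elif comp.kind == "BB_null":
            chain_ops.extend(_chain_bb(nodes))
        elif comp.kind == "AA_null":
            pre_links.append(_norm((nodes[0], nodes[-1])))
            weave_ops.extend(_weave_aa(nodes))
        else:  # AB_null in rank mode: substitution + cycle closure
            seq = nodes if avec[nodes[0]] == 0 else nodes[::-1]
            u, v = seq[0], seq[-1]
            sub_ops.append(Operation.substitution(v, u, attached=avec[v]))
            subbed_old.add(v)
            subbed_new.add(u)
            pseudo = (seq[-2], seq[0]) + tuple(seq[1:-2])
            sub_ops.extend(_close_cycle(pseudo))

    size = universe.size
    del_exts = frozenset(
        x
        for x in range(1, size + 1)
        if avec[x] != 0 and bvec[x] == 0 and x not in subbed_old
    )
    ins_exts = frozenset(
        x
        for x in range(1, size + 1)
        if avec[x] == 0 and bvec[x] != 0 and x not in subbed_new
    )

    steps: list[Operation] = []
    cur = A

    def emit(ops):
        nonlocal cur
        for op in ops:
            cur = apply_op(cur, op)
            steps.append(op)

    emit(cuts)
    emit(chain_ops)
    emit(sub_ops)

    # deletion phase: to-delete extremities now pair only with each other
    if del_exts:
        induced_adj = set()
        for x, y in cur.adjacencies:
            if x in del_exts or y in del_exts:
                if not (x in del_exts and y in del_exts):
                    raise AssertionError(
                        "to-delete extremity still attached to kept material"
                    )
                induced_adj.add((x, y))
        shard = Genome(universe, del_exts, frozenset(induced_adj), relaxed=True)
        for chrom in genome_to_chromosomes(shard):
            if mode == "indel" and chrom.kind == "semi":
                raise AssertionError("semi-chromosome deletion in indel mode")
            emit([Operation.deletion(chrom)])

    # insertion phase: new material enters pre-linked where needed
    if ins_exts:
        shard = Genome(universe, ins_exts, frozenset(pre_links), relaxed=True)
        for chrom in genome_to_chromosomes(shard):
            if mode == "indel" and chrom.kind == "semi":
                raise AssertionError("semi-chromosome insertion in indel mode")
            emit([Operation.insertion(chrom)])

    emit(weave_ops)
    emit(joins)

    if cur != B:
        raise AssertionError("sorting scenario did not reach the target")
    scenario = Scenario(A, tuple(steps))
    st = stats(comps, universe)
    expected = (
        rank_distance_formula(st)
        if mode == "rank"
        else rank_indel_from_stats(st)
    )
    if scenario.total_weight != expected:
        raise AssertionError(
            f"scenario weight {scenario.total_weight} != distance {expected}"
        )
    return scenario


def sort_rank(A: Genome, B: Genome) -> Scenario:
    """Optimal scenario from A to B under the rank distance (six kinds)."""
    return _sort(A, B, "rank")


def sort_rank_indel(A: Genome, B: Genome) -> Scenario:
    """Optimal whole-marker scenario from A to B (five kinds, no
    substitutions); total weight equals the rank-indel distance."""
    if not A.whole_marker or not B.whole_marker:
        raise InvalidGenomeError(
            "rank-indel sorting requires whole-marker genomes"
        )
    return _sort(A, B, "indel")


def block_substitution_weight(p: int, q: int) -> int:
    """Weight of substituting a block of ``p`` markers by ``q`` new ones,
    measured as the rank of the deletion matrix of a p-marker chromosome
    plus the rank of the insertion matrix of a q-marker chromosome."""
    names = [f"s{i}" for i in range(p + q)]
    scratch = make_universe(names)
    out = Chromosome.linear([(n, 1) for n in names[:p]])
    into = Chromosome.linear([(n, 1) for n in names[p:]])
    w_del = exact_rank(operation_matrix(Operation.deletion(out), scratch))
    w_ins = exact_rank(operation_matrix(Operation.insertion(into), scratch))
    return w_del + w_ins
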