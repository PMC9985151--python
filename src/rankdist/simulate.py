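"""Simulation of genomes evolving along a random tree.

A random binary tree is generated by a Yule-type splitting process with
exponential branch lengths.  A root genome with a configurable number of
genes spread over linear chromosomes evolves along each edge: the number
of DCJ events is Poisson with mean equal to the branch length, and the
numbers of segmental insertions and deletions are Poisson with mean equal
to the branch length times the respective rate.  Segment lengths follow a
truncated Zipf law.  Inserted markers receive globally fresh names, and
duplications are unsupported (rate fixed at 0), so no marker is ever
repeated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, UnsupportedError
from .genome import Chromosome, Genome, genome_from_chromosomes, make_universe
from .phylo import PhyloTree

__all__ = ["SimulationParams", "random_tree", "evolve"]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the branch-wise evolution model (defaults: 20 chromosomes,
    5000 genes, insertion rate 0.2, deletion rate 0.4, Zipf exponent 3.5,
    duplication rate pinned to 0)."""

    n_chromosomes: int = 20
    n_genes: int = 5000
    insertion_rate: float = 0.2
    deletion_rate: float = 0.4
    duplication_rate: float = 0.0
    indel_zipf: float = 3.5
    indel_max: int = 50
    seed: int | None = None

    def __post_init__(self):
        if self.duplication_rate != 0:
            raise UnsupportedError(
                "duplications are not supported (duplication_rate must be 0)"
            )
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ParameterError("need at least one gene and one chromosome")
        if self.insertion_rate < 0 or self.deletion_rate < 0:
            raise ParameterError("rates must be non-negative")
        if self.indel_zipf <= 1:
            raise ParameterError("Zipf exponent must exceed 1")


def random_tree(
    n_taxa: int, seed, mean_branch_length: float = 1.0
) -> PhyloTree:
    """Random binary tree via Yule splitting; exponential branch lengths."""
    if n_taxa < 3:
        raise ParameterError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    tree = PhyloTree()
    tree.root = 0
    tree.add_edge(0, 1, rng.exponential(mean_branch_length))
    tree.add_edge(0, 2, rng.exponential(mean_branch_length))
    tips = [1, 2]
    next_id = 3
    while len(tips) < n_taxa:
        k = int(rng.integers(len(tips)))
        tip = tips.pop(k)
        for _ in range(2):
            tree.add_edge(tip, next_id, rng.exponential(mean_branch_length))
            tips.append(next_id)
            next_id += 1
    # decouple labels from creation order so two independently drawn trees
    # are topologically unrelated as labelled trees
    order = rng.permutation(len(tips))
    for i, k in enumerate(order, start=1):
        tree.leaf_labels[sorted(tips)[k]] = f"T{i:02d}"
    return tree


# -- internal chromosome-list state -----------------------------------------
# a genome in flight is a list of (circular?, [(marker, sign), ...])

State = list[tuple[bool, list[tuple[str, int]]]]


def _zipf_truncated(rng, a: float, cap: int) -> int:
    while True:
        k = int(rng.zipf(a))
        if k <= cap:
            return k


def _adjacency_form(state: State):
    """Adjacencies and telomeres as (marker, 'h'/'t') extremity tokens."""
    adjacencies = []
    telomeres = []

    def left(gene):
        name, sign = gene
        return (name, "t") if sign > 0 else (name, "h")

    def right(gene):
        name, sign = gene
        return (name, "h") if sign > 0 else (name, "t")

    for circular, genes in state:
        for g1, g2 in zip(genes, genes[1:]):
            adjacencies.append((right(g1), left(g2)))
        if circular:
            adjacencies.append((right(genes[-1]), left(genes[0])))
        else:
            telomeres.append(left(genes[0]))
            telomeres.append(right(genes[-1]))
    return adjacencies, telomeres


def _rebuild(adjacencies, telomeres, markers) -> State:
    """Chromosome list from an adjacency/telomere description."""
    nbr: dict = {}
    for x, y in adjacencies:
        nbr[x] = y
        nbr[y] = x

    def partner(ext):
        name, end = ext
        return (name, "t" if end == "h" else "h")

    unseen = set(markers)
    state: State = []
    telomere_set = set(telomeres)

    def walk(start_ext):
        genes = []
        ext = start_ext
        while True:
            name, end = ext
            genes.append((name, 1 if end == "t" else -1))
            unseen.discard(name)
            other = partner(ext)
            nxt = nbr.get(other)
            if nxt is None:
                return genes, other
            ext = nxt
            if ext[0] not in unseen:  # circular closure
                return genes, None

    for tel in sorted(telomere_set):
        if tel[0] not in unseen:
            continue
        genes, _end = walk(tel)
        state.append((False, genes))
    while unseen:
        name = sorted(unseen)[0]
        genes, end = walk((name, "t"))
        state.append((True, genes))
    return state


def _dcj_step(state: State, rng) -> State:
    adjacencies, telomeres = _adjacency_form(state)
    sites = [("adj", a) for a in adjacencies] + [("tel", t) for t in telomeres]
    if len(sites) < 2:
        return state
    i, j = rng.choice(len(sites), size=2, replace=False)
    (k1, s1), (k2, s2) = sites[int(i)], sites[int(j)]
    adjacency_set = set(adjacencies)
    telomere_set = set(telomeres)
    if k1 == "adj":
        adjacency_set.discard(s1)
    else:
        telomere_set.discard(s1)
    if k2 == "adj":
        adjacency_set.discard(s2)
    else:
        telomere_set.discard(s2)
    ends1 = list(s1) if k1 == "adj" else [s1]
    ends2 = list(s2) if k2 == "adj" else [s2]
    if len(ends1) == 2 and len(ends2) == 2:
        a, b = ends1
        c, d = ends2
        if rng.random() < 0.5:
            adjacency_set.update([(a, c), (b, d)])
        else:
            adjacency_set.update([(a, d), (b, c)])
    elif len(ends1) == 1 and len(ends2) == 1:
        adjacency_set.add((ends1[0], ends2[0]))
    else:
        (a, b), (c,) = (ends1, ends2) if len(ends1) == 2 else (ends2, ends1)
        if rng.random() < 0.5:
            adjacency_set.add((a, c))
            telomere_set.add(b)
        else:
            adjacency_set.add((b, c))
            telomere_set.add(a)
    markers = [g for _, genes in state for g, _ in genes]
    return _rebuild(adjacency_set, telomere_set, markers)


def _deletion_step(state: State, rng, params) -> State:
    sizes = [len(genes) for _, genes in state]
    if not sizes or sum(sizes) <= 1:
        return state
    k = _zipf_truncated(rng, params.indel_zipf, params.indel_max)
    ci = int(rng.choice(len(state), p=np.asarray(sizes) / sum(sizes)))
    circular, genes = state[ci]
    k = min(k, len(genes))
    if k == len(genes):
        return state[:ci] + state[ci + 1 :]
    start = int(rng.integers(len(genes)))
    if circular:
        keep = [genes[(start + k + t) % len(genes)] for t in range(len(genes) - k)]
        new = (True, keep)
    else:
        start = int(rng.integers(len(genes) - k + 1))
        new = (False, genes[:start] + genes[start + k :])
    return state[:ci] + [new] + state[ci + 1 :]


def _insertion_step(state: State, rng, params, fresh) -> State:
    k = _zipf_truncated(rng, params.indel_zipf, params.indel_max)
    segment = [(next(fresh), int(rng.choice([1, -1]))) for _ in range(k)]
    slots = []
    for ci, (circular, genes) in enumerate(state):
        n_pos = len(genes) if circular else len(genes) + 1
        slots.extend((ci, p) for p in range(n_pos))
    slots.append((-1, 0))  # new linear chromosome
    ci, pos = slots[int(rng.integers(len(slots)))]
    if ci == -1:
        return state + [(False, segment)]
    circular, genes = state[ci]
    new = (circular, genes[:pos] + segment + genes[pos:])
    return state[:ci] + [new] + state[ci + 1 :]


def _root_state(params, rng, fresh) -> State:
    genes = [(next(fresh), int(rng.choice([1, -1]))) for _ in range(params.n_genes)]
    order = rng.permutation(params.n_genes)
    genes = [genes[i] for i in order]
    n_chrom = min(params.n_chromosomes, params.n_genes)
    bounds = np.linspace(0, len(genes), n_chrom + 1).astype(int)
    return [
        (False, genes[bounds[i] : bounds[i + 1]])
        for i in range(n_chrom)
        if bounds[i] < bounds[i + 1]
    ]


def evolve(
    tree: PhyloTree, params: SimulationParams, seed=None
) -> dict[str, Genome]:
    """Evolve genomes down the tree; returns leaf label -> Genome over the
    union universe of all leaf markers."""
    if tree.root is None:
        raise ParameterError("tree must be rooted for simulation")
    rng = np.random.default_rng(params.seed if seed is None else seed)

    counter = iter(range(1, 10**9))
    fresh = (f"g{i:06d}" for i in counter)

    root = _root_state(params, rng, fresh)
    leaf_states: dict[str, State] = {}

    def copy_state(state: State) -> State:
        return [(c, list(genes)) for c, genes in state]

    def visit(node, parent, state):
        for child, length in sorted(tree.adj[node].items()):
            if child == parent:
                continue
            child_state = copy_state(state)
            n_dcj = rng.poisson(length)
            n_ins = rng.poisson(length * params.insertion_rate)
            n_del = rng.poisson(length * params.deletion_rate)
            events = ["dcj"] * n_dcj + ["ins"] * n_ins + ["del"] * n_del
            rng.shuffle(events)
            for ev in events:
                if ev == "dcj":
                    child_state = _dcj_step(child_state, rng)
                elif ev == "ins":
                    child_state = _insertion_step(child_state, rng, params, fresh)
                else:
                    child_state = _deletion_step(child_state, rng, params)
            if child in tree.leaf_labels:
                leaf_states[tree.leaf_labels[child]] = child_state
            else:
                visit(child, node, child_state)

    visit(tree.root, None, root)

    marker_union = sorted(
        {g for state in leaf_states.values() for _, genes in state for g, _ in genes}
    )
    universe = make_universe(marker_union)
    genomes = {}
    for label, state in leaf_states.items():
        chroms = [
            Chromosome("circular" if circ else "linear", tuple(genes))
            for circ, genes in state
            if genes
        ]
        genomes[label] = genome_from_chromosomes(universe, chroms)
    return genomes
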