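"""Markers, extremities, adjacencies, genomes and genomic matrices.

Extremity indexing is fixed package-wide: the i-th marker of a universe
(1-based) has tail ``2i - 1`` and head ``2i``.  A genome is a subset of
extremities plus a partial matching on them (the adjacencies); it embeds
into a ``2n x 2n`` symmetric binary matrix whose columns map each extremity
to its adjacency partner, to itself (free end) or to zero (absent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DimensionError,
    DuplicateMarkerError,
    InvalidGenomeError,
)

__all__ = [
    "MarkerUniverse",
    "Genome",
    "Chromosome",
    "make_universe",
    "genome_from_chromosomes",
    "genome_to_chromosomes",
    "chromosome_support",
    "to_matrix",
    "is_genomic_matrix",
]

FORWARD = 1
REVERSE = -1


@dataclass(frozen=True)
class MarkerUniverse:
    """Ordered set of marker names with the fixed extremity indexing."""

    markers: tuple[str, ...]
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        markers = tuple(self.markers)
        object.__setattr__(self, "markers", markers)
        index = {}
        for i, name in enumerate(markers, start=1):
            if name in index:
                raise DuplicateMarkerError(f"duplicate marker name {name!r}")
            index[name] = i
        object.__setattr__(self, "_index", index)

    @property
    def n(self) -> int:
        """Number of markers."""
        return len(self.markers)

    @property
    def size(self) -> int:
        """Number of extremities (2n)."""
        return 2 * len(self.markers)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def tail(self, name: str) -> int:
        return 2 * self._index[name] - 1

    def head(self, name: str) -> int:
        return 2 * self._index[name]

    def extremities(self, name: str) -> tuple[int, int]:
        """(tail, head) indices of a marker."""
        i = self._index[name]
        return 2 * i - 1, 2 * i

    def marker_of(self, ext: int) -> str:
        return self.markers[(ext - 1) // 2]

    @staticmethod
    def is_head(ext: int) -> bool:
        return ext % 2 == 0

    @staticmethod
    def partner(ext: int) -> int:
        """The other extremity of the same marker."""
        return ext - 1 if ext % 2 == 0 else ext + 1

    def label(self, ext: int) -> str:
        suffix = "h" if self.is_head(ext) else "t"
        return f"{self.marker_of(ext)}{suffix}"


def make_universe(marker_names: Iterable[str]) -> MarkerUniverse:
    """Build a universe; duplicate names raise :class:`DuplicateMarkerError`."""
    return MarkerUniverse(tuple(marker_names))


def _norm_pair(x: int, y: int) -> tuple[int, int]:
    return (x, y) if x < y else (y, x)


@dataclass(frozen=True, eq=False)
class Genome:
    """Immutable genome: present extremities plus a partial matching.

    ``relaxed=False`` (the default, "whole marker" mode) additionally
    requires that the tail of a marker is present iff its head is.
    Equality and hashing ignore the ``relaxed`` flag; two genomes are equal
    iff they have the same universe, extremity set and adjacency set.
    """

    universe: MarkerUniverse
    present: frozenset[int]
    adjacencies: frozenset[tuple[int, int]]
    relaxed: bool = False

    def __post_init__(self):
        present = frozenset(self.present)
        object.__setattr__(self, "present", present)
        size = self.universe.size
        for x in present:
            if not (1 <= x <= size):
                raise InvalidGenomeError(f"extremity {x} outside 1..{size}")
        seen: set[int] = set()
        adjs = set()
        for pair in self.adjacencies:
            x, y = pair
            if x == y:
                raise InvalidGenomeError(f"self-adjacency on extremity {x}")
            if x not in present or y not in present:
                raise InvalidGenomeError(
                    f"adjacency {pair} uses an absent extremity"
                )
            if x in seen or y in seen:
                raise InvalidGenomeError(
                    f"extremity in more than one adjacency: {pair}"
                )
            seen.update(pair)
            adjs.add(_norm_pair(x, y))
        object.__setattr__(self, "adjacencies", frozenset(adjs))
        if not self.relaxed:
            for x in present:
                if MarkerUniverse.partner(x) not in present:
                    raise InvalidGenomeError(
                        f"extremity {self.universe.label(x)} present without "
                        "its partner (use relaxed=True for semi-genomes)"
                    )

    # -- identity ---------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return (
            self.universe.markers == other.universe.markers
            and self.present == other.present
            and self.adjacencies == other.adjacencies
        )

    def __hash__(self) -> int:
        return hash((self.universe.markers, self.present, self.adjacencies))

    # -- views ------------------------------------------------------------
    @property
    def whole_marker(self) -> bool:
        """True iff every marker has both or neither extremity present."""
        return all(
            MarkerUniverse.partner(x) in self.present for x in self.present
        )

    @property
    def free_ends(self) -> frozenset[int]:
        matched = {x for pair in self.adjacencies for x in pair}
        return frozenset(self.present - matched)

    def partner_in_adjacency(self, ext: int) -> int | None:
        for x, y in self.adjacencies:
            if x == ext:
                return y
            if y == ext:
                return x
        return None

    def adjacency_vector(self) -> list[int]:
        """List ``v`` of length 2n+1 (index 0 unused): ``v[i]`` is the
        adjacency partner of ``i``, ``i`` itself for a free end, 0 if absent."""
        v = [0] * (self.universe.size + 1)
        for x in self.present:
            v[x] = x
        for x, y in self.adjacencies:
            v[x] = y
            v[y] = x
        return v

    def markers_present(self) -> frozenset[str]:
        return frozenset(self.universe.marker_of(x) for x in self.present)

    def with_relaxed(self, relaxed: bool) -> "Genome":
        return Genome(self.universe, self.present, self.adjacencies, relaxed)


@dataclass(frozen=True)
class Chromosome:
    """An ordered run of (marker, orientation) pairs.

    ``kind`` is ``linear`` (two free ends), ``circular`` (no free ends) or
    ``semi`` (at least one end stops at an unpaired extremity, i.e. the
    terminal marker is present through a single extremity).  For a forward
    marker the tail is its left extremity and the head its right one.
    """

    kind: str
    content: tuple[tuple[str, int], ...]
    left_complete: bool = True
    right_complete: bool = True

    def __post_init__(self):
        if self.kind not in ("linear", "circular", "semi"):
            raise InvalidGenomeError(f"unknown chromosome kind {self.kind!r}")
        if self.kind != "semi" and not (self.left_complete and self.right_complete):
            raise InvalidGenomeError("incomplete ends require kind='semi'")
        if self.kind == "semi" and self.left_complete and self.right_complete:
            raise InvalidGenomeError("semi-chromosome needs an incomplete end")
        if not self.content:
            raise InvalidGenomeError("empty chromosome")
        object.__setattr__(self, "content", tuple(self.content))

    @classmethod
    def linear(cls, signed_markers: Sequence[tuple[str, int]]) -> "Chromosome":
        return cls("linear", tuple(signed_markers))

    @classmethod
    def circular(cls, signed_markers: Sequence[tuple[str, int]]) -> "Chromosome":
        return cls("circular", tuple(signed_markers))

    @property
    def n_markers(self) -> int:
        return len(self.content)


def _terminal_extremities(chrom: Chromosome, universe: MarkerUniverse):
    """(left extremity, right extremity) of the chromosome run."""
    (m0, s0) = chrom.content[0]
    (m1, s1) = chrom.content[-1]
    t0, h0 = universe.extremities(m0)
    t1, h1 = universe.extremities(m1)
    left = t0 if s0 == FORWARD else h0
    right = h1 if s1 == FORWARD else t1
    return left, right


def chromosome_support(
    chrom: Chromosome, universe: MarkerUniverse
) -> tuple[frozenset[int], frozenset[tuple[int, int]]]:
    """Extremity set and adjacency set contributed by one chromosome."""
    present: set[int] = set()
    for name, _ in chrom.content:
        if name not in universe:
            raise InvalidGenomeError(f"marker {name!r} not in universe")
        present.update(universe.extremities(name))
    left, right = _terminal_extremities(chrom, universe)
    if not chrom.left_complete:
        present.discard(left)
    if not chrom.right_complete:
        present.discard(right)
    adjs: set[tuple[int, int]] = set()
    for (ma, sa), (mb, sb) in zip(chrom.content, chrom.content[1:]):
        ta, ha = universe.extremities(ma)
        tb, hb = universe.extremities(mb)
        x = ha if sa == FORWARD else ta
        y = tb if sb == FORWARD else hb
        adjs.add(_norm_pair(x, y))
    if chrom.kind == "circular":
        if len(chrom.content) == 1:
            adjs.add(_norm_pair(left, right))
        else:
            adjs.add(_norm_pair(right, left))
    return frozenset(present), frozenset(adjs)


def genome_from_chromosomes(
    universe: MarkerUniverse,
    chromosomes: Iterable[Chromosome],
    relaxed: bool = False,
) -> Genome:
    """Assemble a genome from chromosomes; repeated markers are an error."""
    present: set[int] = set()
    adjacencies: set[tuple[int, int]] = set()
    seen_markers: set[str] = set()
    any_semi = False
    for chrom in chromosomes:
        for name, _ in chrom.content:
            if name in seen_markers:
                raise DuplicateMarkerError(
                    f"marker {name!r} occurs in more than one place"
                )
            seen_markers.add(name)
        p, a = chromosome_support(chrom, universe)
        present.update(p)
        adjacencies.update(a)
        any_semi = any_semi or chrom.kind == "semi"
    return Genome(
        universe,
        frozenset(present),
        frozenset(adjacencies),
        relaxed=relaxed or any_semi,
    )


def genome_to_chromosomes(genome: Genome) -> list[Chromosome]:
    """Decompose a genome into chromosomes.

    Traversal alternates marker edges (tail-head of one marker, when both
    extremities are present) with adjacency edges.  Deterministic: each
    chromosome starts at its smallest terminal extremity (smallest extremity
    overall for circular chromosomes) and chromosomes are listed by their
    starting extremity.
    """
    universe = genome.universe
    partner_adj = {}
    for x, y in genome.adjacencies:
        partner_adj[x] = y
        partner_adj[y] = x

    def marker_partner(x: int) -> int | None:
        p = MarkerUniverse.partner(x)
        return p if p in genome.present else None

    unvisited = set(genome.present)
    chromosomes: list[tuple[int, Chromosome]] = []
    # Path chromosomes: start at extremities missing a marker edge or an
    # adjacency edge; cycles are whatever remains.
    ends = sorted(
        x
        for x in unvisited
        if marker_partner(x) is None or x not in partner_adj
    )
    for start in ends:
        if start not in unvisited:
            continue
        seq = _walk(start, unvisited, partner_adj, marker_partner)
        chromosomes.append((start, _run_to_chromosome(seq, genome, False)))
    while unvisited:
        start = min(unvisited)
        seq = _walk(start, unvisited, partner_adj, marker_partner)
        chromosomes.append((start, _run_to_chromosome(seq, genome, True)))
    chromosomes.sort(key=lambda item: item[0])
    return [c for _, c in chromosomes]


def _walk(start, unvisited, partner_adj, marker_partner):
    """Walk a component from ``start`` alternating marker/adjacency edges."""
    seq = [start]
    unvisited.discard(start)
    # Decide the first edge type: prefer the marker edge so that linear
    # chromosomes are traversed marker by marker from their first extremity.
    use_marker = marker_partner(start) is not None
    cur = start
    while True:
        nxt = marker_partner(cur) if use_marker else partner_adj.get(cur)
        if nxt is None or nxt not in unvisited:
            return seq
        seq.append(nxt)
        unvisited.discard(nxt)
        cur = nxt
        use_marker = not use_marker


def _run_to_chromosome(seq: list[int], genome: Genome, circular: bool) -> Chromosome:
    universe = genome.universe
    content: list[tuple[str, int]] = []
    left_complete = True
    right_complete = True
    i = 0
    while i < len(seq):
        x = seq[i]
        name = universe.marker_of(x)
        if i + 1 < len(seq) and seq[i + 1] == MarkerUniverse.partner(x):
            # whole marker traversed tail->head (forward) or head->tail
            sign = REVERSE if MarkerUniverse.is_head(x) else FORWARD
            content.append((name, sign))
            i += 2
        else:
            # lone extremity: half marker terminating the run
            head = MarkerUniverse.is_head(x)
            if i == 0 and len(seq) > 1:
                # present extremity is the marker's right-facing end
                sign = FORWARD if head else REVERSE
                left_complete = False
            elif i == len(seq) - 1 and len(seq) > 1:
                # present extremity is the marker's left-facing end
                sign = REVERSE if head else FORWARD
                right_complete = False
            else:
                # isolated single extremity
                sign = FORWARD
                left_complete, right_complete = (
                    (False, True) if head else (True, False)
                )
            content.append((name, sign))
            i += 1
    if circular:
        return Chromosome("circular", tuple(content))
    if left_complete and right_complete:
        return Chromosome("linear", tuple(content))
    return Chromosome("semi", tuple(content), left_complete, right_complete)


def to_matrix(genome: Genome) -> np.ndarray:
    """The 2n x 2n genomic matrix of a genome (0-based array indices)."""
    size = genome.universe.size
    M = np.zeros((size, size), dtype=np.int64)
    for x in genome.free_ends:
        M[x - 1, x - 1] = 1
    for x, y in genome.adjacencies:
        M[x - 1, y - 1] = 1
        M[y - 1, x - 1] = 1
    return M


def is_genomic_matrix(matrix) -> bool:
    """True iff the matrix is binary, symmetric and squares to a 0/1 diagonal."""
    M = np.asarray(matrix)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DimensionError(f"not a square matrix: shape {M.shape}")
    if M.shape[0] % 2 != 0:
        raise DimensionError(f"odd dimension {M.shape[0]}")
    if not np.issubdtype(M.dtype, np.integer):
        if not np.all(M == M.astype(np.int64)):
            return False
        M = M.astype(np.int64)
    if not np.isin(M, (0, 1)).all():
        return False
    if not np.array_equal(M, M.T):
        return False
    M2 = M @ M
    if np.any(M2 - np.diag(np.diagonal(M2))):
        return False
    return bool(np.isin(np.diagonal(M2), (0, 1)).all())


def genome_from_matrix(universe: MarkerUniverse, matrix) -> Genome:
    """Inverse of :func:`to_matrix` (helper for tests and replay checks)."""
    M = np.asarray(matrix)
    if not is_genomic_matrix(M):
        raise InvalidGenomeError("matrix is not genomic")
    size = universe.size
    if M.shape[0] != size:
        raise DimensionError(
            f"matrix dimension {M.shape[0]} != universe size {size}"
        )
    diag = np.diagonal(M @ M)
    present = frozenset(int(i) + 1 for i in np.nonzero(diag)[0])
    adjacencies = set()
    for i, j in zip(*np.nonzero(M)):
        if i < j:
            adjacencies.add((int(i) + 1, int(j) + 1))
    return Genome(universe, present, frozenset(adjacencies), relaxed=True)
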