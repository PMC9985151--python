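import numpy as np
import pytest

from rankdist.genome import Genome, MarkerUniverse, make_universe


def make_random_universe(rng, n_markers: int) -> MarkerUniverse:
    return make_universe([f"m{i:02d}" for i in range(n_markers)])


def make_random_genome(
    universe: MarkerUniverse,
    rng: np.random.Generator,
    p_marker: float = 0.8,
    p_adj: float = 0.7,
    relaxed: bool = False,
) -> Genome:
    """Random genome: marker (or extremity, if relaxed) subset plus a random
    partial matching on the present extremities."""
    if relaxed:
        present = [
            x for x in range(1, universe.size + 1) if rng.random() < p_marker
        ]
    else:
        present = []
        for m in universe.markers:
            if rng.random() < p_marker:
                present.extend(universe.extremities(m))
    exts = list(present)
    rng.shuffle(exts)
    adjacencies = set()
    for i in range(0, len(exts) - 1, 2):
        if rng.random() < p_adj:
            x, y = exts[i], exts[i + 1]
            adjacencies.add((min(x, y), max(x, y)))
    return Genome(
        universe, frozenset(present), frozenset(adjacencies), relaxed=relaxed
    )


def random_genome_pair(rng, max_markers=12, relaxed=False):
    n = int(rng.integers(1, max_markers + 1))
    universe = make_random_universe(rng, n)
    A = make_random_genome(universe, rng, relaxed=relaxed)
    B = make_random_genome(universe, rng, relaxed=relaxed)
    return universe, A, B


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
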