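# rankdist

Rank and rank-indel genome rearrangement distances for multi-chromosomal
genomes with unequal marker content (no duplicated markers), plus optimal
sorting scenarios, a branch-wise genome evolution simulator, and
distance-based phylogenetic inference and tree comparison.

## Model

A genome over a marker universe of size `n` is a subset of the `2n` marker
extremities (head/tail per marker) plus a partial matching on them (the
adjacencies). It embeds into a `2n x 2n` symmetric binary *genomic matrix*
whose columns map each extremity to its partner, to itself (free end of a
linear chromosome), or to zero (absent).

Two distances are provided:

- **rank distance** `d_r(A, B)` — the exact integer rank of `B - A`.
  Computable in three independent ways: a linear-time breadpoint-graph
  traversal, the closed form `2n - 2c - p0 - pAB` over classified
  breakpoint-graph components, and fraction-free exact rank of the matrix
  difference. A sorting scenario of exactly this weight always exists using
  six weighted operations: cut (1), join (1), double swap (2),
  insertion/deletion of whole (semi-)chromosomes (number of extremities),
  and substitution of a single extremity (2).
- **rank-indel distance** `d_i(A, B) = 2n - 2c - p0 + pAB` — the optimum
  when single-extremity substitutions are banned and genomes must always
  keep whole markers; it satisfies `d_i = d_r + 2 pAB`.

`sort_rank` / `sort_rank_indel` construct scenarios achieving these optima
with every intermediate a valid genome (whole-marker throughout in the
rank-indel case).

## Command line

Gene-order files are FASTA-like: `>name` headers, then one chromosome per
line as signed marker tokens closed by `$` (linear) or `)` (circular):

```
>A
a b -d $
>B
b c d $
```

```
rankdist distance --metric rank A.txt B.txt          # prints one number
rankdist distance --metric rank-indel -v A.txt B.txt # stats on stderr
rankdist sort --mode rank-indel A.txt B.txt          # TSV scenario
rankdist matrix --metric rank -o dist.phy *.txt      # PHYLIP square matrix
rankdist simulate --taxa 10 --genes 500 --seed 1 -o simdir
rankdist nj dist.phy -o tree.nwk
rankdist compare-trees --metric quartet tree.nwk simdir/tree.nwk
```

`simulate` writes `leaves.txt` (gene orders), `tree.nwk` (the true tree)
and `manifest.json` (parameters). Defaults follow the documented
benchmark setup: 20 chromosomes, 5000 genes, insertion rate 0.2, deletion
rate 0.4, duplication rate pinned to 0, Zipf(3.5) indel lengths.

## Python API

```python
from rankdist import (
    make_universe, genome_from_chromosomes, Chromosome,
    rank_distance, rank_indel_distance, sort_rank, sort_rank_indel,
    distance_matrix,
)
from rankdist.phylo import neighbor_joining, rf_normalized, quartet_distance
from rankdist.simulate import SimulationParams, random_tree, evolve
```

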