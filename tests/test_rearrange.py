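import numpy as np
import pytest

from rankdist.distance import (
    exact_rank,
    rank_distance,
    rank_indel_distance,
)
from rankdist.errors import (
    InvalidGenomeError,
    InvalidOperationError,
    NotApplicableError,
)
from rankdist.genome import (
    Chromosome,
    Genome,
    genome_from_chromosomes,
    genome_from_matrix,
    make_universe,
    to_matrix,
)
from rankdist.io import fixtures
from rankdist.rearrange import (
    Operation,
    Scenario,
    apply_op,
    block_substitution_weight,
    is_applicable,
    operation_matrix,
    sort_rank,
    sort_rank_indel,
)

from conftest import make_random_genome, make_random_universe, random_genome_pair


class TestOperationMatrices:
    def test_cut_has_rank_one(self):
        u = make_universe(["a", "x"])
        op = Operation.cut((u.head("a"), u.tail("x")))
        X = operation_matrix(op, u)
        assert exact_rank(X) == 1 == op.weight

    def test_single_marker_deletion_weight_two(self):
        u = make_universe(["x", "y"])
        op = Operation.deletion(Chromosome.linear([("x", 1)]))
        X = operation_matrix(op, u)
        # -(x_t x_t^T) - (x_h x_h^T)
        expected = np.zeros((4, 4), dtype=int)
        expected[0, 0] = expected[1, 1] = -1
        assert np.array_equal(X, expected)
        assert exact_rank(X) == 2 == op.weight

    def test_insertion_is_negated_deletion(self):
        u = make_universe(["b", "c", "z"])
        chrom = Chromosome.circular([("b", 1), ("c", 1)])
        D = operation_matrix(Operation.deletion(chrom), u)
        I = operation_matrix(Operation.insertion(chrom), u)
        assert np.array_equal(I, -D)

    def test_indel_weight_is_extremity_count(self):
        chrom = Chromosome.linear([("a", 1), ("b", -1), ("c", 1)])
        assert Operation.deletion(chrom).weight == 6
        semi = Chromosome("semi", (("a", 1),), left_complete=False)
        assert Operation.deletion(semi).weight == 1

    def test_double_swap_payload_validated(self):
        with pytest.raises(InvalidOperationError):
            Operation.double_swap([(1, 2), (3, 4)], [(1, 2), (3, 4)])
        with pytest.raises(InvalidOperationError):
            Operation.double_swap([(1, 2), (3, 4)], [(1, 5), (3, 6)])

    def test_substitution_matrix_rank_two(self):
        u = make_universe(["a", "x", "y"])
        # attached and free variants
        for op in (
            Operation.substitution(u.tail("x"), u.tail("y"), attached=u.head("a")),
            Operation.substitution(u.tail("x"), u.tail("y"), attached=None),
        ):
            assert exact_rank(operation_matrix(op, u)) == 2 == op.weight


class TestApplicabilityAndApply:
    def test_cut_on_present_adjacency(self):
        A, _ = fixtures()["axy"]
        u = A.universe
        op = Operation.cut((u.head("a"), u.tail("x")))
        assert is_applicable(A, op)
        cut = apply_op(A, op)
        assert op.adjacency not in cut.adjacencies

    def test_join_needs_two_free_ends(self):
        A, _ = fixtures()["axy"]
        u = A.universe
        assert not is_applicable(A, Operation.join((u.head("a"), u.tail("a"))))
        with pytest.raises(NotApplicableError):
            apply_op(A, Operation.join((u.head("a"), u.tail("a"))))

    def test_inverse_pairs_restore_genome(self, rng):
        for _ in range(30):
            u = make_random_universe(rng, int(rng.integers(2, 8)))
            A = make_random_genome(u, rng)
            if A.adjacencies:
                pair = sorted(A.adjacencies)[0]
                there = apply_op(A, Operation.cut(pair))
                back = apply_op(there, Operation.join(pair))
                assert back == A
            if A.markers_present() != set(u.markers):
                absent = sorted(set(u.markers) - A.markers_present())[0]
                chrom = Chromosome.linear([(absent, 1)])
                there = apply_op(A, Operation.insertion(chrom))
                back = apply_op(there, Operation.deletion(chrom))
                assert back == A

    def test_symbolic_equals_matrix_route(self, rng):
        # two-route equivalence on operations sampled from real scenarios
        checked = 0
        for _ in range(60):
            _, A, B = random_genome_pair(rng, max_markers=8)
            cur = A
            for op in sort_rank(A, B).steps:
                X = operation_matrix(op, cur.universe)
                sym = is_applicable(cur, op)
                M = to_matrix(cur) + X
                from rankdist.genome import is_genomic_matrix

                assert sym == is_genomic_matrix(M)
                nxt = apply_op(cur, op)
                assert np.array_equal(to_matrix(nxt), M)
                # matrix route reproduces the set route exactly
                assert genome_from_matrix(cur.universe, M) == nxt
                cur = nxt
                checked += 1
        assert checked >= 200

    def test_inapplicable_op_detected_by_both_routes(self, rng):
        from rankdist.genome import is_genomic_matrix

        for _ in range(50):
            u = make_random_universe(rng, 4)
            A = make_random_genome(u, rng)
            x, y = (
                int(rng.integers(1, u.size + 1)),
                int(rng.integers(1, u.size + 1)),
            )
            if x == y:
                continue
            for op in (Operation.cut((x, y)), Operation.join((x, y))):
                sym = is_applicable(A, op)
                mat = is_genomic_matrix(to_matrix(A) + operation_matrix(op, u))
                assert sym == mat


class TestWorkedScenarios:
    def test_indel_scenario_cut_delete_insert_join(self):
        # the weight-6 route: cut {a_h,x_t}, delete x, insert y, join {a_h,y_t}
        A, B = fixtures()["axy"]
        u = A.universe
        steps = (
            Operation.cut((u.head("a"), u.tail("x"))),
            Operation.deletion(Chromosome.linear([("x", 1)])),
            Operation.insertion(Chromosome.linear([("y", 1)])),
            Operation.join((u.head("a"), u.tail("y"))),
        )
        scenario = Scenario(A, steps)
        assert scenario.replay() == B
        assert scenario.total_weight == 6 == rank_indel_distance(A, B)

    def test_four_extremity_substitutions(self):
        # x_t->w_t, x_h->z_h, y_h->w_h, y_t->z_t transform A into B, weight 8
        A, B = fixtures()["xbcy"]
        u = A.universe
        moves = [("x", "t", "w", "t"), ("x", "h", "z", "h"),
                 ("y", "h", "w", "h"), ("y", "t", "z", "t")]
        cur = A
        total = 0
        for m1, e1, m2, e2 in moves:
            old = u.tail(m1) if e1 == "t" else u.head(m1)
            new = u.tail(m2) if e2 == "t" else u.head(m2)
            op = Operation.substitution(
                old, new, attached=cur.partner_in_adjacency(old)
            )
            assert is_applicable(cur, op)
            cur = apply_op(cur, op)
            total += op.weight
        assert cur == B
        assert total == 8 == rank_distance(A, B)

    def test_block_substitution_cost_model(self):
        # two single-marker substitutions at 2p+2q each, p=q=1
        assert block_substitution_weight(1, 1) == 4
        assert 2 * block_substitution_weight(1, 1) == 8
        assert block_substitution_weight(3, 2) == 10

    def test_end_deletion_equals_cut_plus_deletion(self):
        # deleting k markers at a chromosome end == cut + chromosome
        # deletion, total weight 2k + 1
        u = make_universe(["a", "b", "c"])
        A = genome_from_chromosomes(
            u, [Chromosome.linear([("a", 1), ("b", 1), ("c", 1)])]
        )
        target = genome_from_chromosomes(u, [Chromosome.linear([("a", 1)])])
        steps = (
            Operation.cut((u.head("a"), u.tail("b"))),
            Operation.deletion(Chromosome.linear([("b", 1), ("c", 1)])),
        )
        scenario = Scenario(A, steps)
        assert scenario.replay() == target
        assert scenario.total_weight == 2 * 2 + 1

    def test_internal_deletion_equals_swap_plus_circular_deletion(self):
        # internal run of k markers: double swap extracts a circular
        # chromosome, deletion removes it; total weight 2k + 2
        u = make_universe(["a", "b", "c", "d"])
        A = genome_from_chromosomes(
            u,
            [Chromosome.linear([("a", 1), ("b", 1), ("c", 1), ("d", 1)])],
        )
        target = genome_from_chromosomes(
            u, [Chromosome.linear([("a", 1), ("d", 1)])]
        )
        swap = Operation.double_swap(
            removed=[(u.head("a"), u.tail("b")), (u.head("c"), u.tail("d"))],
            added=[(u.head("a"), u.tail("d")), (u.head("c"), u.tail("b"))],
        )
        steps = (
            swap,
            Operation.deletion(Chromosome.circular([("b", 1), ("c", 1)])),
        )
        scenario = Scenario(A, steps)
        assert scenario.replay() == target
        assert scenario.total_weight == 2 * 2 + 2


class TestSorting:
    def test_identical_genomes_empty_scenario(self, rng):
        _, A, _ = random_genome_pair(rng)
        s = sort_rank(A, A)
        assert s.steps == () and s.total_weight == 0
        if A.whole_marker:
            si = sort_rank_indel(A, A)
            assert si.steps == ()

    def test_rank_scenario_contract(self, rng):
        for _ in range(120):
            _, A, B = random_genome_pair(rng, max_markers=10)
            s = sort_rank(A, B)
            assert s.replay() == B
            assert s.total_weight == rank_distance(A, B)

    def test_rank_scenario_contract_relaxed_inputs(self, rng):
        for _ in range(60):
            _, A, B = random_genome_pair(rng, max_markers=8, relaxed=True)
            s = sort_rank(A, B)
            assert s.replay() == B
            assert s.total_weight == rank_distance(A, B)

    def test_indel_scenario_contract(self, rng):
        for _ in range(120):
            _, A, B = random_genome_pair(rng, max_markers=10)
            s = sort_rank_indel(A, B)
            assert s.replay() == B
            assert s.total_weight == rank_indel_distance(A, B)
            allowed = {
                "cut", "join", "double_swap", "chrom_deletion",
                "chrom_insertion",
            }
            assert {op.kind for op in s.steps} <= allowed
            for g in s.intermediates():
                assert g.whole_marker  # never a lone extremity

    def test_scenario_weights_equal_matrix_ranks(self, rng):
        for _ in range(40):
            _, A, B = random_genome_pair(rng, max_markers=8)
            for s in (sort_rank(A, B), sort_rank_indel(A, B)):
                for op in s.steps:
                    X = operation_matrix(op, A.universe)
                    assert exact_rank(X) == op.weight

    def test_indel_sorting_rejects_relaxed(self):
        u = make_universe(["a"])
        g = Genome(u, frozenset({1}), frozenset(), relaxed=True)
        whole = Genome(u, frozenset(), frozenset())
        with pytest.raises(InvalidGenomeError):
            sort_rank_indel(g, whole)

    def test_scenario_tsv_format(self):
        A, B = fixtures()["axy"]
        text = sort_rank_indel(A, B).to_tsv("A", "B")
        lines = text.strip().splitlines()
        assert lines[0].startswith("# scenario\tA\tB\ttotal_weight=6")
        assert all(len(ln.split("\t")) == 3 for ln in lines[1:])
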