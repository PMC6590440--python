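"""Signed-permutation distances, inversion scenarios and tree placement.

The breadth-first-search oracle used throughout is independent of the
IDA* engine: it enumerates reversal sequences exhaustively.
"""

from collections import deque
from itertools import permutations, product

import pytest
from hypothesis import given, settings, strategies as st

from plastevol.rearrangement import (
    REPEAT_BLOCK,
    SignedGeneOrder,
    apply_reversal,
    breakpoint_count,
    collapse_to_blocks,
    infer_inversion_scenario,
    read_orders,
    reversal_distance,
    reversal_distance_perm,
    to_permutation,
    write_orders,
    _rev,
)


def bfs_distance(perm):
    """Oracle: exhaustive BFS over reversal sequences."""
    n = len(perm)
    ident = tuple(range(1, n + 1))
    if perm == ident:
        return 0
    seen = {perm}
    frontier = deque([(perm, 0)])
    while frontier:
        p, d = frontier.popleft()
        for i in range(n):
            for j in range(i, n):
                c = _rev(p, i, j)
                if c == ident:
                    return d + 1
                if c not in seen:
                    seen.add(c)
                    frontier.append((c, d + 1))
    raise AssertionError("unreachable")


def random_signed_perm(rng, n):
    vals = list(range(1, n + 1))
    rng.shuffle(vals)
    return tuple(v * rng.choice([1, -1]) for v in vals)


class TestReversalDistance:
    @pytest.mark.parametrize("perm,expected", [
        ((1, 2, 3), 0),
        ((1, -3, -2), 1),
        ((2, 1), 3),
        ((-1,), 1),
        ((3, 2, 1), 3),
    ])
    def test_small_known_cases(self, perm, expected):
        assert reversal_distance_perm(perm) == expected

    def test_exhaustive_n3(self):
        for vals in permutations(range(1, 4)):
            for signs in product([1, -1], repeat=3):
                perm = tuple(v * s for v, s in zip(vals, signs))
                assert reversal_distance_perm(perm) == bfs_distance(perm)

    def test_random_n5_vs_bfs(self):
        import random

        rng = random.Random(11)
        for _ in range(25):
            perm = random_signed_perm(rng, 5)
            assert reversal_distance_perm(perm) == bfs_distance(perm)

    def test_symmetry_and_triangle(self):
        import random

        rng = random.Random(3)
        names = list("abcde")
        for _ in range(15):
            orders = []
            for _k in range(3):
                perm = random_signed_perm(rng, 5)
                blocks = [(names[abs(v) - 1], 1 if v > 0 else -1) for v in perm]
                orders.append(SignedGeneOrder(blocks, circular=False))
            a, b, c = orders
            dab = reversal_distance(a, b)
            assert dab == reversal_distance(b, a)
            assert dab <= reversal_distance(a, c) + reversal_distance(c, b)

    def test_lower_bound_from_breakpoints(self):
        import random

        rng = random.Random(9)
        names = list("abcdef")
        ident = SignedGeneOrder([(n, 1) for n in names], circular=False)
        for _ in range(20):
            perm = random_signed_perm(rng, 6)
            other = SignedGeneOrder(
                [(names[abs(v) - 1], 1 if v > 0 else -1) for v in perm], circular=False)
            bk = len(ident.adjacency_set() - other.adjacency_set())
            assert reversal_distance(ident, other) >= -(-bk // 2)  # ceil

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.permutations(list(range(1, 6))),
           st.lists(st.sampled_from([1, -1]), min_size=5, max_size=5))
    def test_distance_matches_bfs_property(self, vals, signs):
        perm = tuple(v * s for v, s in zip(vals, signs))
        assert reversal_distance_perm(perm) == bfs_distance(perm)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.permutations(list(range(1, 7))),
           st.lists(st.sampled_from([1, -1]), min_size=6, max_size=6))
    def test_scenario_replay_property(self, vals, signs):
        names = list("abcdef")
        src = SignedGeneOrder([(n, 1) for n in names], circular=False)
        tgt = SignedGeneOrder(
            [(names[v - 1], s) for v, s in zip(vals, signs)], circular=False)
        sc = infer_inversion_scenario(src, tgt)
        blocks = list(src.blocks)
        for ev in sc.events:
            blocks = apply_reversal(blocks, *ev.interval)
        assert blocks == tgt.blocks
        assert sc.distance >= -(-breakpoint_count(src, tgt) // 2)

    def test_cap_exceeded_raises(self):
        perm = tuple(range(1, 25))
        with pytest.raises(ValueError, match="cap"):
            reversal_distance_perm(perm, cap=20)


class TestBreakpoints:
    def test_identical_orders(self):
        s = SignedGeneOrder([("a", 1), ("b", 1), ("c", 1), ("d", 1)])
        assert breakpoint_count(s, s) == 0

    def test_equivalence_under_rotation_and_reflection(self):
        s = SignedGeneOrder([("a", 1), ("b", 1), ("c", 1), ("d", 1)])
        assert breakpoint_count(s, s.rotated(2)) == 0
        assert breakpoint_count(s, s.reversed_order()) == 0

    def test_single_internal_inversion_creates_two_breakpoints(self):
        s = SignedGeneOrder([(c, 1) for c in "abcdef"])
        t = SignedGeneOrder(apply_reversal(s.blocks, 1, 3))
        assert breakpoint_count(s, t) == 2

    def test_matches_adjacency_oracle_on_random_orders(self):
        import random

        rng = random.Random(21)
        names = list("abcdefgh")
        for _ in range(30):
            perm = random_signed_perm(rng, 8)
            t = SignedGeneOrder([(names[abs(v) - 1], 1 if v > 0 else -1) for v in perm])
            s = SignedGeneOrder([(n, 1) for n in names])
            # oracle: direct circular adjacency enumeration with strand
            # normalization, written independently
            def adj(order):
                out = set()
                bl = order.blocks
                for k in range(len(bl)):
                    (x, sx), (y, sy) = bl[k], bl[(k + 1) % len(bl)]
                    out.add(min(((x, sx), (y, sy)), ((y, -sy), (x, -sx))))
                return out

            assert breakpoint_count(s, t) == len(adj(s) - adj(t))


class TestCollapse:
    def test_identical_orders_become_one_block(self):
        s = SignedGeneOrder([(f"g{i}", 1) for i in range(10)], circular=False)
        src, tgt, dups = collapse_to_blocks(s, s)
        assert len(src) == 1 and len(tgt) == 1 and not dups

    def test_single_inverted_gene_gives_three_blocks(self):
        s = SignedGeneOrder([(f"g{i}", 1) for i in range(5)], circular=False)
        t = SignedGeneOrder(apply_reversal(s.blocks, 2, 2), circular=False)
        src, tgt, _ = collapse_to_blocks(s, t)
        assert len(src) == 3 and len(tgt) == 3

    def test_tandem_duplicate_extracted(self):
        s = SignedGeneOrder([("a", 1), ("b", 1), ("c", 1), ("d", 1)], circular=False)
        t = SignedGeneOrder([("a", 1), ("b", 1), ("b", 1), ("c", 1), ("d", 1)], circular=False)
        src, tgt, dups = collapse_to_blocks(s, t)
        assert [d.block for d in dups] == ["b"]
        assert len(src) == 1 and len(tgt) == 1

    def test_non_tandem_duplicate_rejected(self):
        s = SignedGeneOrder([("a", 1), ("b", 1), ("c", 1), ("d", 1), ("e", 1), ("f", 1), ("g", 1)], circular=False)
        t = SignedGeneOrder([("b", 1), ("a", 1), ("c", 1), ("d", 1), ("e", 1), ("f", 1), ("b", 1), ("g", 1)], circular=False)
        with pytest.raises(ValueError, match="non-tandem"):
            collapse_to_blocks(s, t)


class TestScenarios:
    def test_identity_scenario_empty(self):
        s = SignedGeneOrder([(c, 1) for c in "abcd"])
        sc = infer_inversion_scenario(s, s)
        assert sc.distance == 0 and sc.events == []

    def test_replay_reproduces_target_on_random_cases(self):
        import random

        rng = random.Random(5)
        names = list("abcdef")
        src = SignedGeneOrder([(n, 1) for n in names], circular=False)
        for _ in range(15):
            perm = random_signed_perm(rng, 6)
            tgt = SignedGeneOrder(
                [(names[abs(v) - 1], 1 if v > 0 else -1) for v in perm], circular=False)
            sc = infer_inversion_scenario(src, tgt)
            blocks = list(src.blocks)
            for ev in sc.events:
                blocks = apply_reversal(blocks, *ev.interval)
            assert blocks == tgt.blocks
            assert sc.distance == len(sc.events)
            assert sc.distance >= -(-sc.breakpoints_initial // 2)

    def test_published_encodings(self, published_orders):
        anc = published_orders["Ancestral"]
        expectations = {
            "Skra": (1, ["IR", "DR"]),
            "Slep": (2, ["IR", "DR", "IR"]),
            "Smoe": (2, ["IR", "DR", "IR"]),
            "Isoetes": (2, ["IR", "DR", "IR"]),
        }
        for taxon, (d, traj) in expectations.items():
            src, tgt, _ = collapse_to_blocks(anc, published_orders[taxon])
            sc = infer_inversion_scenario(src, tgt)
            assert sc.distance == d, taxon
            assert sc.orientation_trajectory == traj, taxon

    def test_most_rearranged_genome_needs_five_inversions(self, published_orders):
        anc = published_orders["Ancestral"]
        src, tgt, dups = collapse_to_blocks(anc, published_orders["Sunc"])
        sc = infer_inversion_scenario(src, tgt)
        assert sc.distance >= 5
        assert sorted(d.block for d in dups) == ["psbK", "trnQ-UUG"]
        # orientation parity: spanning events match the IR->IR endpoints
        assert sum(e.spans_repeat for e in sc.events) % 2 == 0

    def test_orientation_parity_property(self, published_orders):
        anc = published_orders["Ancestral"]
        for taxon in ("Skra", "Slep", "Smoe", "Stam", "Isoetes"):
            tgt_flag = published_orders[taxon].orientation_flag
            src, tgt, _ = collapse_to_blocks(anc, published_orders[taxon])
            sc = infer_inversion_scenario(src, tgt)
            n_span = sum(e.spans_repeat for e in sc.events)
            same = anc.orientation_flag == tgt_flag
            assert (n_span % 2 == 0) == same, taxon


class TestTreePlacement:
    def test_shared_event_pushed_to_stem(self, mini_clade):
        from plastevol.rearrangement import place_events_on_tree
        from plastevol.simulate import MINI_CLADE_TREE
        from plastevol.trees import parse_newick

        records, truth = mini_clade
        tree = parse_newick(MINI_CLADE_TREE)
        scen, srcs = {}, {}
        for tip in tree.leaf_names():
            src, tgt, _ = collapse_to_blocks(truth.root_order, truth.tip_orders[tip])
            scen[tip] = infer_inversion_scenario(src, tgt)
            srcs[tip] = src
        placed = place_events_on_tree(scen, srcs, tree)
        # the static clade carries no events at all
        for branch in ("T1", "T2", "T3", "Static"):
            assert not placed.get(branch)
        # planted history recovered exactly: one shared inversion on the
        # dynamic stem, one on the T67 stem, private events terminal
        counts = {br: len(evs) for br, evs in placed.items()}
        assert counts == {"Dynamic": 1, "T5": 1, "T67": 1, "T7": 1}

    def test_private_event_stays_terminal(self):
        from plastevol.rearrangement import place_events_on_tree
        from plastevol.trees import parse_newick

        base = SignedGeneOrder([(c, 1) for c in "abcdefgh"], circular=False)
        shared = SignedGeneOrder(apply_reversal(base.blocks, 1, 3), circular=False)
        private = SignedGeneOrder(apply_reversal(shared.blocks, 5, 6), circular=False)
        tree = parse_newick("((X,Y)XY,Z)R;")
        scen, srcs = {}, {}
        for tip, tgt in (("X", shared), ("Y", private), ("Z", base)):
            sc = infer_inversion_scenario(base, tgt)
            scen[tip], srcs[tip] = sc, base
        placed = place_events_on_tree(scen, srcs, tree)
        assert len(placed.get("XY", [])) == 1  # shared inversion on the stem
        assert len(placed.get("Y", [])) == 1  # private inversion terminal
        assert not placed.get("Z")


class TestExchangeFormat:
    def test_round_trip(self, tmp_path, published_orders):
        path = tmp_path / "orders.txt"
        write_orders(published_orders, path)
        back = read_orders(path)
        assert set(back) == set(published_orders)
        for name, order in published_orders.items():
            assert back[name].blocks == order.blocks
            assert back[name].orientation_flag == order.orientation_flag
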