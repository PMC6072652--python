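import random
from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from curveball import (
    BipartiteState,
    DirectedGraph,
    UndirectedGraph,
    apply_trade,
    bipartite_trade,
    degrees,
    directed_trade,
    edge_set,
    enumerate_switches,
    er_gnm,
    inverse_proposal,
    size_one_trade,
    tradeable_sets,
    trades_realizing_switch,
    undirected_trade,
    validate,
)
from curveball.errors import InvalidPairError, StaleProposalError
from curveball.moves import apply_switch


class TestTradeableSets:
    def test_shared_and_partner_elements_excluded(self):
        # i = 8, j = 9; shared {3, 4} and the partner entry are untouchable
        t_i, t_j = tradeable_sets({1, 2, 3, 4}, {3, 4, 5, 6, 7, 8}, 8, 9)
        assert (t_i, t_j) == ({1, 2}, {5, 6, 7})
        assert t_i | t_j == {1, 2, 5, 6, 7}

    def test_identical_sets_nothing_tradeable(self):
        assert tradeable_sets({1, 2}, {1, 2}, 0, 3) == (set(), set())

    def test_partner_only_entry_excluded(self):
        # A_i = {j}: the mutual arc is never traded
        assert tradeable_sets({9}, set(), 8, 9) == (set(), set())

    def test_same_index_rejected(self):
        with pytest.raises(InvalidPairError):
            tradeable_sets({1}, {2}, 5, 5)

    def test_inputs_untouched(self):
        a, b = {1, 2, 9}, {0, 8}
        tradeable_sets(a, b, 8, 9)
        assert a == {1, 2, 9} and b == {0, 8}


class TestDirectedTrade:
    def test_fig_style_trade_redistributes_union(self, bank, rng):
        g = bank["directed_pair"]
        p = directed_trade(g, 8, 9, rng)
        assert p.tradeable_i == {1, 2} and p.tradeable_j == {5, 6, 7}
        # kept elements {3, 4} and the mutual arc 9->8 never move
        assert {3, 4} <= p.new_i and {3, 4} <= p.new_j and 8 in p.new_j
        assert len(p.new_i) == 4 and len(p.new_j) == 6
        assert 8 not in p.new_i and 9 not in p.new_j

    def test_specific_subset_choice_matches_set_algebra(self, bank):
        # oracle: B_i = (A_i \ A_{i-j}) | S for S = {5, 7}
        g = bank["directed_pair"]
        for seed in range(200):
            p = directed_trade(g, 8, 9, random.Random(seed))
            if p.new_i == {3, 4, 5, 7}:
                assert p.new_j == {8, 3, 4, 6, 1, 2}
                assert p.size == 2
                break
        else:
            pytest.fail("subset {5,7} never drawn in 200 seeds")

    def test_empty_union_repeats_network(self, rng):
        g = DirectedGraph(3, [{1}, {2}, {0}])  # oriented triangle
        p = directed_trade(g, 0, 1, rng)
        assert p.size == 0 and p.new_i == p.old_i and p.new_j == p.old_j

    def test_invalid_pair(self, bank, rng):
        with pytest.raises(InvalidPairError):
            directed_trade(bank["directed_pair"], 8, 8, rng)


class TestUndirectedTrade:
    def test_exchange_updates_traded_nodes_sets(self, bank):
        # trading 1 for 4 between nodes 6 and 7 must rewrite A_1 and A_4
        g = bank["undirected_pair"].copy()
        p = size_one_trade(g, 6, 7, 1, 4)
        apply_trade(g, p)
        assert g.adjacency[6] == {7, 3, 2, 4}
        assert g.adjacency[7] == {6, 3, 5, 1}
        assert g.adjacency[4] == {6} and g.adjacency[1] == {7}
        assert validate(g).ok

    def test_mutual_edge_never_traded(self, bank, rng):
        g = bank["undirected_pair"]
        for seed in range(50):
            p = undirected_trade(g, 6, 7, random.Random(seed))
            assert 7 in p.new_i and 6 in p.new_j

    def test_size_zero_leaves_graph_intact(self, rng):
        g = UndirectedGraph(3, [{1}, {0, 2}, {1}])
        p = undirected_trade(g, 0, 2, rng)  # A_0 == A_2 == {1}
        assert p.size == 0
        apply_trade(g, p)
        assert g.adjacency == [{1}, {0, 2}, {1}] and validate(g).ok


class TestBipartiteTrade:
    def test_forced_single_exchange(self):
        s = BipartiteState(2, 3, [{0, 1}, {1, 2}])
        p = bipartite_trade(s, 0, 1, random.Random(0))
        assert p.tradeable_i == {0} and p.tradeable_j == {2}
        assert p.new_i in ({0, 1}, {1, 2})
        if p.size == 1:
            assert p.new_i == {1, 2} and p.new_j == {0, 1}

    def test_identical_rows_size_zero(self, rng):
        s = BipartiteState(2, 2, [{0, 1}, {0, 1}])
        assert bipartite_trade(s, 0, 1, rng).size == 0

    def test_identity_rows_swap_permutation_entries(self, bank, rng):
        s = bank["bipartite_margins1"]
        p = bipartite_trade(s, 0, 1, rng)
        assert p.tradeable_i == {0} and p.tradeable_j == {1}
        assert p.new_i in ({0}, {1})

    def test_no_partner_exclusion(self, rng):
        # column index equal to a row index is an ordinary tradeable column
        s = BipartiteState(2, 2, [{1}, {0}])
        p = bipartite_trade(s, 0, 1, rng)
        assert p.tradeable_i == {1} and p.tradeable_j == {0}


class TestApplyTrade:
    def test_stale_proposal_rejected(self, bank, rng):
        g = bank["directed_pair"].copy()
        p = directed_trade(g, 8, 9, rng)
        g.out_adjacency[8].discard(1)
        with pytest.raises(StaleProposalError):
            apply_trade(g, p)

    def test_apply_then_inverse_restores(self, rng):
        for kind in ("directed", "undirected"):
            g = er_gnm(10, 20, kind, rng)
            trade = directed_trade if kind == "directed" else undirected_trade
            before = edge_set(g)
            p = trade(g, 2, 7, rng)
            apply_trade(g, p)
            apply_trade(g, inverse_proposal(p))
            assert edge_set(g) == before

    @pytest.mark.parametrize("kind", ["bipartite", "directed", "undirected"])
    def test_degrees_preserved_over_random_trades(self, kind, rng):
        if kind == "bipartite":
            g = BipartiteState(6, 7, [set(rng.sample(range(7), 3)) for _ in range(6)])
        else:
            g = er_gnm(12, 24, kind, rng)
        ds = degrees(g)
        n = g.n_rows if kind == "bipartite" else g.n_nodes
        trade = {"bipartite": bipartite_trade, "directed": directed_trade,
                 "undirected": undirected_trade}[kind]
        for _ in range(300):
            i, j = rng.sample(range(n), 2)
            apply_trade(g, trade(g, i, j, rng))
            assert degrees(g) == ds
            assert validate(g).ok


class TestSubsetUniformity:
    def test_chosen_subsets_uniform_over_all_k_subsets(self):
        """10^5 draws from fixed tradeable sets hit every C(5,2) subset
        equally often (chi-square)."""
        g = DirectedGraph(
            10, [set()] * 8 + [{1, 2, 3, 4}, {8, 3, 4, 5, 6, 7}])
        rng = random.Random(99)
        counts: dict[frozenset, int] = {}
        for _ in range(100_000):
            p = directed_trade(g, 8, 9, rng)
            chosen = frozenset(p.new_i - (p.old_i - p.tradeable_i))
            counts[chosen] = counts.get(chosen, 0) + 1
        assert len(counts) == 10  # C(5, 2)
        _, pvalue = stats.chisquare(list(counts.values()))
        assert pvalue > 0.001


class TestEnumerateSwitches:
    def test_oriented_triangle_has_none(self, bank):
        assert enumerate_switches(bank["oriented_triangle"]) == []

    def test_undirected_4cycle_switch_count_matches_brute_force(self):
        g = UndirectedGraph(4, [{1, 3}, {0, 2}, {1, 3}, {2, 0}])
        switches = enumerate_switches(g)
        # independent oracle: try all edge pairs and re-pairings directly
        E = edge_set(g)
        expected = 0
        edges = sorted(tuple(sorted(e)) for e in E)
        for (x, y), (u, v) in combinations(edges, 2):
            for p1, p2 in ((frozenset((x, v)), frozenset((u, y))),
                           (frozenset((x, u)), frozenset((y, v)))):
                if len(p1) == 2 and len(p2) == 2 and p1 != p2 \
                        and p1 not in E and p2 not in E:
                    expected += 1
        assert len(switches) == expected == 2

    def test_two_disjoint_arcs_single_switch(self):
        g = DirectedGraph(4, [{1}, set(), {3}, set()])
        switches = enumerate_switches(g)
        assert len(switches) == 1
        assert switches[0].edges_after == ((0, 3), (2, 1))

    def test_every_enumerated_switch_is_applicable(self, rng):
        for _ in range(10):
            g = er_gnm(8, 12, "directed", rng)
            ds = degrees(g)
            for sw in enumerate_switches(g):
                h = apply_switch(g.copy(), sw)
                assert validate(h).ok and degrees(h) == ds


class TestTradesRealizingSwitch:
    def test_undirected_switch_two_trades(self, rng):
        """Every undirected switch is realized by exactly two size-one
        trades: y<->v on (A_x, A_u) and x<->u on (A_y, A_v)."""
        realized = 0
        while realized < 20:
            g = er_gnm(rng.randint(6, 9), 10, "undirected", rng)
            switches = enumerate_switches(g)
            if not switches:
                continue
            sw = switches[rng.randrange(len(switches))]
            g2 = apply_switch(g.copy(), sw)
            trades = trades_realizing_switch(g, g2)
            assert len(trades) == 2
            assert all(t.size == 1 for t in trades)
            pairs = {frozenset((t.i, t.j)) for t in trades}
            assert len(pairs) == 2 and not (pairs.pop() & pairs.pop())
            realized += 1

    def test_directed_switch_at_least_one_trade(self, rng):
        realized = 0
        while realized < 20:
            g = er_gnm(rng.randint(6, 9), 14, "directed", rng)
            switches = enumerate_switches(g)
            if not switches:
                continue
            sw = switches[rng.randrange(len(switches))]
            g2 = apply_switch(g.copy(), sw)
            trades = trades_realizing_switch(g, g2)
            assert len(trades) >= 1
            assert all(t.size == 1 for t in trades)
            realized += 1

    def test_bipartite_switch_exactly_one_trade(self, rng):
        realized = 0
        while realized < 10:
            s = BipartiteState(4, 5, [set(rng.sample(range(5), 2))
                                      for _ in range(4)])
            switches = enumerate_switches(s)
            if not switches:
                continue
            sw = switches[rng.randrange(len(switches))]
            s2 = apply_switch(s.copy(), sw)
            trades = trades_realizing_switch(s, s2)
            assert len(trades) == 1 and trades[0].size == 1
            realized += 1

    def test_identical_graphs_no_trades(self, bank):
        g = bank["oriented_triangle"]
        assert trades_realizing_switch(g, g.copy()) == []

    def test_non_switch_difference_rejected(self, rng):
        g = er_gnm(8, 12, "directed", rng)
        h = g.copy()
        # scramble h far from g while keeping degrees
        for _ in range(50):
            i, j = rng.sample(range(8), 2)
            apply_trade(h, directed_trade(h, i, j, rng))
        if len(edge_set(g) - edge_set(h)) != 2:
            with pytest.raises(InvalidPairError):
                trades_realizing_switch(g, h)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**20), kind=st.sampled_from(
    ["bipartite", "directed", "undirected"]))
def test_trade_preserves_degrees_and_simplicity(seed, kind):
    """Property: any trade on any graph preserves the degree sequence,
    simplicity and (undirected) symmetry."""
    rng = random.Random(seed)
    if kind == "bipartite":
        g = BipartiteState(5, 6, [set(rng.sample(range(6), rng.randint(0, 4)))
                                  for _ in range(5)])
        trade = bipartite_trade
        n = 5
    else:
        n = rng.randint(4, 12)
        m = rng.randint(0, n * (n - 1) // (2 if kind == "undirected" else 1))
        g = er_gnm(n, m, kind, rng)
        trade = directed_trade if kind == "directed" else undirected_trade
    ds = degrees(g)
    for _ in range(20):
        i, j = rng.sample(range(n), 2)
        p = trade(g, i, j, rng)
        apply_trade(g, p)
    assert degrees(g) == ds
    assert validate(g).ok
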