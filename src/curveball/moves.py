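"""Atomic randomization moves: Curveball trades and classic edge switches.

A *trade* between two adjacency sets A_i and A_j first computes the
tradeable sets

    A_{i-j} = A_i \\ (A_j U {j})        A_{j-i} = A_j \\ (A_i U {i})

(the elements each side could give away; excluding the partner node keeps
the result self-loop free), then redistributes the union A_{i-j} U A_{j-i}
at random: i receives a uniformly chosen |A_{i-j}|-subset and j the rest.
The *size* of a trade is the number of elements that actually change owner;
a draw that re-selects the status quo has size zero and simply repeats the
current network.  For undirected graphs a symmetric repair step rewrites
the neighbour sets of every traded element so that the adjacency list stays
symmetric.  Bipartite trades act on biadjacency rows, where columns are a
separate node class and no self-loop exclusion is needed.

A *switch* is the classic rewiring move: edges (x,y),(u,v) are replaced by
(x,v),(u,y) when that creates no self-loop and no duplicate edge.  Every
switch equals a size-one trade, which is the bridge between the switching
chain and the trade chain exploited by the restricted baseline and the
switch/trade equivalence tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import combinations
from .errors import InvalidPairError, StaleProposalError
from .graphs import (
    BipartiteState,
    DirectedGraph,
    Graph,
    Kind,
    UndirectedGraph,
    edge_set,
    graph_kind,
)

__all__ = [
    "TradeProposal",
    "Switch",
    "tradeable_sets",
    "directed_trade",
    "undirected_trade",
    "bipartite_trade",
    "size_one_trade",
    "apply_trade",
    "inverse_proposal",
    "enumerate_switches",
    "trades_realizing_switch",
]


@dataclass(frozen=True)
class TradeProposal:
    """Immutable record of one trade between sets ``i`` and ``j``."""

    kind: Kind
    i: int
    j: int
    old_i: frozenset[int]
    old_j: frozenset[int]
    tradeable_i: frozenset[int]
    tradeable_j: frozenset[int]
    new_i: frozenset[int]
    new_j: frozenset[int]

    @property
    def size(self) -> int:
        """Number of elements that change owner (0 = network repeated)."""
        return len(self.tradeable_i - self.new_i)


@dataclass(frozen=True)
class Switch:
    """A classic switch: ``edges_before`` replaced by ``edges_after``."""

    edges_before: tuple
    edges_after: tuple


def tradeable_sets(A_i: set[int], A_j: set[int], i: int, j: int
                   ) -> tuple[set[int], set[int]]:
    """Return ``(A_i \\ (A_j | {j}), A_j \\ (A_i | {i}))``.

    Pure function; the inputs are not modified.
    """
    if i == j:
        raise InvalidPairError(f"trade requires two distinct sets, got i == j == {i}")
    return A_i - A_j - {j}, A_j - A_i - {i}


def _build_proposal(kind: Kind, A_i: set[int], A_j: set[int], i: int, j: int,
                    t_i: set[int], t_j: set[int], chosen_i: set[int]) -> TradeProposal:
    union = t_i | t_j
    new_i = (A_i - t_i) | chosen_i
    new_j = (A_j - t_j) | (union - chosen_i)
    return TradeProposal(
        kind=kind, i=i, j=j,
        old_i=frozenset(A_i), old_j=frozenset(A_j),
        tradeable_i=frozenset(t_i), tradeable_j=frozenset(t_j),
        new_i=frozenset(new_i), new_j=frozenset(new_j),
    )


def _trade(kind: Kind, A_i: set[int], A_j: set[int], i: int, j: int,
           rng: random.Random, exclude_partner: bool) -> TradeProposal:
    if exclude_partner:
        t_i, t_j = tradeable_sets(A_i, A_j, i, j)
    else:
        if i == j:
            raise InvalidPairError(f"trade requires two distinct rows, got {i} twice")
        t_i, t_j = A_i - A_j, A_j - A_i
    pool = sorted(t_i | t_j)
    rng.shuffle(pool)
    chosen_i = set(pool[: len(t_i)])
    return _build_proposal(kind, A_i, A_j, i, j, t_i, t_j, chosen_i)


def directed_trade(graph: DirectedGraph, i: int, j: int,
                   rng: random.Random) -> TradeProposal:
    """Propose a trade between the out-neighbour sets of nodes i and j."""
    return _trade("directed", graph.out_adjacency[i], graph.out_adjacency[j],
                  i, j, rng, exclude_partner=True)


def undirected_trade(graph: UndirectedGraph, i: int, j: int,
                     rng: random.Random) -> TradeProposal:
    """Propose a trade between the neighbour sets of nodes i and j.

    The symmetric repair of traded elements' own sets happens when the
    proposal is committed by :func:`apply_trade`.
    """
    return _trade("undirected", graph.adjacency[i], graph.adjacency[j],
                  i, j, rng, exclude_partner=True)


def bipartite_trade(state: BipartiteState, r1: int, r2: int,
                    rng: random.Random) -> TradeProposal:
    """Propose a trade between two biadjacency rows.

    Columns are a distinct node class, so there is no partner exclusion and
    no self-loop hazard; row and column sums are preserved.
    """
    return _trade("bipartite", state.rows[r1], state.rows[r2],
                  r1, r2, rng, exclude_partner=False)


def size_one_trade(graph: Graph, i: int, j: int, a: int, b: int) -> TradeProposal:
    """Deterministic trade exchanging exactly ``a`` (from side i) for ``b``.

    ``a`` must be tradeable from i's set and ``b`` from j's; used by the
    size-1-restricted baseline chain and by switch/trade equivalence
    checks.
    """
    kind = graph_kind(graph)
    A_i, A_j = _adjacency_of(graph, i), _adjacency_of(graph, j)
    if kind == "bipartite":
        if i == j:
            raise InvalidPairError(f"trade requires two distinct rows, got {i} twice")
        t_i, t_j = A_i - A_j, A_j - A_i
    else:
        t_i, t_j = tradeable_sets(A_i, A_j, i, j)
    if a not in t_i or b not in t_j:
        raise InvalidPairError(
            f"({a}, {b}) is not an exchangeable pair for sets ({i}, {j})")
    chosen_i = (t_i - {a}) | {b}
    return _build_proposal(kind, A_i, A_j, i, j, t_i, t_j, chosen_i)


def _adjacency_of(graph: Graph, i: int) -> set[int]:
    if isinstance(graph, UndirectedGraph):
        return graph.adjacency[i]
    if isinstance(graph, DirectedGraph):
        return graph.out_adjacency[i]
    return graph.rows[i]


def _adjacency_list(graph: Graph) -> list[set[int]]:
    if isinstance(graph, UndirectedGraph):
        return graph.adjacency
    if isinstance(graph, DirectedGraph):
        return graph.out_adjacency
    return graph.rows


def apply_trade(graph: Graph, proposal: TradeProposal) -> Graph:
    """Commit a proposal to ``graph`` in place and return it.

    For undirected graphs this performs the symmetric repair: every node
    that moved from j's set to i's has ``j`` replaced by ``i`` in its own
    neighbour set, and vice versa.  Raises :class:`StaleProposalError` if
    the graph no longer matches the state the proposal was computed from.
    """
    if graph_kind(graph) != proposal.kind:
        raise StaleProposalError(
            f"proposal kind {proposal.kind!r} does not match graph")
    adj = _adjacency_list(graph)
    i, j = proposal.i, proposal.j
    if adj[i] != proposal.old_i or adj[j] != proposal.old_j:
        raise StaleProposalError(
            f"sets ({i}, {j}) changed since the proposal was generated")
    adj[i] = set(proposal.new_i)
    adj[j] = set(proposal.new_j)
    if proposal.kind == "undirected":
        for k in proposal.new_i - proposal.old_i:   # moved j -> i
            adj[k].discard(j)
            adj[k].add(i)
        for k in proposal.new_j - proposal.old_j:   # moved i -> j
            adj[k].discard(i)
            adj[k].add(j)
    return graph


def inverse_proposal(proposal: TradeProposal) -> TradeProposal:
    """The reverse trade: selecting the same pair on the traded graph and
    choosing the original subsets returns the pre-trade network.
    """
    excl_j = {proposal.j} if proposal.kind != "bipartite" else set()
    excl_i = {proposal.i} if proposal.kind != "bipartite" else set()
    return TradeProposal(
        kind=proposal.kind, i=proposal.i, j=proposal.j,
        old_i=proposal.new_i, old_j=proposal.new_j,
        tradeable_i=frozenset(proposal.new_i - proposal.new_j - excl_j),
        tradeable_j=frozenset(proposal.new_j - proposal.new_i - excl_i),
        new_i=proposal.old_i, new_j=proposal.old_j,
    )


# ---------------------------------------------------------------------------
# switches


def _valid_directed_switch(E: set, x: int, y: int, u: int, v: int) -> bool:
    # (x,y),(u,v) -> (x,v),(u,y)
    if x == v or u == y:
        return False
    if (x, v) in E or (u, y) in E:
        return False
    if (x, v) == (u, y):
        return False
    return True


def enumerate_switches(graph: Graph, kind: Kind | None = None) -> list[Switch]:
    """All valid classic switches of a graph.

    Directed: pairs of arcs (x,y),(u,v) rewired to (x,v),(u,y).  Undirected:
    both re-pairings of each edge pair are examined.  Bipartite: pairs of
    (row, col) ones rewired across rows (a checkerboard swap).  A switch is
    valid when it creates no self-loop and no already-existing edge.
    """
    kind = kind or graph_kind(graph)
    E = edge_set(graph)
    switches: list[Switch] = []
    if kind in ("directed", "bipartite"):
        arcs = sorted(E)
        for (x, y), (u, v) in combinations(arcs, 2):
            if kind == "bipartite":
                ok = y != v and x != u and (x, v) not in E and (u, y) not in E
            else:
                ok = _valid_directed_switch(E, x, y, u, v)
            if ok:
                switches.append(Switch(((x, y), (u, v)), ((x, v), (u, y))))
        return switches
    # undirected: consider both re-pairings of every edge pair
    edges = sorted(tuple(sorted(e)) for e in E)
    for (x, y), (u, v) in combinations(edges, 2):
        for (p1, p2) in ((frozenset((x, v)), frozenset((u, y))),
                         (frozenset((x, u)), frozenset((y, v)))):
            if len(p1) != 2 or len(p2) != 2 or p1 == p2:
                continue
            if p1 in E or p2 in E:
                continue
            switches.append(Switch(
                (frozenset((x, y)), frozenset((u, v))), (p1, p2)))
    return switches


def apply_switch(graph: Graph, switch: Switch) -> Graph:
    """Commit a switch in place (no validity re-check beyond membership)."""
    kind = graph_kind(graph)
    adj = _adjacency_list(graph)
    if kind == "undirected":
        for e in switch.edges_before:
            a, b = tuple(e)
            adj[a].discard(b)
            adj[b].discard(a)
        for e in switch.edges_after:
            a, b = tuple(e)
            adj[a].add(b)
            adj[b].add(a)
    else:
        for a, b in switch.edges_before:
            adj[a].discard(b)
        for a, b in switch.edges_after:
            adj[a].add(b)
    return graph


def trades_realizing_switch(G: Graph, G_prime: Graph,
                            kind: Kind | None = None) -> list[TradeProposal]:
    """Exhaustively list the size-one trades transforming G into G_prime.

    Preconditions: identical degree sequences and an edge-set difference of
    exactly one switch (two edges removed, two added).  Returns every
    distinct ``(pair, exchanged elements)`` proposal whose application
    yields G_prime.
    """
    from .graphs import degrees  # local import to avoid cycle at module load

    kind = kind or graph_kind(G)
    if degrees(G) != degrees(G_prime):
        raise InvalidPairError("graphs do not share a degree sequence")
    E, E2 = edge_set(G), edge_set(G_prime)
    if E == E2:
        return []
    if len(E - E2) != 2 or len(E2 - E) != 2:
        raise InvalidPairError("graphs do not differ by exactly one switch")

    target = E2
    found: list[TradeProposal] = []
    n_sets = len(_adjacency_list(G))
    for i, j in combinations(range(n_sets), 2):
        A_i, A_j = _adjacency_of(G, i), _adjacency_of(G, j)
        if kind == "bipartite":
            t_i, t_j = A_i - A_j, A_j - A_i
        else:
            t_i, t_j = tradeable_sets(A_i, A_j, i, j)
        for a in sorted(t_i):
            for b in sorted(t_j):
                prop = size_one_trade(G, i, j, a, b)
                trial = G.copy()
                apply_trade(trial, prop)
                if edge_set(trial) == target:
                    found.append(prop)
    return found
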