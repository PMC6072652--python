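"""Synthetic network ensembles and the package's toy fixtures.

Two generator families mirror the conditions under which trade chains are
usually benchmarked: Erdős–Rényi G(n, m) graphs (n drawn uniformly from a
range, m = d·n with the average degree d drawn uniformly from a range) and
sequentially grown preferential-attachment graphs whose out-degrees are
uniform on {1, 2, 3} — the sparse, hub-dominated regime in which trades
rarely move more than one element and the Curveball advantage over
single-swap chains narrows.

``realize_degree_sequence`` builds one simple realization from bare
degrees (Havel–Hakimi style), which is the natural chain starting point
when a user supplies only margins.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Literal

import networkx as nx

from .errors import ConfigError, DegreeSequenceError
from .graphs import (
    BipartiteState,
    DegreeSequence,
    DirectedGraph,
    Graph,
    UndirectedGraph,
    degrees,
)

__all__ = [
    "EnsembleSpec",
    "er_gnm",
    "ba_network",
    "sample_ensemble",
    "realize_degree_sequence",
    "fixtures",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """Parameters of a synthetic benchmark ensemble.

    ``n_range`` bounds the node count (inclusive); for the ER model
    ``d_range`` bounds the average degree d (m = d * n), for the
    preferential-attachment model it is ignored (out-degrees are always
    uniform on {1, 2, 3}).
    """

    model: Literal["er", "ba"]
    kind: Literal["directed", "undirected"]
    n_range: tuple[int, int]
    d_range: tuple[int, int]
    replicates: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("er", "ba"):
            raise ConfigError(f"unknown model {self.model!r}")
        if self.kind not in ("directed", "undirected"):
            raise ConfigError(f"unknown kind {self.kind!r}")
        if not (3 <= self.n_range[0] <= self.n_range[1] <= 10**6):
            raise ConfigError("n_range must satisfy 3 <= lo <= hi <= 1e6")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")


def er_gnm(n: int, m: int, kind: Literal["directed", "undirected"],
           rng: random.Random) -> Graph:
    """Uniform simple graph with exactly ``m`` edges on ``n`` nodes."""
    capacity = n * (n - 1) if kind == "directed" else n * (n - 1) // 2
    if m > capacity:
        raise ConfigError(f"m={m} exceeds the {capacity} possible simple edges")
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < m:
        i = rng.randrange(n)
        j = rng.randrange(n - 1)
        if j >= i:
            j += 1
        if kind == "undirected" and i > j:
            i, j = j, i
        chosen.add((i, j))
    if kind == "directed":
        adj: list[set[int]] = [set() for _ in range(n)]
        for i, j in chosen:
            adj[i].add(j)
        return DirectedGraph(n, adj)
    adj = [set() for _ in range(n)]
    for i, j in chosen:
        adj[i].add(j)
        adj[j].add(i)
    return UndirectedGraph(n, adj)


def ba_network(n: int, kind: Literal["directed", "undirected"],
               rng: random.Random) -> Graph:
    """Sequential preferential attachment with out-degree uniform on {1,2,3}.

    Each arriving node v draws k ~ U{1,2,3} (capped by the number of
    existing nodes) and attaches to k distinct existing targets chosen
    with probability proportional to in-degree + 1 (directed) or
    degree + 1 (undirected).  The +1 smoothing lets degree-zero seeds be
    chosen at all.
    """
    if n < 4:
        raise ConfigError("preferential attachment needs n >= 4")
    adj: list[set[int]] = [set() for _ in range(n)]
    weight = [1] * n  # in-degree + 1 (directed) or degree + 1 (undirected)
    for v in range(1, n):
        k = min(rng.randint(1, 3), v)
        targets: set[int] = set()
        while len(targets) < k:
            total = sum(weight[u] for u in range(v) if u not in targets)
            pick = rng.random() * total
            acc = 0.0
            for u in range(v):
                if u in targets:
                    continue
                acc += weight[u]
                if pick < acc:
                    targets.add(u)
                    break
        for u in targets:
            adj[v].add(u)
            weight[u] += 1
            if kind == "undirected":
                adj[u].add(v)
                weight[v] += 1
    if kind == "directed":
        return DirectedGraph(n, adj)
    return UndirectedGraph(n, adj)


def sample_ensemble(spec: EnsembleSpec) -> list[Graph]:
    """Draw ``spec.replicates`` independent networks from the spec."""
    rng = random.Random(spec.seed)
    graphs: list[Graph] = []
    for _ in range(spec.replicates):
        n = rng.randint(*spec.n_range)
        if spec.model == "er":
            d = rng.randint(*spec.d_range)
            graphs.append(er_gnm(n, d * n, spec.kind, rng))
        else:
            graphs.append(ba_network(n, spec.kind, rng))
    return graphs


def realize_degree_sequence(ds: DegreeSequence) -> Graph:
    """One simple realization of a degree sequence, or raise.

    Undirected sequences go through the Havel–Hakimi construction,
    directed ones through its bidegree analogue (both via networkx);
    bipartite margins are filled greedily Gale–Ryser style, largest rows
    first into the currently fullest columns.
    """
    if ds.kind == "undirected":
        if not nx.is_graphical(ds.degrees):
            raise DegreeSequenceError(
                f"degree sequence {ds.degrees} is not graphical "
                "(Erdős–Gallai conditions fail)")
        g = nx.havel_hakimi_graph(list(ds.degrees))
        adj = [set(g.neighbors(i)) for i in range(len(ds.degrees))]
        return UndirectedGraph(len(ds.degrees), adj)
    if ds.kind == "directed":
        if not nx.is_digraphical(ds.in_degrees, ds.out_degrees):
            raise DegreeSequenceError(
                f"in={ds.in_degrees}, out={ds.out_degrees} is not digraphical "
                "(Fulkerson conditions fail)")
        g = nx.directed_havel_hakimi_graph(list(ds.in_degrees), list(ds.out_degrees))
        n = len(ds.in_degrees)
        adj = [set(g.successors(i)) for i in range(n)]
        return DirectedGraph(n, adj)
    # bipartite: greedy Gale–Ryser filling
    nr, nc = len(ds.row_sums), len(ds.col_sums)
    residual = list(ds.col_sums)
    rows: list[set[int]] = [set() for _ in range(nr)]
    for r in sorted(range(nr), key=lambda r: -ds.row_sums[r]):
        cols = sorted(range(nc), key=lambda c: -residual[c])[: ds.row_sums[r]]
        if len(cols) < ds.row_sums[r] or any(residual[c] <= 0 for c in cols):
            raise DegreeSequenceError(
                f"rows {ds.row_sums}, cols {ds.col_sums} violate the "
                "Gale–Ryser conditions")
        for c in cols:
            residual[c] -= 1
            rows[r].add(c)
    if any(residual):
        raise DegreeSequenceError(
            f"rows {ds.row_sums}, cols {ds.col_sums} violate the "
            "Gale–Ryser conditions")
    result = BipartiteState(nr, nc, rows)
    assert degrees(result) == ds
    return result


def fixtures() -> dict[str, Graph]:
    """Small named graphs used across examples, docs and tests.

    ``oriented_triangle``
        The arcs (0,1), (1,2), (2,0): the minimal directed graph on which
        no switch or non-trivial trade applies, yet whose reversal is a
        second realization of the same degrees.
    ``directed_pair``
        Ten directed nodes where the out-sets of nodes 8 and 9 share two
        neighbours and 9 points at 8; the tradeable union between 8 and 9
        is {1, 2, 5, 6, 7}.
    ``undirected_pair``
        Eight undirected nodes where neighbours 6 and 7 share node 3; the
        tradeable union between 6 and 7 is {1, 2, 4, 5}.
    ``bipartite_margins1``
        The 3x3 identity biadjacency: all margins 1, a 6-state space.
    ``undirected_5node``
        Degrees (2, 2, 2, 1, 1): a small enumerable undirected space.
    """
    oriented_triangle = DirectedGraph(3, [{1}, {2}, {0}])
    directed_pair = DirectedGraph(
        10, [set(), set(), set(), set(), set(), set(), set(), set(),
             {1, 2, 3, 4},            # node 8 ("i")
             {8, 3, 4, 5, 6, 7}])     # node 9 ("j"), 8 is an out-neighbour
    undirected_pair = UndirectedGraph(
        8, [set(),                    # 0 isolated
            {6}, {6}, {6, 7}, {7}, {7},
            {7, 3, 1, 2},             # node 6 ("i")
            {6, 3, 4, 5}])            # node 7 ("j")
    bipartite_margins1 = BipartiteState(3, 3, [{0}, {1}, {2}])
    undirected_5node = UndirectedGraph(5, [{3, 1}, {0, 2}, {1, 4}, {0}, {2}])
    return {
        "oriented_triangle": oriented_triangle,
        "directed_pair": directed_pair,
        "undirected_pair": undirected_pair,
        "bipartite_margins1": bipartite_margins1,
        "undirected_5node": undirected_5node,
    }
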