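"""Markov chain runners for the trade and switch randomization moves.

Three variants share one step-count semantics (every attempted move is one
step, including rejected switches and size-zero trades, so perturbation
traces are comparable at equal x-coordinates):

``curveball``
    Draw an unordered pair of distinct adjacency sets uniformly and commit
    a full trade.
``restricted_size1``
    Draw a pair exactly like the Curveball, but exchange at most one
    uniformly chosen element per side — the switching model dressed as a
    trade, used as the mixing baseline.
``switching``
    Draw two edges uniformly and attempt the classic switch, rejecting
    moves that would create self-loops or duplicate edges.

A single seeded ``random.Random`` stream drives every choice, consumed in
a fixed order (pair first, then subset/elements), so a chain is
bit-reproducible from ``(input, seed)``.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal

from .errors import ConfigError
from .graphs import (
    BipartiteState,
    DirectedGraph,
    Graph,
    Kind,
    UndirectedGraph,
    edge_set,
    graph_kind,
)
from .moves import (
    apply_switch,
    apply_trade,
    bipartite_trade,
    directed_trade,
    size_one_trade,
    tradeable_sets,
    undirected_trade,
)

Variant = Literal["curveball", "switching", "restricted_size1"]

__all__ = ["ChainConfig", "ChainResult", "run_chain",
           "chain_step", "switching_step", "restricted_size1_step"]


@dataclass(frozen=True)
class ChainConfig:
    """Parameters of one randomization run."""

    n_steps: int
    kind: Kind
    variant: Variant = "curveball"
    seed: int = 0
    record_every: int | None = None

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ConfigError("n_steps must be >= 0")
        if self.variant not in ("curveball", "switching", "restricted_size1"):
            raise ConfigError(f"unknown variant {self.variant!r}")
        if self.kind not in ("bipartite", "directed", "undirected"):
            raise ConfigError(f"unknown kind {self.kind!r}")
        if self.record_every is not None:
            if self.record_every <= 0:
                raise ConfigError("record_every must be positive")
            if self.record_every > self.n_steps:
                raise ConfigError("record_every must not exceed n_steps")


@dataclass
class ChainResult:
    """Final state plus bookkeeping of one chain run."""

    final_graph: Graph
    steps_recorded: list[int] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    accepted_sizes: Counter = field(default_factory=Counter)
    n_zero_trades: int = 0


def _n_sets(graph: Graph) -> int:
    return graph.n_rows if isinstance(graph, BipartiteState) else graph.n_nodes


def _draw_pair(n: int, rng: random.Random) -> tuple[int, int]:
    """Uniform unordered pair of distinct indices (two fixed draws)."""
    i = rng.randrange(n)
    j = rng.randrange(n - 1)
    if j >= i:
        j += 1
    return i, j


def chain_step(graph: Graph, kind: Kind, variant: Variant,
               rng: random.Random) -> int:
    """Advance ``graph`` by one step in place; return the trade size.

    Rejected switches and size-zero trades return 0.
    """
    if variant == "switching":
        return switching_step(graph, kind, rng)
    if variant == "restricted_size1":
        return restricted_size1_step(graph, kind, rng)
    i, j = _draw_pair(_n_sets(graph), rng)
    if kind == "bipartite":
        prop = bipartite_trade(graph, i, j, rng)
    elif kind == "directed":
        prop = directed_trade(graph, i, j, rng)
    else:
        prop = undirected_trade(graph, i, j, rng)
    apply_trade(graph, prop)
    return prop.size


def switching_step(graph: Graph, kind: Kind, rng: random.Random) -> int:
    """One classic switch attempt: sample two edges, rewire if legal.

    For undirected graphs the two sampled edges are given random endpoint
    orientations, so both re-pairings of an edge pair are proposed with
    equal probability.  Returns 1 if the switch was committed, else 0.
    """
    E = edge_set(graph)
    if kind == "undirected":
        edges = sorted(tuple(sorted(e)) for e in E)
    else:
        edges = sorted(E)
    if len(edges) < 2:
        return 0
    e1 = edges[rng.randrange(len(edges))]
    e2 = edges[rng.randrange(len(edges))]
    if e1 == e2:
        return 0
    if kind == "undirected":
        # random endpoint orientation so both re-pairings are proposable
        x, y = e1 if rng.random() < 0.5 else e1[::-1]
        u, v = e2 if rng.random() < 0.5 else e2[::-1]
        new1, new2 = frozenset((x, v)), frozenset((u, y))
        if len(new1) != 2 or len(new2) != 2 or new1 == new2:
            return 0
        if new1 in E or new2 in E:
            return 0
        adj = graph.adjacency
        adj[x].discard(y); adj[y].discard(x)
        adj[u].discard(v); adj[v].discard(u)
        adj[x].add(v); adj[v].add(x)
        adj[u].add(y); adj[y].add(u)
        return 1
    x, y = e1
    u, v = e2
    if kind == "bipartite":
        ok = y != v and x != u and (x, v) not in E and (u, y) not in E
    else:
        ok = (x != v and u != y and (x, v) not in E and (u, y) not in E
              and (x, v) != (u, y))
    if not ok:
        return 0
    if kind == "bipartite":
        graph.rows[x].discard(y)
        graph.rows[u].discard(v)
        graph.rows[x].add(v)
        graph.rows[u].add(y)
    else:
        graph.out_adjacency[x].discard(y)
        graph.out_adjacency[u].discard(v)
        graph.out_adjacency[x].add(v)
        graph.out_adjacency[u].add(y)
    return 1


def restricted_size1_step(graph: Graph, kind: Kind, rng: random.Random) -> int:
    """One size-1-restricted trade step.

    The pair is drawn exactly as in the Curveball; if both tradeable sets
    are non-empty, one uniformly chosen element from each side is
    exchanged (with the symmetric repair for undirected graphs).
    """
    i, j = _draw_pair(_n_sets(graph), rng)
    if kind == "bipartite":
        A_i, A_j = graph.rows[i], graph.rows[j]
        t_i, t_j = A_i - A_j, A_j - A_i
    else:
        adj = graph.out_adjacency if kind == "directed" else graph.adjacency
        t_i, t_j = tradeable_sets(adj[i], adj[j], i, j)
    if not t_i or not t_j:
        return 0
    a = sorted(t_i)[rng.randrange(len(t_i))]
    b = sorted(t_j)[rng.randrange(len(t_j))]
    apply_trade(graph, size_one_trade(graph, i, j, a, b))
    return 1


def run_chain(graph: Graph, config: ChainConfig) -> ChainResult:
    """Run a randomization chain; the input graph is left untouched.

    When ``record_every`` is set, the perturbation score against the
    starting network is recorded at every multiple of ``record_every``.
    Identical ``(graph, config)`` always yields an identical result.
    """
    if graph_kind(graph) != config.kind:
        raise ConfigError(
            f"graph kind {graph_kind(graph)!r} does not match config.kind "
            f"{config.kind!r}")
    from .diagnostics import perturbation_score  # deferred: module cycle

    rng = random.Random(config.seed)
    work = graph.copy()
    result = ChainResult(final_graph=work)
    for step in range(1, config.n_steps + 1):
        size = chain_step(work, config.kind, config.variant, rng)
        result.accepted_sizes[size] += 1
        if size == 0:
            result.n_zero_trades += 1
        if config.record_every is not None and step % config.record_every == 0:
            result.steps_recorded.append(step)
            result.scores.append(perturbation_score(graph, work))
    return result
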