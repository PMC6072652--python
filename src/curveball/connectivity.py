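"""Directed-chain connectivity repair: frozen 3-cycles and re-orientation.

Switches (and hence trades, which are compositions of switches) cannot
reverse every directed 3-cycle: the isolated oriented triangle
(0,1), (1,2), (2,0) admits no valid switch at all, yet its reversal is a
distinct realization of the same in/out degree sequence.  Sampling the
full realization space therefore needs one extra preprocessing move:
detect the *frozen* (non-switchable) 3-cycles and give each an independent
uniformly random orientation before running the trade chain.

``is_frozen`` implements a local criterion — a 3-cycle is flagged when
none of its three arcs participates in any valid switch with any other
arc, and its reversal yields a valid simple graph.  This is a conservative
surrogate for the exact graph-theoretic characterization and is certified
empirically: the test suite checks it against a brute-force
switch-reachability oracle on every small instance it uses.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import InvalidPairError, SizeLimitError
from .graphs import DirectedGraph, degrees, edge_set

__all__ = [
    "Triangle",
    "find_directed_3cycles",
    "is_frozen",
    "reorient_frozen_triangles",
    "reachability_oracle",
    "StateSpacePartition",
]


@dataclass(frozen=True)
class Triangle:
    """A directed 3-cycle a -> b -> c -> a, canonical rotation (a minimal)."""

    nodes: tuple[int, int, int]

    @property
    def arcs(self) -> tuple[tuple[int, int], ...]:
        a, b, c = self.nodes
        return ((a, b), (b, c), (c, a))

    @property
    def reversed_arcs(self) -> tuple[tuple[int, int], ...]:
        a, b, c = self.nodes
        return ((b, a), (c, b), (a, c))


def find_directed_3cycles(graph: DirectedGraph) -> list[Triangle]:
    """All directed 3-cycles, each reported once (smallest node first)."""
    adj = graph.out_adjacency
    found: list[Triangle] = []
    n = graph.n_nodes
    for a in range(n):
        for b in adj[a]:
            if b <= a:
                continue
            for c in adj[b]:
                if c <= a or c == b:
                    continue
                if a in adj[c]:
                    found.append(Triangle((a, b, c)))
    return found


def is_frozen(triangle: Triangle, graph: DirectedGraph) -> bool:
    """True iff no arc of the 3-cycle can take part in any valid switch
    and the reversed orientation is itself a valid simple graph.

    A frozen cycle's orientation is invariant under the switch (and trade)
    chain, so the two orientations lie in different reachability classes.
    """
    E = edge_set(graph)
    tri_arcs = set(triangle.arcs)
    if not tri_arcs <= E:
        raise InvalidPairError(f"triangle {triangle.nodes} is not in the graph")
    # a reversal that collides with an existing reciprocal arc is not a
    # realization, hence nothing to re-orient
    if any(arc in E for arc in triangle.reversed_arcs):
        return False
    for (x, y) in tri_arcs:
        for (u, v) in E:
            if (u, v) == (x, y):
                continue
            for (p, q), (r, s) in (((x, y), (u, v)), ((u, v), (x, y))):
                # switch (p,q),(r,s) -> (p,s),(r,q)
                if p == s or r == q:
                    continue
                if (p, s) in E or (r, q) in E or (p, s) == (r, q):
                    continue
                return False
    return True


def reorient_frozen_triangles(graph: DirectedGraph,
                              rng: random.Random) -> DirectedGraph:
    """Copy ``graph`` with every frozen 3-cycle independently kept or
    reversed with probability 1/2.

    Degrees are preserved; non-frozen cycles are untouched.  This is a
    one-shot preprocessing step to run before the trade chain whenever the
    statistic of interest depends on node identities.
    """
    out = graph.copy()
    for tri in find_directed_3cycles(graph):
        if not is_frozen(tri, graph):
            continue
        if rng.random() < 0.5:
            adj = out.out_adjacency
            for (a, b) in tri.arcs:
                adj[a].discard(b)
            for (a, b) in tri.reversed_arcs:
                adj[a].add(b)
    return out


# ---------------------------------------------------------------------------
# brute-force reachability oracle


@dataclass
class StateSpacePartition:
    """All realizations of a degree sequence, split into switch classes."""

    realizations: list[DirectedGraph]
    classes: list[list[int]]
    start_index: int

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def reachability_oracle(graph: DirectedGraph,
                        max_nodes: int = 10, max_arcs: int = 20
                        ) -> StateSpacePartition:
    """Enumerate every realization of ``degrees(graph)`` and partition the
    space into switch-connectivity classes by breadth-first search over
    single switches.

    Brute force: only small instances are accepted.
    """
    from .diagnostics import enumerate_realizations, realization_key
    from .moves import apply_switch, enumerate_switches

    if graph.n_nodes > max_nodes:
        raise SizeLimitError(f"{graph.n_nodes} nodes exceeds limit {max_nodes}")
    if graph.n_edges > max_arcs:
        raise SizeLimitError(f"{graph.n_edges} arcs exceeds limit {max_arcs}")

    space = enumerate_realizations(degrees(graph), max_nodes=max_nodes)
    index = {realization_key(g): k for k, g in enumerate(space.realizations)}
    start = index[realization_key(graph)]

    n = len(space.realizations)
    seen = [False] * n
    classes: list[list[int]] = []
    for root in range(n):
        if seen[root]:
            continue
        component = []
        queue = [root]
        seen[root] = True
        while queue:
            k = queue.pop()
            component.append(k)
            g = space.realizations[k]
            for sw in enumerate_switches(g, "directed"):
                h = apply_switch(g.copy(), sw)
                m = index[realization_key(h)]
                if not seen[m]:
                    seen[m] = True
                    queue.append(m)
        classes.append(sorted(component))
    return StateSpacePartition(space.realizations, classes, start)
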