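"""Convergence and unbiasedness instrumentation.

Two questions matter for a degree-preserving randomization chain: how fast
it moves away from its starting network (mixing), and whether it samples
every realization of the degree sequence equally often (unbiasedness).

Mixing is tracked with the *perturbation score*, the fraction of the
original network's edges that are absent from the randomized network — a
cheap proxy that climbs from 0 towards its ensemble plateau as the chain
forgets its start.  Unbiasedness is tested exactly on small instances: the
full realization space of a degree sequence is enumerated by brute force
and the empirical visit counts of a chain are compared to the uniform
distribution with a Pearson chi-square test.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import pandas as pd
from itertools import combinations
from scipy import stats

from .chains import ChainConfig, Variant, chain_step, run_chain
from .errors import ConfigError, ContaminationError, SizeLimitError
from .graphs import (
    BipartiteState,
    DegreeSequence,
    DirectedGraph,
    Graph,
    Kind,
    UndirectedGraph,
    degrees,
    edge_set,
    graph_kind,
)

__all__ = [
    "perturbation_score",
    "PerturbationTrace",
    "StateSpace",
    "enumerate_realizations",
    "realization_key",
    "UniformityReport",
    "uniformity_test",
    "convergence_experiment",
]


@dataclass(frozen=True)
class PerturbationTrace:
    """(step, score) pairs recording distance from the starting network."""

    steps: tuple[int, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.steps) != len(self.scores):
            raise ConfigError("steps and scores must have equal length")
        if any(not 0.0 <= s <= 1.0 for s in self.scores):
            raise ConfigError("perturbation scores must lie in [0, 1]")


def perturbation_score(original: Graph, randomized: Graph) -> float:
    """Fraction of the original's edges absent from the randomized graph.

    Both graphs must be of the same kind with the same degree sequence
    (the setting in which a chain produced one from the other); the score
    is then symmetric in its arguments.
    """
    if graph_kind(original) != graph_kind(randomized):
        raise ConfigError("graphs must be of the same kind")
    if degrees(original) != degrees(randomized):
        raise ConfigError("graphs must share a degree sequence")
    E = edge_set(original)
    if not E:
        return 0.0
    return len(E - edge_set(randomized)) / len(E)


# ---------------------------------------------------------------------------
# exhaustive realization spaces


@dataclass
class StateSpace:
    """All realizations of a degree sequence, canonically ordered."""

    degree_sequence: DegreeSequence
    realizations: list[Graph]

    def __len__(self) -> int:
        return len(self.realizations)

    def index(self) -> dict[str, int]:
        return {realization_key(g): k for k, g in enumerate(self.realizations)}


def realization_key(graph: Graph) -> str:
    """Canonical hashable key: the flattened 0/1 matrix as a bit-string."""
    if isinstance(graph, BipartiteState):
        return "".join(
            "1" if c in row else "0"
            for row in graph.rows for c in range(graph.n_cols))
    if isinstance(graph, DirectedGraph):
        n = graph.n_nodes
        return "".join(
            "1" if j in graph.out_adjacency[i] else "0"
            for i in range(n) for j in range(n))
    n = graph.n_nodes
    return "".join(
        "1" if j in graph.adjacency[i] else "0"
        for i in range(n) for j in range(n))


def _enumerate_margin_rows(row_sums: tuple[int, ...], col_caps: list[int],
                           n_cols: int, forbidden_diag: bool):
    """Yield lists of column sets, one per row, with prescribed row sums
    and column sums; ``forbidden_diag`` excludes cell (i, i)."""
    n_rows = len(row_sums)

    def cap(c: int, next_row: int) -> int:
        # rows next_row..n_rows-1 may still place a 1 in column c,
        # except row c itself when the diagonal is forbidden
        k = n_rows - next_row
        if forbidden_diag and next_row <= c < n_rows:
            k -= 1
        return k

    def rec(r: int, residual: list[int], acc: list[set[int]]):
        if r == n_rows:
            if all(x == 0 for x in residual):
                yield [set(s) for s in acc]
            return
        candidates = [c for c in range(n_cols)
                      if residual[c] > 0 and not (forbidden_diag and c == r)]
        need = row_sums[r]
        if need > len(candidates):
            return
        for combo in combinations(candidates, need):
            for c in combo:
                residual[c] -= 1
            if all(residual[c] <= cap(c, r + 1) for c in range(n_cols)):
                acc.append(set(combo))
                yield from rec(r + 1, residual, acc)
                acc.pop()
            for c in combo:
                residual[c] += 1

    yield from rec(0, list(col_caps), [])


def enumerate_realizations(ds: DegreeSequence, max_nodes: int = 7,
                           max_cells: int = 36) -> StateSpace:
    """Exhaustively enumerate every simple graph realizing ``ds``.

    Brute force with column-sum pruning; refuses instances beyond
    ``max_nodes`` (unimode) or ``max_cells`` (bipartite).  An unrealizable
    sequence yields an empty space, not an error.
    """
    if ds.kind == "bipartite":
        nr, nc = len(ds.row_sums), len(ds.col_sums)
        if nr * nc > max_cells:
            raise SizeLimitError(f"{nr}x{nc} biadjacency exceeds {max_cells} cells")
        reals: list[Graph] = [
            BipartiteState(nr, nc, rows)
            for rows in _enumerate_margin_rows(ds.row_sums, list(ds.col_sums),
                                               nc, forbidden_diag=False)
        ]
    elif ds.kind == "directed":
        n = len(ds.out_degrees)
        if n > max_nodes:
            raise SizeLimitError(f"{n} nodes exceeds limit {max_nodes}")
        reals = [
            DirectedGraph(n, rows)
            for rows in _enumerate_margin_rows(ds.out_degrees, list(ds.in_degrees),
                                               n, forbidden_diag=True)
        ]
    elif ds.kind == "undirected":
        n = len(ds.degrees)
        if n > max_nodes:
            raise SizeLimitError(f"{n} nodes exceeds limit {max_nodes}")
        reals = list(_enumerate_undirected(ds.degrees))
    else:  # pragma: no cover - DegreeSequence validates kind
        raise ConfigError(f"unknown kind {ds.kind!r}")
    reals.sort(key=realization_key)
    return StateSpace(ds, reals)


def _enumerate_undirected(deg: tuple[int, ...]):
    """All simple undirected graphs with the given degree sequence.

    Processes nodes in order; node i chooses its neighbours among j > i to
    satisfy its residual degree (edges to j < i were fixed earlier)."""
    n = len(deg)

    def rec(i: int, residual: list[int], adj: list[set[int]]):
        if i == n:
            if all(x == 0 for x in residual):
                yield UndirectedGraph(n, [set(s) for s in adj])
            return
        need = residual[i]
        later = [j for j in range(i + 1, n) if residual[j] > 0]
        if need > len(later):
            return
        for combo in combinations(later, need):
            for j in combo:
                residual[j] -= 1
                adj[i].add(j)
                adj[j].add(i)
            residual[i] = 0
            yield from rec(i + 1, residual, adj)
            residual[i] = need
            for j in combo:
                residual[j] += 1
                adj[i].discard(j)
                adj[j].discard(i)

    yield from rec(0, list(deg), [set() for _ in range(n)])


# ---------------------------------------------------------------------------
# uniformity testing


@dataclass
class UniformityReport:
    """Chi-square comparison of chain visit counts with uniformity."""

    n_states: int
    counts: list[int]
    statistic: float
    pvalue: float

    @property
    def n_samples(self) -> int:
        return sum(self.counts)


def uniformity_test(graph: Graph, space: StateSpace, *,
                    variant: Variant = "curveball",
                    n_samples: int = 60_000, burn_in: int = 1_000,
                    spacing: int = 10, seed: int = 0,
                    reorient: bool = False,
                    independent_runs: bool = False) -> UniformityReport:
    """Sample a chain started at ``graph`` and chi-square its visit counts
    against the uniform distribution over ``space``.

    By default one long chain is run: ``burn_in`` steps are discarded, then
    a state is retained every ``spacing`` steps.  With
    ``independent_runs=True`` each retained sample comes from a fresh run
    of ``burn_in`` steps (preceded by frozen-triangle re-orientation when
    ``reorient`` is set); this is the mode needed to measure unbiasedness
    across switch-disconnected classes, which a single chain cannot cross.

    Any sample falling outside ``space`` raises
    :class:`~curveball.errors.ContaminationError` — that signals a broken
    move, not bad luck.
    """
    from .connectivity import reorient_frozen_triangles

    kind = graph_kind(graph)
    index = space.index()
    counts = [0] * len(space)
    rng = random.Random(seed)

    def register(g: Graph) -> None:
        key = realization_key(g)
        if key not in index:
            raise ContaminationError(
                f"sampled graph {key} is not a realization of the degree sequence")
        counts[index[key]] += 1

    if independent_runs:
        for _ in range(n_samples):
            start = graph
            if reorient and kind == "directed":
                start = reorient_frozen_triangles(graph, rng)
            work = start.copy()
            for _ in range(burn_in):
                chain_step(work, kind, variant, rng)
            register(work)
    else:
        work = graph
        if reorient and kind == "directed":
            work = reorient_frozen_triangles(graph, rng)
        work = work.copy()
        for _ in range(burn_in):
            chain_step(work, kind, variant, rng)
        for _ in range(n_samples):
            for _ in range(spacing):
                chain_step(work, kind, variant, rng)
            register(work)

    statistic, pvalue = stats.chisquare(counts)
    return UniformityReport(len(space), counts, float(statistic), float(pvalue))


# ---------------------------------------------------------------------------
# convergence experiment (perturbation traces for chain comparison)


def convergence_experiment(networks: list[Graph], *, n_steps: int,
                           record_every: int,
                           variants: tuple[Variant, ...] = ("curveball",
                                                            "restricted_size1"),
                           seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run competing chain variants from the same starts and tabulate
    perturbation traces.

    Every network is randomized once per variant (same per-network seed for
    each variant, so starts and pair draws are comparable), recording the
    perturbation score every ``record_every`` steps.  Returns a tidy trace
    table ``(network_id, variant, step, score)`` and a per-variant/step
    summary with mean and standard deviation across networks.
    """
    if record_every <= 0 or n_steps // record_every == 0:
        raise ConfigError("configuration records zero steps")
    rows = []
    for net_id, graph in enumerate(networks):
        kind = graph_kind(graph)
        for variant in variants:
            config = ChainConfig(n_steps=n_steps, kind=kind, variant=variant,
                                 seed=seed + net_id, record_every=record_every)
            result = run_chain(graph, config)
            for step, score in zip(result.steps_recorded, result.scores):
                rows.append((net_id, variant, step, score))
    traces = pd.DataFrame(rows, columns=["network_id", "variant", "step", "score"])
    summary = (traces.groupby(["variant", "step"])["score"]
               .agg(["mean", "std"]).reset_index())
    return traces, summary
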