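"""Core graph containers, degree bookkeeping, validation and text I/O.

All randomization moves in this package operate on adjacency *sets*: an
undirected network stores one neighbour set per node (each edge appears in
two sets), a directed network stores one out-neighbour set per node, and a
bipartite network is stored as its biadjacency rows, i.e. one column-index
set per row.  Nodes are 0-based contiguous integers internally; arbitrary
string labels from input files are kept on the side for write-back.

Self-loops and multiple edges are excluded throughout: the chains sample
from the space of *simple* graphs with a fixed degree sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

from .errors import DegreeSequenceError, GraphValidationError, ParseError

logger = logging.getLogger(__name__)

Kind = Literal["bipartite", "directed", "undirected"]

__all__ = [
    "UndirectedGraph",
    "DirectedGraph",
    "BipartiteState",
    "DegreeSequence",
    "ValidationReport",
    "read_edge_list",
    "write_edge_list",
    "read_biadjacency",
    "write_biadjacency",
    "degrees",
    "edge_set",
    "validate",
    "graph_kind",
]


@dataclass
class UndirectedGraph:
    """Simple undirected graph as a list of neighbour sets.

    Each edge {i, j} is represented twice: ``j in adjacency[i]`` and
    ``i in adjacency[j]``.
    """

    n_nodes: int
    adjacency: list[set[int]]
    labels: list[str] | None = None

    def copy(self) -> "UndirectedGraph":
        return UndirectedGraph(self.n_nodes, [set(s) for s in self.adjacency], self.labels)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.adjacency) // 2


@dataclass
class DirectedGraph:
    """Simple directed graph as a list of out-neighbour sets.

    Reciprocal arc pairs (i->j and j->i) are allowed; parallel arcs and
    self-loops are not.
    """

    n_nodes: int
    out_adjacency: list[set[int]]
    labels: list[str] | None = None

    def copy(self) -> "DirectedGraph":
        return DirectedGraph(self.n_nodes, [set(s) for s in self.out_adjacency], self.labels)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.out_adjacency)


@dataclass
class BipartiteState:
    """Binary biadjacency matrix stored as one column-index set per row."""

    n_rows: int
    n_cols: int
    rows: list[set[int]]
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def copy(self) -> "BipartiteState":
        return BipartiteState(
            self.n_rows, self.n_cols, [set(s) for s in self.rows],
            self.row_labels, self.col_labels,
        )

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.rows)


Graph = UndirectedGraph | DirectedGraph | BipartiteState


@dataclass(frozen=True)
class DegreeSequence:
    """Per-node edge counts, the invariant preserved by every move.

    Exactly one field group is populated depending on ``kind``:
    ``degrees`` (undirected), ``in_degrees``/``out_degrees`` (directed), or
    ``row_sums``/``col_sums`` (bipartite).
    """

    kind: Kind
    degrees: tuple[int, ...] | None = None
    in_degrees: tuple[int, ...] | None = None
    out_degrees: tuple[int, ...] | None = None
    row_sums: tuple[int, ...] | None = None
    col_sums: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        for seq in (self.degrees, self.in_degrees, self.out_degrees,
                    self.row_sums, self.col_sums):
            if seq is not None and any(d < 0 for d in seq):
                raise DegreeSequenceError("degree entries must be non-negative")
        if self.kind == "undirected":
            if self.degrees is None:
                raise DegreeSequenceError("undirected sequence needs `degrees`")
            if sum(self.degrees) % 2:
                raise DegreeSequenceError("undirected degree sum must be even")
        elif self.kind == "directed":
            if self.in_degrees is None or self.out_degrees is None:
                raise DegreeSequenceError("directed sequence needs in and out degrees")
            if len(self.in_degrees) != len(self.out_degrees):
                raise DegreeSequenceError("in/out degree length mismatch")
            if sum(self.in_degrees) != sum(self.out_degrees):
                raise DegreeSequenceError("sum(in) must equal sum(out)")
        elif self.kind == "bipartite":
            if self.row_sums is None or self.col_sums is None:
                raise DegreeSequenceError("bipartite sequence needs row and column sums")
            if sum(self.row_sums) != sum(self.col_sums):
                raise DegreeSequenceError("sum of row sums must equal sum of column sums")
        else:
            raise DegreeSequenceError(f"unknown kind {self.kind!r}")


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`; violations are data, not exceptions."""

    ok: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def graph_kind(graph: Graph) -> Kind:
    if isinstance(graph, UndirectedGraph):
        return "undirected"
    if isinstance(graph, DirectedGraph):
        return "directed"
    if isinstance(graph, BipartiteState):
        return "bipartite"
    raise TypeError(f"not a graph: {type(graph)!r}")


# ---------------------------------------------------------------------------
# degree bookkeeping


def degrees(graph: Graph) -> DegreeSequence:
    """Degree sequence of a graph of any kind."""
    if isinstance(graph, UndirectedGraph):
        return DegreeSequence("undirected",
                              degrees=tuple(len(s) for s in graph.adjacency))
    if isinstance(graph, DirectedGraph):
        out = tuple(len(s) for s in graph.out_adjacency)
        indeg = [0] * graph.n_nodes
        for s in graph.out_adjacency:
            for j in s:
                indeg[j] += 1
        return DegreeSequence("directed", in_degrees=tuple(indeg), out_degrees=out)
    if isinstance(graph, BipartiteState):
        rows = tuple(len(s) for s in graph.rows)
        cols = [0] * graph.n_cols
        for s in graph.rows:
            for c in s:
                cols[c] += 1
        return DegreeSequence("bipartite", row_sums=rows, col_sums=tuple(cols))
    raise TypeError(f"not a graph: {type(graph)!r}")


def edge_set(graph: Graph) -> set:
    """Edges as hashable pairs.

    Directed: ordered ``(i, j)`` arcs.  Undirected: ``frozenset({i, j})``
    pairs, each edge once.  Bipartite: ``(row, col)`` pairs.
    """
    if isinstance(graph, UndirectedGraph):
        return {frozenset((i, j)) for i, s in enumerate(graph.adjacency) for j in s}
    if isinstance(graph, DirectedGraph):
        return {(i, j) for i, s in enumerate(graph.out_adjacency) for j in s}
    if isinstance(graph, BipartiteState):
        return {(r, c) for r, s in enumerate(graph.rows) for c in s}
    raise TypeError(f"not a graph: {type(graph)!r}")


def validate(graph: Graph) -> ValidationReport:
    """Check the simple-graph invariants of any container.

    Undirected: no self-loops, symmetric adjacency, indices in range.
    Directed: no self-loops, indices in range.  Bipartite: column indices
    in range.  (Duplicate entries cannot arise inside a set.)
    """
    v: list[str] = []
    if isinstance(graph, UndirectedGraph):
        n = graph.n_nodes
        if len(graph.adjacency) != n:
            v.append(f"adjacency has {len(graph.adjacency)} sets for {n} nodes")
        for i, s in enumerate(graph.adjacency):
            if i in s:
                v.append(f"self-loop at node {i}")
            for j in s:
                if not 0 <= j < n:
                    v.append(f"index {j} out of range in A_{i}")
                elif i not in graph.adjacency[j]:
                    v.append(f"asymmetric edge: {j} in A_{i} but {i} not in A_{j}")
    elif isinstance(graph, DirectedGraph):
        n = graph.n_nodes
        if len(graph.out_adjacency) != n:
            v.append(f"adjacency has {len(graph.out_adjacency)} sets for {n} nodes")
        for i, s in enumerate(graph.out_adjacency):
            if i in s:
                v.append(f"self-loop at node {i}")
            for j in s:
                if not 0 <= j < n:
                    v.append(f"index {j} out of range in A_{i}")
    elif isinstance(graph, BipartiteState):
        if len(graph.rows) != graph.n_rows:
            v.append(f"{len(graph.rows)} row sets for {graph.n_rows} rows")
        for i, s in enumerate(graph.rows):
            for c in s:
                if not 0 <= c < graph.n_cols:
                    v.append(f"column {c} out of range in row {i}")
    else:
        v.append(f"unknown graph type {type(graph)!r}")
    return ValidationReport(ok=not v, violations=v)


# ---------------------------------------------------------------------------
# edge-list I/O


def _parse_edge_lines(path: Path) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tokens, got {len(tokens)}: {raw.rstrip()!r}"
                )
            pairs.append((tokens[0], tokens[1]))
    return pairs


def read_edge_list(path: str | Path, kind: Literal["directed", "undirected"]
                   ) -> DirectedGraph | UndirectedGraph:
    """Read a two-column whitespace-separated edge list.

    Node labels are arbitrary strings, mapped to 0-based indices in order of
    first appearance (the mapping is kept on the graph for write-back).
    Lines may carry ``#`` comments.  Duplicate edges are collapsed with a
    logged count; self-loops are rejected.
    """
    path = Path(path)
    if kind not in ("directed", "undirected"):
        raise ValueError(f"kind must be 'directed' or 'undirected', got {kind!r}")
    pairs = _parse_edge_lines(path)
    index: dict[str, int] = {}

    def idx(label: str) -> int:
        if label not in index:
            index[label] = len(index)
        return index[label]

    edges: list[tuple[int, int]] = []
    for a, b in pairs:
        if a == b:
            raise GraphValidationError(f"{path}: self-loop on node {a!r}")
        edges.append((idx(a), idx(b)))

    n = len(index)
    labels = list(index)
    n_dup = 0
    if kind == "directed":
        adj: list[set[int]] = [set() for _ in range(n)]
        for i, j in edges:
            if j in adj[i]:
                n_dup += 1
            else:
                adj[i].add(j)
        if n_dup:
            logger.warning("%s: collapsed %d duplicate arc(s)", path, n_dup)
        return DirectedGraph(n, adj, labels)
    adj = [set() for _ in range(n)]
    for i, j in edges:
        if j in adj[i]:
            n_dup += 1
        else:
            adj[i].add(j)
            adj[j].add(i)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate edge(s)", path, n_dup)
    return UndirectedGraph(n, adj, labels)


def write_edge_list(graph: DirectedGraph | UndirectedGraph, path: str | Path) -> None:
    """Write an edge list using original labels, one edge per line, sorted.

    Undirected edges are emitted once with endpoints in label order.
    """
    path = Path(path)
    labels = graph.labels or [str(i) for i in range(graph.n_nodes)]
    lines: list[str] = []
    if isinstance(graph, DirectedGraph):
        for i, j in edge_set(graph):
            lines.append(f"{labels[i]}\t{labels[j]}")
    elif isinstance(graph, UndirectedGraph):
        for e in edge_set(graph):
            a, b = sorted((labels[x] for x in e))
            lines.append(f"{a}\t{b}")
    else:
        raise TypeError("write_edge_list handles directed and undirected graphs")
    lines.sort()
    path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# biadjacency I/O


def read_biadjacency(path: str | Path, header: bool = False) -> BipartiteState:
    """Read a rectangular TSV of 0/1 entries as a bipartite state.

    With ``header=True`` the first row and first column are treated as
    labels and skipped.
    """
    path = Path(path)
    raw_rows: list[list[str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            raw_rows.append(line.split("\t") if "\t" in line else line.split())
    if not raw_rows:
        raise ParseError(f"{path}: empty matrix")

    col_labels = row_labels = None
    if header:
        col_labels = raw_rows[0][1:]
        row_labels = [r[0] for r in raw_rows[1:]]
        raw_rows = [r[1:] for r in raw_rows[1:]]

    width = len(raw_rows[0])
    rows: list[set[int]] = []
    for i, r in enumerate(raw_rows):
        if len(r) != width:
            raise ParseError(f"{path}: row {i} has {len(r)} entries, expected {width}")
        row = set()
        for j, cell in enumerate(r):
            if cell == "1":
                row.add(j)
            elif cell != "0":
                raise GraphValidationError(
                    f"{path}: non-binary entry {cell!r} at row {i}, column {j}"
                )
        rows.append(row)
    return BipartiteState(len(rows), width, rows, row_labels, col_labels)


def write_biadjacency(state: BipartiteState, path: str | Path, header: bool = False) -> None:
    """Write a bipartite state as a TSV of 0/1 entries."""
    path = Path(path)
    lines = []
    if header:
        cols = state.col_labels or [f"c{j}" for j in range(state.n_cols)]
        lines.append("\t" + "\t".join(cols))
    row_labels = state.row_labels or [f"r{i}" for i in range(state.n_rows)]
    for i, row in enumerate(state.rows):
        cells = ["1" if j in row else "0" for j in range(state.n_cols)]
        prefix = row_labels[i] + "\t" if header else ""
        lines.append(prefix + "\t".join(cells))
    path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")
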