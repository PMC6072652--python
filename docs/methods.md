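# Methods

## Model and state spaces

All samplers operate on the space of *simple* networks (no self-loops,
no parallel edges; reciprocal arc pairs are allowed in digraphs) with a
fixed degree sequence: per-node degrees for undirected networks, in/out
degree pairs for directed networks, row and column sums for bipartite
biadjacency matrices. A network is stored as a list of adjacency sets —
out-neighbour sets `A_v`, neighbour sets (each edge held twice, `i ∈ A_j`
and `j ∈ A_i`), or row sets of column indices. The target distribution
is always uniform over the realizations of the degree sequence.

## The trade move

A trade on sets `(A_i, A_j)` computes the tradeable sets
`A_{i−j} = A_i \ (A_j ∪ {j})` and `A_{j−i} = A_j \ (A_i ∪ {i})`, then
assigns a uniformly chosen `|A_{i−j}|`-subset of `A_{i−j} ∪ A_{j−i}` to
`i` and the complement to `j`. Bipartite trades drop the `{i}`, `{j}`
exclusion terms: rows and columns are disjoint node classes, so no
self-loop can arise. Undirected trades add a repair pass — each element
that changed owner has `j` replaced by `i` (or vice versa) in its own
neighbour set — which is exactly what keeps the doubly-stored adjacency
symmetric.

Design choices worth stating explicitly:

- **Subset choice.** The tradeable union is sorted, shuffled with the
  chain's generator, and a prefix taken. Every `k`-subset (including the
  one that re-selects the status quo) is equally likely, which makes the
  proposal distribution symmetric — the property the chain's detailed
  balance rests on. Sorting before shuffling makes the draw independent
  of set-iteration order, hence bit-reproducible.
- **Trade size** is the number of elements that actually change owner,
  so a draw that re-selects `A_{i−j}` has size 0 even when the union is
  non-empty. Size-0 outcomes are committed as steps (a lazy chain; this
  also guarantees aperiodicity).
- **Proposals are immutable records** (`TradeProposal`) carrying the old
  sets; `apply_trade` commits them in place and raises on a stale
  proposal. Every executed trade is invertible by re-choosing the
  original subsets with the same pair, and `inverse_proposal` constructs
  that reverse trade directly — the reversibility the uniformity
  argument needs, and the property the test suite checks on thousands of
  committed trades.

## Chain variants and step semantics

Three variants share one step-count convention — *every attempt is one
step*, including rejected switches and size-0 trades — so perturbation
traces are comparable at equal x-coordinates:

- `curveball`: uniform unordered pair of distinct set indices, full
  trade.
- `restricted_size1`: pair drawn identically, but at most one uniformly
  chosen element per side is exchanged. This is the switching model
  dressed in trade form; it serves as the mixing baseline because it
  isolates exactly one difference from the full chain — the number of
  elements moved per step.
- `switching`: two edges drawn uniformly (undirected edges with random
  endpoint orientation, so both re-pairings of an edge pair are
  proposable), rewired iff no self-loop or duplicate edge results.

A single `random.Random` stream drives each chain, consumed in a fixed
order (pair, then subset/element draws), so a run is a pure function of
`(input, config)`. The standard-library generator was chosen over a
numpy `Generator` because chain steps are dominated by scalar draws on
small sets, where it is markedly faster; its algorithms are stable
across Python versions, preserving reproducibility.

Whether published trace experiments counted pair-draws or committed
moves as "steps" is not always stated; this package counts pair-draws,
and traces may shift horizontally relative to implementations that count
otherwise.

## Frozen triangles and the directed chain

Switches cannot reverse every directed 3-cycle; the isolated oriented
triangle is the minimal frozen case, and a frozen cycle splits the
realization space into switch-disconnected classes. `is_frozen` uses a
local criterion: a 3-cycle is frozen iff none of its three arcs
participates in any valid switch with any other arc, and its reversal
creates no duplicate arc (a reversal colliding with a reciprocal arc is
not a realization, so there is nothing to fix). This is a conservative
surrogate for the exact characterization of switch-connectivity classes;
it is certified empirically, by mandatory agreement with a brute-force
oracle (`reachability_oracle`, exhaustive enumeration plus BFS over
single switches) on every small instance in the test suite. Two facts
the oracle confirmed and the tests encode:

- two disjoint 3-cycles in one graph are never both frozen — any arc of
  one forms a valid switch with any arc of the other, and the resulting
  space is a single switch class;
- the undirected 4-cycle does admit valid switches (the two diagonal
  re-pairings), connecting the three realizations of degrees (2,2,2,2).

`reorient_frozen_triangles` is a one-shot preprocessing step: each
frozen cycle independently keeps or reverses its orientation with
probability 1/2 before the chain runs. It is exposed as a CLI flag
(`--no-reorient-triangles`) because topology-only statistics (motif
counts, nestedness, C-score) are insensitive to the orientation of
frozen cycles and can skip the step.

## Diagnostics

**Perturbation score** — the fraction of the original network's edges
absent from the randomized one; symmetric for degree-matched pairs, and
the cheapest available proxy for distance-from-start. Note the minimal
non-zero score is `2/|E|` (one switch); no degree-matched pair differs
in exactly one edge.

**Exhaustive spaces** — `enumerate_realizations` brute-forces every 0/1
matrix with the prescribed margins (zero diagonal for digraphs,
symmetric for undirected graphs) with column-sum pruning, refusing
instances beyond ~7 unimode nodes / 36 bipartite cells. Realizations are
keyed by their flattened bit-string, which is exact, hashable and
order-stable.

**Uniformity** — visit counts of retained chain samples are compared to
uniformity with Pearson's chi-square. Defaults: burn-in 1,000 steps,
spacing 10 steps between retained samples, α = 0.001, and three
independent seeds with a majority rule, which keeps the test sensitive
to real bias while tolerating the occasional honest rejection at 60,000
samples. Any sample falling outside the enumerated space raises a
contamination error rather than a statistic — that is a broken move, not
bad luck. For spaces that switches cannot connect (the triangle's two
orientations), a single chain can never be uniform; there the test
switches to independent runs — fresh re-orientation plus a short chain
per retained sample. On the triangle the per-run burn-in is set to 20
steps since the chain there is provably state-invariant (every trade has
size 0): the sampled distribution is exactly the Bernoulli(1/2) of the
re-orientation step, and the burn-in length only costs time.

## Synthetic ensembles

- **Erdős–Rényi G(n, m)**: m distinct edges uniformly without
  replacement; ensembles draw `n` uniformly from a range and `m = d·n`
  with `d` uniform on a range. The benchmark and trace experiments use
  directed ER with `n = 200, d = 10` (dense enough that typical trades
  move several elements).
- **Preferential attachment**: nodes arrive one at a time, draw an
  out-degree uniformly from {1, 2, 3} (capped by the nodes present) and
  attach to distinct targets with probability proportional to
  in-degree + 1 (directed) or degree + 1 (undirected). The +1 smoothing
  lets degree-zero seeds be chosen. This construction reproduces the
  regime of interest — uniformly low out-degree with hub-concentrated
  in-degree — in which tradeable sets are small and often overlap, trades
  shrink to size ≤ 1, and the full chain's advantage over the
  size-1-restricted baseline attenuates.

The generators emulate degree structure only. They do not reproduce
trophic coherence, modularity, spatial constraints or sampling noise of
empirical food webs and co-occurrence networks, so passing tests
demonstrate correctness of the sampler and the predicted mixing
ordering on these ensembles — not how large the Curveball advantage is
on any particular empirical network.

## Problem sizes in the tests and acceptance script

Chosen as desk-scale study conditions: switch/trade equivalence on 100
random graphs of 8–12 nodes per kind; invariant checks over 10⁴ random
trades per kind; reversibility over 10³ committed trades per kind;
uniformity with 60,000 retained samples (tests) / 30,000 (script) on the
6-state bipartite, 7-state undirected and 2-state triangle spaces; the
triangle negative control over 10⁵ steps; trace comparisons on 10
replicate digraphs with 5,000 steps recorded every 100 (ER, n = 200,
d = 10) and the attenuation check at step 2,000 on 10 preferential-
attachment digraphs of n = 400 against ER digraphs of matched n and m,
averaged over three seeds — at matched sparse m the per-seed gaps are
small, so the assertion is made on the seed-averaged means.

## Known limitations

- `is_frozen` is certified by oracle agreement on small instances, not
  proved; on structures where non-switchability emerges only after
  rearranging the rest of the graph, the local criterion could in
  principle disagree (no such case has been found by the randomized
  agreement tests).
- `enumerate_realizations` and `reachability_oracle` are exponential by
  design and refuse large instances; they are verification tools, not
  samplers.
- The switching chain re-derives the edge list each step (O(m)); it is
  provided as a reference baseline, not tuned for speed.
- `realize_degree_sequence` returns one deterministic (Havel–Hakimi
  style) realization — a chain starting point, not a uniform sample.
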