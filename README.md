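# curveball

Degree-preserving randomization of bipartite, directed and undirected
networks with Curveball trade chains.

Null-model analysis of networks — food webs, species co-occurrence
networks, host–parasite webs, contact networks — asks whether an observed
structural pattern (nestedness, motifs, C-score, a particular link) is
surprising given the degrees of the nodes. Answering that requires
sampling *uniformly* from the set of all simple networks with exactly the
observed degree sequence. The classic tool is the switching (edge-swap)
chain, which rewires one pair of edges per step and mixes slowly. The
Curveball trade chain instead lets two whole adjacency sets exchange a
random subset of their differing elements in a single step — the effect
of many simultaneous swaps — while preserving every degree exactly.

## The trade move

Networks are stored as adjacency sets: out-neighbour sets `A_v` for a
directed network, neighbour sets for an undirected network, biadjacency
rows for a bipartite one. A trade between sets `A_i` and `A_j`:

1. compute the tradeable sets
   `A_{i−j} = A_i \ (A_j ∪ {j})` and `A_{j−i} = A_j \ (A_i ∪ {i})`
   (shared elements and the partner node itself never move — the latter
   exclusion is what keeps the result self-loop-free);
2. redistribute the union `A_{i−j} ∪ A_{j−i}` uniformly at random:
   `i` receives an `|A_{i−j}|`-subset, `j` the rest;
3. (undirected only) repair symmetry: every element that changed owner
   has `i` and `j` swapped in its own neighbour set.

The *size* of a trade is the number of elements that change owner; a
size-0 trade repeats the current network and still counts as a step.
Every classic switch equals a size-one trade (directed: at least one;
undirected: exactly two distinct ones), so the trade chain reaches
everything the switch chain does, in bigger strides.

One directed subtlety: some directed 3-cycles are *frozen* — no sequence
of switches or trades can reverse them (the isolated oriented triangle
`(0,1),(1,2),(2,0)` is the minimal case). `reorient_frozen_triangles`
detects them and gives each a uniformly random orientation before the
chain runs, which restores access to the full realization space when
node identities matter.

## Worked example

```python
import random
import curveball as cb

rng = random.Random(0)
web = cb.er_gnm(50, 300, "directed", rng)          # a 50-node, 300-arc digraph

start = cb.reorient_frozen_triangles(web, random.Random(1))
result = cb.run_chain(start, cb.ChainConfig(
    n_steps=5000, kind="directed", seed=1, record_every=1000))

print("degrees preserved:", cb.degrees(result.final_graph) == cb.degrees(web))
for step, score in zip(result.steps_recorded, result.scores):
    print(f"step {step:5d}  perturbation {score:.3f}")
print("size-0 steps:", result.n_zero_trades, "of 5000")
print("trade sizes:", dict(sorted(result.accepted_sizes.items())))
```

prints

```
degrees preserved: True
step  1000  perturbation 0.867
step  2000  perturbation 0.870
step  3000  perturbation 0.830
step  4000  perturbation 0.843
step  5000  perturbation 0.833
size-0 steps: 180 of 5000
trade sizes: {0: 180, 1: 1088, 2: 1777, 3: 1332, 4: 483, 5: 124, 6: 14, 7: 2}
```

The perturbation score is the fraction of the original's 300 arcs absent
from the current network; it plateaus near `1 − d/(n−1)` once the chain
has forgotten its start. Most steps here trade 2–3 elements at once —
the multi-swap strides that make the chain mix faster than single
switching. Degrees are exactly preserved throughout.

The same machinery is available from the shell:

```sh
curveball randomize --kind directed --steps 25000 --seed 1 web.txt null.txt
curveball converge --config experiment.conf --out traces/
curveball uniformity --kind bipartite --fixture bipartite_margins1 --samples 60000 --seed 1
```

Each command writes a JSON manifest sufficient to reproduce the run.

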