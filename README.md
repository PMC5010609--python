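# neurowire

Wiring-length optimality analysis of single-neuron arborizations.

Neurons are thought to lay out their dendrites and axons economically: the
further apart two connected points are, the more wire (and time, and
metabolic cost) the connection takes.  `neurowire` tests this hypothesis
on individual reconstructed neurons.  It reduces a traced morphology to
its *critical points* — the stem origins at the soma (roots), the
branching points, and the terminal tips — and then asks: over all
arborizations that connect the same points, keep every point's role, and
branch exactly as often at each point, how short could the wiring have
been?  And how long?  Comparing the real wiring length with these bounds
quantifies how close the neuron sits to its wiring optimum.

It is written for quantitative neuroanatomists and computational
neuroscientists working with NeuroMorpho-style SWC (or Neurolucida ASCII)
reconstructions, and is used from Python; a thin `neurowire` command-line
tool covers the common runs.

## The optimization problem

Let a compartment's critical points be `n` nodes forming `t` trees.  With
each node's out-degree (child-branch count) and role (root, branching
point, terminal) fixed to the real neuron's values, the shortest
admissible arborization is a **degree- and role-constrained minimum
spanning forest (DRCMST)** under Euclidean edge length

    L(F) = Σ_{(u,v) ∈ F} ‖x_u − x_v‖₂ ,

an NP-hard problem.  Candidate forests are encoded as permutations of
length `n − t`: two auxiliary arrays (parent slots, each node repeated
out-degree times; child slots, each non-root once) turn the permutation
value `s` at position `k` into the edge "node at slot `s` becomes parent
of child `k`", and a union-find repair guarantees every permutation
decodes to a valid forest.  A memetic steady-state genetic algorithm
(tournament selection, PMX crossover, swap mutation, distance-directed
local refinement; one offspring per step replacing the worst individual)
searches this space, minimizing or maximizing `L`.  Axonal clouds beyond
200 points are split into sub-regions (k-means clusters, or concentric
shells by distance to the soma), solved independently, merged outward
from the root, and polished by a local search near the sub-region
junctions; both partitioning methods are tried and the shorter tree wins.

Because the solver is heuristic, the package ships a data-free validation
benchmark: random clouds are constrained to the degree/role profile of
their own exact Euclidean minimum spanning tree, making the MST the known
optimum, and the solver's mean percentage excess over the MST (the
**MST gap**) is reported per cloud size.

## Worked example

```bash
python examples/02_dendritic_optimization.py
```

```
dendritic cloud: n=70, trees=5
real wiring     :    2594.4 um
shortest found  :    2484.5 um ( 95.76% of real)
longest found   :    9744.9 um (375.61% of real)
```

The synthetic neuron's five dendritic trees have 70 critical points and
2594 µm of critical-point wiring (chords between connected critical
points; tracing tortuosity is deliberately ignored on both sides of the
comparison).  The shortest admissible rewiring is only ~4% shorter, while
the longest is ~3.8× longer: the arborization sits near the bottom of a
wide feasible range, i.e. it is near-optimal in wiring length.  The other
example scripts cover critical-point extraction
(`01_critical_points.py`), partitioned axon solving
(`03_axon_partitioning.py`) and the MST benchmark
(`04_mst_benchmark.py`).

The same analyses from the shell:

```bash
neurowire fixtures --out-dir fixtures --n-neurons 3 --seed 1
neurowire analyze fixtures/synthetic_00.swc --seed 1 --out report.json
neurowire batch fixtures --seed 1 --out wiring_report.csv
neurowire benchmark --n 100 --replicates 10 --seed 1
```

## Layout

- `src/neurowire/morphology.py` — SWC / Neurolucida ASCII parsing,
  critical-point extraction, real wiring length
- `src/neurowire/drcmst.py` — permutation encoding, auxiliary arrays,
  decode/encode; `validate.py` — independent forest checker
- `src/neurowire/ssga.py` — the memetic steady-state GA
  (`_kernels.py` holds the numba-compiled inner loops)
- `src/neurowire/partition.py` — k-means / soma-distance partitioning,
  block merging, junction local search
- `src/neurowire/benchmark.py` — random clouds, exact MST, MST-gap
  benchmark; `synthetic.py` — ground-truthed neuron generator
- `src/neurowire/pipeline.py`, `cli.py` — per-neuron reports, batch
  tables, command-line interface

See `docs/methods.md` for the model, parameter defaults, and known
limitations.
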