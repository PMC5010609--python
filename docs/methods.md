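# Methods

## Problem statement

A reconstructed neuron is reduced, per compartment (axon; all dendrites
together), to its critical points: stem origins at the soma (*roots*),
branching points, and terminal tips.  Soma samples are never cloud nodes;
each stem's root is the first traced sample of the compartment, and
degree-2 tracing chains are path-compressed away.  Wiring length is the
sum of straight-line (chord) distances between connected critical points,
for the real arborization and for every candidate alike — path tortuosity
is ignored on both sides of the comparison, so the reported percentages
compare like with like.

Given the cloud, the search space is every forest on the same nodes in
which (i) each root stays a root of one of the `t` trees, (ii) every
non-root has exactly one parent, and (iii) every node has exactly its
real child count (out-degree).  Branching points in the analysed class of
neurons are bifurcations, so the extractor rejects nodes with more than
two child branches by default (`allow_multifurcations=True` accepts them
with their data-driven out-degree; a root with two children is likewise
accepted).  Minimizing total Euclidean length over this space is the
degree- and role-constrained minimum spanning forest problem, which is
NP-hard; maximizing uses the same machinery with the comparison sign
flipped.

## Encoding and decoding

A candidate forest is a permutation of `n − t` slot indices.  Auxiliary
array 1 lists parent slots (roots first, then branching nodes, ascending
id, each node repeated out-degree times); array 2 lists child slots
(non-roots ascending).  Value `s` at position `k` makes the node owning
slot `s` the parent of child `k`.  Decoding processes positions in order
with a union-find; an assignment is rejected when it would (a) close a
cycle, or (b) leave no remaining slot in any root-containing component.
Condition (b) is exactly completability of the remaining sub-problem:
pending children head root-free components that must attach, one at a
time, through slots of already-anchored components, and ordering
capacity-rich components first shows a completion exists if and only if
some remaining slot sits in a rooted component.  On rejection the nearest
later acceptable slot is swapped in.  Decoding is therefore total —
every permutation maps to a valid forest — deterministic, and O(n α(n))
per genotype.  Encoding is the inverse assignment (lowest free slot of
each child's parent), so encode∘decode and decode∘encode preserve edge
sets exactly; an independent union-find validator, separate from the
decoder, checks spanning, acyclicity and degree/role compliance in tests
and after every merge.

Partitioned sub-problems generalize the encoding: a spatial block of a
constrained tree need not have out-degree sum equal to its child count,
so block permutations run over all block slots and only the first `c`
positions are consumed; leftover slots are the free parent capacity that
junction edges use at merge time.

## The search engine

A memetic steady-state GA, minimization and maximization sharing the
engine through a sign flip:

| parameter | default | notes |
|---|---|---|
| population size | 50 | random permutations; optionally one member encodes the real forest (off by default, diagnostic only) |
| evaluation budget | max(50 000, 250·slots) | every decode counts, including refinement |
| crossover | PMX, rate 0.9 | preserves absolute positions, which carry the child→slot assignment |
| mutation | single value swap, rate 0.9 | |
| selection / replacement | tournament of 2; offspring replaces the worst individual on strict improvement; ties keep the incumbent | |
| local refinement | on; 5 candidate parents per child | first-improvement 2-swaps and 3-cycles that move a child onto a slot of one of its nearest parents (farthest when maximizing) |

Plain order-crossover/swap search was evaluated first and stalled at a
2-exchange local optimum far above the MST on benchmark clouds (~22%
mean gap at n=50, unchanged from 2·10⁵ to 10⁶ evaluations).  Because
MST-constrained instances are chain-rich — most nodes have out-degree
one, making the problem TSP-like — the engine adds the distance-directed
refinement above, after which the same budgets reach ≲1% at n=50.  All
randomness flows from a single integer seed (population seeding and the
compiled search loop use derived streams), so runs are bit-reproducible.

## Axon partitioning

Problems beyond 200 nodes (the practical limit for whole-cloud solves)
are partitioned:

- **k-means** on 3D coordinates, k = nearest hundred of the node count
  (minimum 1), 10 seeded restarts; blocks ordered root-block first, then
  by centroid distance to the root.  The published counterexample of a
  500-point cloud solved with k = 6 is accommodated by making k
  overridable.
- **soma distance**: nodes sorted by distance to the soma (the axon root
  position is the soma proxy), consecutive shells of a fixed group size
  (scan set {100, 125, 150, 165, 200}), remainder in the last shell,
  distance ties broken by node id.

Each block keeps every node's global out-degree.  The root block keeps
the real root and one spare capacity unit; every other block is rooted at
a pseudo-root, its node nearest the previously ordered block's centroid,
preferring nodes with parent capacity; blocks whose capacity cannot span
them receive extra pseudo-roots until balanced.  After the block solves,
the solutions form rooted fragments that are merged outward from the
real-root fragment: each step attaches the pending fragment with the
shortest junction edge to a free parent slot in the already-merged part
(cycle-free by construction), a capacity-aware rule guaranteeing
completion; each pseudo-root's incoming junction edge consumes exactly
the capacity its block solve left unused, so the merged tree satisfies
the global degree constraints exactly.  A junction local search then
swaps permutation values within 10 positions of each block boundary of
the block-grouped global permutation (each block's pseudo-root heads its
child segment so junction edges sit at the boundaries), accepting strict
improvements until a sweep passes clean.  The whole solve–merge–polish
cycle is repeated (default 20 times, same sub-regions) and the best
global tree wins; per direction, both partitioning methods are run and
the better result is reported with the method recorded.

## Validation benchmark

Uniform random clouds in a 100 µm cube (the scale cancels in the ratio;
a uniform ball is also available) are constrained to the degree/role
profile of their exact Euclidean MST rooted at the node nearest the
centroid, making the MST the known optimum of the induced problem.  The
benchmark reports mean ± sd of the percentage gap
100·(found − MST)/MST over replicates (default 10).  The exact MST comes
from `scipy.sparse.csgraph.minimum_spanning_tree` on the dense distance
matrix; the Euclidean MST is unique for generic point sets, and tests
verify it against brute-force spanning-tree enumeration at n ≤ 6.

`scripts/acceptance.py` runs this benchmark at n = 50 and 100
unpartitioned and at n = 200, 400, 800 with the partition pipeline under
both methods (shorter tree kept per cloud).  Problem sizes used: 10
replicates per condition, with 5 merge repetitions at n = 200/400 and,
at n = 800, 5 replicates with 3 repetitions — the package's chosen
benchmark sizes; gaps at these settings are stable to well under a
percentage point across seeds.

## Synthetic neurons

The fixture generator grows bifurcation-only morphologies: a soma,
several dendritic stems (one optionally apical-coded to exercise the
basal/apical merge) and one axonal tree.  Branch lengths are Normal(40,
10) µm clipped at 5 µm, directions persist with Gaussian perturbation
(sd 0.5 rad), and each branch is traced with 3 intermediate samples
jittered at 2% of branch length, so traced arcs strictly exceed critical
chords.  Elongated axons stretch the axonal field 3× along z.  The
generator records the exact critical-point topology and chord length
(computed from the coordinates as rounded to file precision), giving
every upstream stage an independent ground truth.  It emulates branch
counts, tree multiplicity and gross shape — not branch-angle statistics,
diameter taper, or obstacle-driven tortuosity — so passing tests show
pipeline correctness, not biological realism of the fixtures.

## Numerical choices and degenerate inputs

- Coordinates are used as-is in micrometres; duplicate critical-point
  coordinates are allowed and zero-length edges contribute 0.
- Local searches accept only improvements larger than 1e-12, and all
  tie-breaks (equal fitness, equal distance) keep the incumbent or the
  lowest id, for determinism.
- Single-node and all-root clouds decode to empty forests of length 0;
  blocks with fewer than 2 nodes are merged directly without a GA run.
- Seeds are combined with a fixed integer hash (`derive_seed`) kept below
  2³¹; identical inputs and seeds give byte-identical reports.

## Limitations

- The solver is a heuristic: reported minima are upper bounds on the true
  optimum (and maxima lower bounds); the MST-gap benchmark calibrates how
  tight they are at each problem size.
- Partitioned solves trade optimality for tractability; the gap grows
  with cloud size (junction structure is fixed by the partition).
- Tortuosity, conduction-time costs, and synaptic-target structure are
  out of scope; wiring cost is summed Euclidean length only.
- The Neurolucida ASCII reader consumes coordinates, branch structure and
  tree class only; markers, spines and display attributes are ignored.
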