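# Methods

## Model and objective

A partition of an undirected, unweighted simple graph assigns every node
to exactly one module. Its quality is modularity

    Q = Σ_m [ L_m / L − (D_m / 2L)² ],

the within-module edge fraction minus its expectation under a
degree-preserving random null model. `L_m` and `D_m` are exact integers,
so the package compares partitions on the integer scale
`S = 4L²Q = 4L·ΣL_m − ΣD_m²`. This makes tie-breaking exact, makes the
refinement-stage monotonicity guarantee a statement about integers, and
reproduces exact rationals such as 27/40 = 0.6750 without rounding
artifacts. Graphs are kept simple: self-loops are rejected, duplicate
edges in input files are collapsed with a logged warning, and weighted
or directed variants are out of scope. Isolated (degree-0) nodes are
accepted; they contribute 0 to Q in any module.

Node labels are opaque; internally they map to dense indices in
first-appearance order of the input. That order is also the node
priority used by the refinement stage, which keeps results deterministic
and independent of the input format.

## Stage 1 — multi-start partitioning

Each attempt draws a uniform random node→module assignment over a module
index set of size `m_max` and relocates single nodes greedily (largest
strictly positive integer gain; ties toward the smaller module id;
freshly shuffled node order per sweep) until no single-node move —
including into an empty module of the index set — improves Q. The best
of `n_starts = 100` seeded attempts is kept; the seed stream uses
`numpy.random.SeedSequence.spawn`, so best-of-n results are nested in
`n_starts`.

Graphs with at most `exact_threshold` nodes (default 16) are solved to
proven global optimality instead, as a clique-partitioning integer
program: one binary per node pair ("same module"), transitivity by
triangle inequalities, and — when `m_max` binds — continuous
representative variables bounding the module count. Objective
coefficients are the integers `4L·A_ne − 2 d_n d_e`. The program is
solved with HiGHS through `scipy.optimize.milp`. An exact solve is
deterministic and start-independent, so `n_starts` collapses to one run.
The threshold of 16 keeps the worst-case triangle-inequality count
(3·C(16,3) = 1680 rows) comfortably sub-second; beyond ~30 nodes the
formulation's O(N³) constraints make multi-start search the better tool.
If the time budget (`time_limit_s`, default 60 s) expires without a
feasible point, the attempt falls back to local search and the run
record flags the result as not proven optimal.

`m_max` defaults to `max(2, ⌈N/3⌉)` capped at 50 — large enough to admit
the smallest communities of interest (triangles) without inflating the
search space — and is user-overridable.

## Stage 2 — fix-and-release refinement

Starting from the stage-1 incumbent, modules are visited in their
canonical entry order, held fixed across all major iterations. The
module at turn releases its members in batches: members sorted by
internal index ascending, chunked to at most

    MAX_m^r = max(1, ⌊U / Aver_m⌋),   Aver_m = 2 L_m^sub / |m|,

where `Aver_m` is the average degree of the module's induced subgraph
(inter-module links excluded) and `U = 200`. The division form is
adopted — the cap's purpose is to keep the reduced problem tractable,
and dividing shrinks it for denser modules — and the operator is exposed
as a config switch (`divide` | `multiply`) and logged. A degree-0 module
releases all its nodes at once.

Each released batch is reassigned over the modules that are non-empty in
the current incumbent (no new modules are opened; module-count increases
are the job of the resolution pass, and modules emptied by evacuation
are dropped at canonicalisation). Batches of at most
`exact_threshold_reduced` nodes (default 24) are solved exactly with a
hybrid program — binary assignment variables for released nodes,
continuous pairwise variables linked by standard inequalities (the pair
variables are integral by implication) — and larger batches by the same
relocation search restricted to the released nodes. The incumbent is
feasible in every reduced problem, so the integer score after each solve
is non-decreasing by construction; the implementation additionally
guards the update and records the full score trace. One pass over all
modules is a major iteration; the loop terminates when two successive
major iterations bring no strict integer improvement (equivalent to a
1e-12 tolerance on Q, since genuine improvements are at least 1/(4L²)),
with a logged safety cap of 100 iterations.

## Resolution correction

Each module of the final partition is treated as a disjoint subnetwork
(inter-module links ignored) and the full two-stage pipeline is run on
it once. The proposed split replaces the module iff it has ≥ 2
sub-modules and its modularity *computed on subnetwork links alone*
exceeds the threshold (default 0.3, a conventional indicator of genuine
community structure). A split into one module is vacuous and never
accepted; subnetworks with fewer than two nodes or no edges are skipped
and logged. The procedure only ever splits — every final module is a
subset of exactly one input module — and the reported final Q is
evaluated on the full graph, so it can only decrease when splits are
accepted (otherwise the global maximisation would have found them). The
pass is applied once by default; `recursive=True` repeats it until no
split is accepted, for exploration. The per-module report exposes every
sub-modularity so users can apply stricter post-hoc filters; a
statistical-significance complement to the fixed threshold is a known
limitation, not implemented here.

## Benchmark generators

* **Ring of cliques** (k cliques K_s, default 10 × K_3): clique i's
  node 0 joins clique i+1's node 1, so adjacent cliques share exactly
  one edge through distinct boundary nodes. Fully deterministic.
* **Y-shaped network** (two K_20, two K_5): four single inter-clique
  edges A–B, B–c, B–d, c–d at fixed low-index boundary nodes. This
  four-edge arrangement is the unique simple four-clique wiring
  consistent with both reference modularities of the example
  (0.5426 for the 3-module and 0.5416 for the 4-module partition);
  modularity is invariant to the boundary-node choice, which is fixed
  only to make the graphs byte-identical across runs.
* **Planted partition** (default 128 nodes, 4 groups of 32, expected
  degree 16): independent edges with
  `p_in = (1−μ)·z/(n/g − 1)` and `p_out = μ·z/(n − n/g)`, so the
  expected degree is `z` and the expected fraction of a node's links
  leaving its group is the mixing parameter μ. Generation delegates to
  `networkx.planted_partition_graph` with a fixed seed. The independent
  -pair model (rather than a fixed-degree configuration model) realises
  the standard benchmark, which specifies only expected degree and
  mixing; test suites use μ ≤ 0.5, beyond which "community" stops being
  meaningful.

What the synthetic suites do not emulate: heavy-tailed degree and
community-size distributions, weighted or directed edges, and
overlapping membership. Passing them shows the optimiser recovers clean
planted structure, not that real biological networks are partitioned
"correctly".

## Similarity metric

NMI in the confusion-matrix form
`−2 Σ N_ij ln(N_ij N / N_i N_j) / [Σ N_i ln(N_i/N) + Σ N_j ln(N_j/N)]`
(natural logarithms, `0·ln 0 = 0`), equal to `2I/(H_A+H_B)`. The formula
is undefined when a marginal entropy vanishes; by the measure's range
semantics two single-module partitions score 1.0 and a single-module
partition against a non-trivial one scores 0.0.

## Numerical and design choices

* All partition comparisons (multi-start selection, move gains,
  refinement termination) use the integer score S; floating point enters
  only in reporting Q and in MILP objective coefficients, whose optima
  are verified on the integer scale after extraction.
* Exact-solver formulations: the clique-partitioning form is used for
  the full problem because the quadratic `D_m²` objective term cannot be
  linearised with edge-assignment variables alone; the reduced problem
  uses assignment variables (module identity matters when most nodes are
  frozen) plus implied-integral pair variables.
* Determinism: identical (graph, config, seed) gives identical output
  files byte-for-byte. Repeats, multi-starts, benchmark networks and
  per-subnetwork solves all derive child seeds from the master seed.
* Problem sizes in the shipped tests and the acceptance script are the
  desk-scale ones: the two 30/50-node resolution examples, the 34-node
  karate-club network, 10 planted-partition networks at μ = 0.2, and
  50 random graphs of ≤ 8 nodes for the brute-force oracle suite; the
  full 100-network sweep over μ ∈ [0.1, 0.5] is available through
  `run_benchmark`/`imodnet benchmark`.
* Known limitations: module visit order and node priority are fixed
  rules (alternative orderings are deliberately not explored); no
  weighted/directed/overlapping variants; no significance testing of
  sub-module splits; global optimality is only proven below the exact
  thresholds.
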