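# imodnet

Community detection in undirected networks by two-stage modularity
maximisation, with an explicit correction for the resolution limit of
the modularity measure. Intended for systems-biology and network-science
users who need reproducible partitions of protein-interaction,
transcriptional, metabolic or social networks, together with the
standard synthetic benchmarks for validating detection methods.

## The method

For a network with `L` edges partitioned into modules `m`, modularity is

    Q = Σ_m [ L_m / L − (D_m / 2L)² ]

where `L_m` counts edges with both endpoints inside module `m` and `D_m`
is the sum of its members' degrees. `Q` compares the within-module edge
fraction against a degree-preserving random null model; values around
0.4–0.8 indicate strong community structure. Maximising `Q` is NP-hard,
so the pipeline works in two stages:

1. **Multi-start partitioning.** The best of `N^max = 100` randomised
   attempts. Each attempt runs a relocation search from a uniform random
   node→module assignment to a local optimum in which no single-node
   reassignment increases `Q`. Small graphs are instead solved to proven
   global optimality as a clique-partitioning integer program (pairwise
   same-module binaries, triangle inequalities; HiGHS via
   `scipy.optimize.milp`).
2. **Fix-and-release refinement.** Modules are visited in fixed order;
   each releases its nodes in index-priority batches of at most
   `MAX_m^r = ⌊U / Aver_m⌋` nodes (`Aver_m` = average intra-module
   degree, `U = 200`), and every released batch is re-optimised over the
   existing modules with all other assignments frozen. The incumbent is
   always feasible, so `Q` never decreases; the loop stops after two
   major iterations without improvement.

Because global `Q`-maximisation hides communities smaller than a scale
set by total network size, a **resolution correction** re-runs the
pipeline once on each detected module as a disjoint subnetwork
(inter-module links ignored) and accepts a split iff its subnetwork
modularity exceeds a threshold (default 0.3) with at least two
sub-modules.

The package also ships the matching benchmark generators (ring of
cliques, Y-shaped four-clique network, 128-node four-group
planted-partition graphs with mixing parameter μ) and normalised mutual
information (NMI) for scoring detected against planted structure.

## Worked example

The ring of ten 3-node cliques is the classic resolution-limit stress
case: plain modularity maximisation merges adjacent cliques.

```python
import imodnet as im

g, truth = im.generators.ring_of_cliques(10, 3)
res = im.ModularityModel(g, seed=1).fit(repeats=10)
print(res.summary())
rr = res.resolve(threshold=0.3)
print(rr.n_modules, round(rr.q, 4), rr.score_against(truth))
```

prints

```
Community detection results
==============================================
Nodes (N)                                   30
Edges (L)                                   40
Modules (M)                                  5
Modularity Q                            0.6750
Q after stage 1                         0.6650
Major iterations                             5
Stage-1 mode                       multi-start
Repeats                                     10
Wall time (s)                             3.46
==============================================
10 0.65 1.0
```

Maximising `Q` alone yields 5 modules of two cliques each (Q = 0.6750,
the true global maximum); the resolution pass splits every pair
(each subnetwork split scores 5/14 ≈ 0.357 > 0.3) and recovers the ten
planted cliques exactly (NMI = 1.0) at full-graph Q = 0.6500.

The same workflow is available from the shell:

```bash
imodnet generate ring --cliques 10 --size 3 --out ring.txt --truth-out truth.tsv
imodnet detect --edgelist ring.txt --out part.tsv --seed 1 --repeats 10
imodnet resolve --edgelist ring.txt --partition part.tsv --out final.tsv --report report.tsv
imodnet score --truth truth.tsv --pred final.tsv --edgelist ring.txt
```

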