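"""Benchmark network generators with known community structure.

Three constructions:

* a ring of cliques — the classic resolution-limit stress case: k
  complete graphs K_s joined in a cycle by single edges;
* a Y-shaped four-clique network (two large, two small cliques) whose
  small cliques are merged by plain modularity maximisation;
* planted-partition graphs (the four-group, 128-node benchmark):
  independent edges with intra-group probability p_in and inter-group
  probability p_out chosen so the expected degree is ``degree`` and the
  expected fraction of a node's links leaving its group is ``mu``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import Graph
from .partition import Partition

__all__ = ["ring_of_cliques", "y_clique_network", "gn_benchmark", "PlantedPartition"]


@dataclass(frozen=True)
class PlantedPartition:
    """A generated benchmark graph with its known community structure."""

    graph: Graph
    truth: Partition
    mu: float
    target_degree: float


def ring_of_cliques(n_cliques: int = 10, clique_size: int = 3) -> tuple[Graph, Partition]:
    """Ring of ``n_cliques`` complete graphs K_``clique_size``.

    Clique i donates its node 0 to an edge reaching node 1 of clique
    i+1 (mod n_cliques), so adjacent cliques are joined by exactly one
    edge through two distinct boundary nodes.  Truth partition: one
    module per clique.
    """
    if n_cliques < 3 or clique_size < 3:
        raise ValueError("need n_cliques >= 3 and clique_size >= 3")
    nodes = list(range(n_cliques * clique_size))
    edges = []
    for c in range(n_cliques):
        base = c * clique_size
        for i in range(clique_size):
            for j in range(i + 1, clique_size):
                edges.append((base + i, base + j))
    for c in range(n_cliques):
        nxt = (c + 1) % n_cliques
        edges.append((c * clique_size, nxt * clique_size + 1))
    g = Graph(nodes, edges)
    truth = Partition(g, np.repeat(np.arange(n_cliques), clique_size))
    return g, truth


def y_clique_network(large: int = 20, small: int = 5) -> tuple[Graph, Partition]:
    """Four cliques A=K_large, B=K_large, c=K_small, d=K_small.

    Exactly four single inter-clique edges: A-B, B-c, B-d and c-d, each
    attached at distinct low-index boundary nodes.  Modularity
    maximisation merges c and d (3 modules); the true structure has 4.
    """
    if not (large > small >= 3):
        raise ValueError("need large > small >= 3")
    sizes = [large, large, small, small]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    nodes = list(range(int(offsets[-1])))
    edges = []
    for c, size in enumerate(sizes):
        base = int(offsets[c])
        for i in range(size):
            for j in range(i + 1, size):
                edges.append((base + i, base + j))
    a0, b0, c0, d0 = (int(o) for o in offsets[:4])
    edges += [
        (a0, b0),          # A-B
        (b0 + 1, c0),      # B-c
        (b0 + 2, d0),      # B-d
        (c0 + 1, d0 + 1),  # c-d
    ]
    g = Graph(nodes, edges)
    truth = Partition(g, np.repeat(np.arange(4), sizes))
    return g, truth


def gn_benchmark(
    n: int = 128,
    groups: int = 4,
    degree: float = 16.0,
    mu: float = 0.2,
    seed: int | None = None,
) -> PlantedPartition:
    """Planted-partition benchmark with known equal-size communities.

    ``p_in = (1-mu) * degree / (n/groups - 1)`` and
    ``p_out = mu * degree / (n - n/groups)`` give expected node degree
    ``degree`` with an expected fraction ``mu`` of links leaving the
    node's group.  Defaults reproduce the standard 128-node, four-group,
    degree-16 suite.
    """
    if n % groups != 0:
        raise ValueError("groups must divide n")
    if not (0.0 <= mu < 1.0):
        raise ValueError("mu must lie in [0, 1)")
    size = n // groups
    p_in = (1.0 - mu) * degree / (size - 1)
    p_out = mu * degree / (n - size)
    if not (0.0 <= p_in <= 1.0):
        raise ValueError(f"intra-group probability p_in={p_in:.3f} outside [0, 1]")
    if not (0.0 <= p_out <= 1.0):
        raise ValueError(f"inter-group probability p_out={p_out:.3f} outside [0, 1]")
    nxg = nx.planted_partition_graph(groups, size, p_in, p_out, seed=seed)
    g = Graph(sorted(nxg.nodes()), sorted(tuple(sorted(e)) for e in nxg.edges()))
    truth = Partition(g, np.repeat(np.arange(groups), size))
    return PlantedPartition(graph=g, truth=truth, mu=mu, target_degree=degree)
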