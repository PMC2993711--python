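"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

import imodnet as im
from imodnet.partition import modularity_score


# ---------------------------------------------------------------------------
# independent oracles (kept free of the code paths they check)

def enumerate_set_partitions(items):
    """All set partitions of a sequence (restricted-growth strings)."""
    items = list(items)
    n = len(items)
    if n == 0:
        yield []
        return

    def rec(i, blocks):
        if i == n:
            yield [list(b) for b in blocks]
            return
        for b in blocks:
            b.append(items[i])
            yield from rec(i + 1, blocks)
            b.pop()
        blocks.append([items[i]])
        yield from rec(i + 1, blocks)
        blocks.pop()

    yield from rec(0, [])


def brute_force_best(g: im.Graph) -> tuple[int, int]:
    """(max integer-scaled modularity, module count of a maximiser)."""
    best, best_m = None, None
    for blocks in enumerate_set_partitions(range(g.n_nodes)):
        labels = np.empty(g.n_nodes, dtype=np.int64)
        for m, block in enumerate(blocks):
            labels[block] = m
        s = modularity_score(g, labels)
        if best is None or s > best:
            best, best_m = s, len(blocks)
    return best, best_m


def edgewise_modularity(g: im.Graph, p: im.Partition) -> float:
    """Q via the pairwise definition (1/2L) sum_ne [A - d_n d_e / 2L] delta."""
    L = g.n_edges
    adj = {(int(i), int(j)) for i, j in g.edges} | {(int(j), int(i)) for i, j in g.edges}
    d = g.degrees
    labels = p.labels
    total = 0.0
    for n, e in itertools.product(range(g.n_nodes), repeat=2):
        if labels[n] == labels[e]:
            a = 1.0 if (n, e) in adj else 0.0
            total += a - d[n] * d[e] / (2.0 * L)
    return total / (2.0 * L)


def random_graph(rng: np.random.Generator, n_lo=4, n_hi=9, require_edges=True) -> im.Graph:
    """Seeded Erdos-Renyi graph wrapped in the package's container."""
    while True:
        n = int(rng.integers(n_lo, n_hi))
        p = float(rng.uniform(0.25, 0.85))
        nxg = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nxg.number_of_edges() or not require_edges:
            return im.Graph(list(nxg.nodes()), list(nxg.edges()))


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def ring():
    return im.generators.ring_of_cliques(10, 3)


@pytest.fixture(scope="session")
def yshape():
    return im.generators.y_clique_network(20, 5)


@pytest.fixture
def triangle():
    return im.Graph([0, 1, 2], [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def two_triangles():
    """Two K_3 cliques joined by a single edge; optimum Q = 5/14."""
    return im.Graph(range(6), [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
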