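"""Undirected simple-graph container and edge-list / GML input.

The container keeps node labels opaque and maps them to dense integer
indices in first-appearance order; all algorithmic code works on the
indices, and the index order is also the node-priority order used by the
fix-and-release refinement stage.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import IO, Hashable, Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["Graph", "read_edge_list", "read_gml", "induced_subgraph"]


class Graph:
    """An undirected, unweighted simple graph.

    Parameters
    ----------
    nodes : sequence of hashable labels
        Node identifiers in the order that defines the internal indices.
    edges : iterable of (u, v) label pairs
        Undirected edges. Self-loops and duplicate edges are rejected;
        use :func:`read_edge_list` for tolerant ingestion of real files.
    """

    __slots__ = ("nodes", "_index", "edges", "degrees", "adjacency")

    def __init__(self, nodes: Sequence[Hashable], edges: Iterable[tuple]) -> None:
        self.nodes: tuple = tuple(nodes)
        self._index: dict = {u: i for i, u in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise ValueError("duplicate node labels")
        n = len(self.nodes)
        seen: set = set()
        pairs: list = []
        adj: list = [[] for _ in range(n)]
        for u, v in edges:
            try:
                i, j = self._index[u], self._index[v]
            except KeyError as exc:
                raise ValueError(f"edge endpoint {exc.args[0]!r} is not a node") from None
            if i == j:
                raise ValueError(f"self-loop on node {u!r}")
            key = (i, j) if i < j else (j, i)
            if key in seen:
                raise ValueError(f"duplicate edge {u!r}-{v!r}")
            seen.add(key)
            pairs.append(key)
            adj[i].append(j)
            adj[j].append(i)
        self.edges: np.ndarray = (
            np.asarray(pairs, dtype=np.int64) if pairs else np.empty((0, 2), dtype=np.int64)
        )
        self.adjacency: list = [np.asarray(sorted(a), dtype=np.int64) for a in adj]
        self.degrees: np.ndarray = np.asarray([len(a) for a in adj], dtype=np.int64)

    # -- basic properties -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self, node: Hashable) -> int:
        """Internal (first-appearance) index of a node label."""
        return self._index[node]

    def __contains__(self, node: Hashable) -> bool:
        return node in self._index

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Graph(N={self.n_nodes}, L={self.n_edges})"

    def validate(self) -> None:
        """Check the simple-graph invariants (used by tests and generators)."""
        assert int(self.degrees.sum()) == 2 * self.n_edges
        for i in range(self.n_nodes):
            for j in self.adjacency[i]:
                assert i in self.adjacency[j]

    # -- conversions ------------------------------------------------------

    def to_networkx(self):
        """Return a :class:`networkx.Graph` with the original labels."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((self.nodes[i], self.nodes[j]) for i, j in self.edges)
        return g

    @classmethod
    def from_networkx(cls, g) -> "Graph":
        """Build from a networkx graph (node order = iteration order)."""
        return cls(list(g.nodes()), list(g.edges()))


def read_edge_list(source: str | Path | IO[str]) -> Graph:
    """Read a whitespace-delimited edge list (two labels per line).

    Lines starting with ``#`` and blank lines are ignored.  Duplicate
    edges (in either orientation) are collapsed with a logged warning;
    self-loops and malformed lines raise ``ValueError`` naming the line.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    nodes: list = []
    index: dict = {}
    seen: set = set()
    edges: list = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise ValueError(
                f"line {lineno}: expected two node labels, got {len(tokens)}: {line!r}"
            )
        u, v = tokens
        if u == v:
            raise ValueError(f"line {lineno}: self-loop {line!r}")
        for t in (u, v):
            if t not in index:
                index[t] = len(nodes)
                nodes.append(t)
        key = (index[u], index[v]) if index[u] < index[v] else (index[v], index[u])
        if key in seen:
            logger.warning("line %d: duplicate edge %s-%s collapsed", lineno, u, v)
            continue
        seen.add(key)
        edges.append((u, v))
    return Graph(nodes, edges)


def read_gml(path: str | Path) -> Graph:
    """Read a GML network file (nodes with ``id``, edges source/target)."""
    import networkx as nx

    g = nx.read_gml(path, label="id")
    if g.is_directed() or g.is_multigraph():
        g = nx.Graph(g)
    return Graph.from_networkx(g)


def induced_subgraph(g: Graph, node_subset: Iterable) -> Graph:
    """Subgraph on ``node_subset`` with inter-subset edges dropped.

    Node order follows the parent graph's order; degrees are recomputed
    within the subgraph.
    """
    subset = set(node_subset)
    missing = subset - set(g.nodes)
    if missing:
        raise ValueError(f"nodes not in graph: {sorted(map(repr, missing))}")
    keep = [u for u in g.nodes if u in subset]
    keep_idx = {g.index(u) for u in keep}
    edges = [
        (g.nodes[i], g.nodes[j]) for i, j in g.edges if i in keep_idx and j in keep_idx
    ]
    return Graph(keep, edges)
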