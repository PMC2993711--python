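"""Partitions, per-module statistics and the modularity quality function.

Modularity of a partition into modules m is

    Q = sum_m [ L_m / L - (D_m / 2L)^2 ]

where L_m counts edges with both endpoints inside module m and D_m sums
the full-graph degrees of the module's members.  All statistics are
accumulated as exact integers; Q is formed in double precision at the
end, so values such as 27/40 = 0.6750 are exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping

import numpy as np

from .graph import Graph

__all__ = [
    "Partition",
    "ModuleStats",
    "module_stats",
    "modularity",
    "modularity_score",
    "write_partition",
    "read_partition",
]


class Partition:
    """Assignment of every node of a graph to exactly one module.

    Module identifiers are small integers.  :meth:`canonicalize` renumbers
    the non-empty modules 0..M-1 in order of their smallest member index,
    which makes partition files reproducible and comparisons label-free.
    """

    __slots__ = ("graph", "labels")

    def __init__(self, graph: Graph, labels) -> None:
        labels = np.asarray(labels, dtype=np.int64)
        if labels.shape != (graph.n_nodes,):
            raise ValueError("labels must assign every node exactly once")
        if labels.size and labels.min() < 0:
            raise ValueError("negative module identifier")
        self.graph = graph
        self.labels = labels

    @classmethod
    def from_assignment(cls, graph: Graph, assignment: Mapping) -> "Partition":
        missing = [u for u in graph.nodes if u not in assignment]
        if missing:
            raise ValueError(f"unassigned nodes: {missing[:5]}")
        module_ids = sorted(set(assignment[u] for u in graph.nodes))
        remap = {m: i for i, m in enumerate(module_ids)}
        return cls(graph, [remap[assignment[u]] for u in graph.nodes])

    @classmethod
    def single_module(cls, graph: Graph) -> "Partition":
        return cls(graph, np.zeros(graph.n_nodes, dtype=np.int64))

    @property
    def n_modules(self) -> int:
        """Number of non-empty modules (M)."""
        return len(np.unique(self.labels)) if self.labels.size else 0

    @property
    def assignment(self) -> dict:
        return {u: int(self.labels[i]) for i, u in enumerate(self.graph.nodes)}

    def members(self, module_id: int) -> np.ndarray:
        """Internal indices of the module's nodes, ascending."""
        return np.flatnonzero(self.labels == module_id)

    def canonicalize(self) -> "Partition":
        """Renumber non-empty modules by smallest member index."""
        order: dict = {}
        new = np.empty_like(self.labels)
        for i, m in enumerate(self.labels):
            m = int(m)
            if m not in order:
                order[m] = len(order)
            new[i] = order[m]
        return Partition(self.graph, new)

    def relabel_nodes(self, new_graph: Graph) -> "Partition":
        """Carry the assignment onto a graph with the same labels."""
        a = self.assignment
        return Partition(new_graph, [a[u] for u in new_graph.nodes])

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.graph is other.graph and np.array_equal(
            self.canonicalize().labels, other.canonicalize().labels
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Partition(N={len(self.labels)}, M={self.n_modules})"


@dataclass(frozen=True)
class ModuleStats:
    """Per-module intra-link counts L_m and degree sums D_m.

    Arrays are indexed by module id; empty modules carry zeros.
    """

    intra_links: np.ndarray
    degree_sum: np.ndarray


def module_stats(g: Graph, p: Partition, n_modules: int | None = None) -> ModuleStats:
    """Exact integer L_m and D_m for every module of ``p``."""
    if p.graph is not g and list(p.graph.nodes) != list(g.nodes):
        raise ValueError("partition does not match graph")
    m = int(p.labels.max()) + 1 if p.labels.size else 0
    if n_modules is not None:
        m = max(m, n_modules)
    d = np.bincount(p.labels, weights=g.degrees, minlength=m).astype(np.int64)
    if g.n_edges:
        lu = p.labels[g.edges[:, 0]]
        lv = p.labels[g.edges[:, 1]]
        intra = np.bincount(lu[lu == lv], minlength=m).astype(np.int64)
    else:
        intra = np.zeros(m, dtype=np.int64)
    return ModuleStats(intra_links=intra, degree_sum=d)


def modularity_score(g: Graph, labels: np.ndarray) -> int:
    """Integer-scaled modularity S = 4 L^2 Q = 4 L sum(L_m) - sum(D_m^2).

    Exact integer arithmetic; used for tie-free comparisons and the
    monotonicity guarantee of the refinement stage.
    """
    L = g.n_edges
    m = int(labels.max()) + 1 if labels.size else 0
    d = np.bincount(labels, weights=g.degrees, minlength=m).astype(np.int64)
    lu = labels[g.edges[:, 0]]
    lv = labels[g.edges[:, 1]]
    intra = np.bincount(lu[lu == lv], minlength=m)
    return 4 * L * int(intra.sum()) - int(np.dot(d, d))


def modularity(g: Graph, p: Partition) -> float:
    """Modularity Q of a full partition; exact-rational friendly."""
    L = g.n_edges
    if L == 0:
        raise ValueError("modularity undefined for edgeless graph")
    return modularity_score(g, p.labels) / (4.0 * L * L)


def write_partition(
    p: Partition, q: float, sink: str | Path | IO[str], config: str = ""
) -> None:
    """Write a canonical partition as TSV with a commented header.

    Header records Q, M and an optional config echo; body is one
    ``node<TAB>module`` line per node in graph order.
    """
    p = p.canonicalize()
    buf = io.StringIO()
    buf.write(f"# Q={q:.10g}\n")
    buf.write(f"# M={p.n_modules}\n")
    if config:
        buf.write(f"# config: {config}\n")
    for i, u in enumerate(p.graph.nodes):
        buf.write(f"{u}\t{int(p.labels[i])}\n")
    text = buf.getvalue()
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text)


def read_partition(source: str | Path | IO[str], graph: Graph) -> Partition:
    """Read a partition TSV written by :func:`write_partition`."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    assignment: dict = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split("\t")
        if len(tokens) != 2:
            raise ValueError(f"line {lineno}: expected 'node<TAB>module'")
        assignment[tokens[0]] = int(tokens[1])
    # graph labels may be non-strings (e.g. ints); match on str form
    by_str = {str(u): u for u in graph.nodes}
    mapped = {by_str[k]: v for k, v in assignment.items() if k in by_str}
    return Partition.from_assignment(graph, mapped)
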