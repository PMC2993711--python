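"""Stage 1: initial partition by multi-start modularity maximisation.

Each attempt starts from a uniform random node→module assignment over the
module index set and runs to a local optimum in which no single-node
reassignment (including to an empty module of the index set) increases
modularity.  Small graphs are instead solved to proven global optimality
with the clique-partitioning integer program.  The best of N^max attempts
is kept; N^max = 100 by default.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import SolverConfig
from .exact import solve_exact_full
from .graph import Graph
from .partition import Partition, modularity_score

logger = logging.getLogger(__name__)

__all__ = ["solve_once", "initial_partition", "local_search"]


def local_search(
    g: Graph,
    labels: np.ndarray,
    m_max: int,
    rng: np.random.Generator,
    max_sweeps: int = 500,
) -> np.ndarray:
    """Greedy single-node relocation to a local modularity optimum.

    Nodes are visited in a freshly shuffled order each sweep; a node moves
    to the module with the largest strictly positive integer-scaled gain
    (ties broken toward the smallest module id).  Terminates when a full
    sweep makes no move.
    """
    L = g.n_edges
    deg = g.degrees
    labels = np.asarray(labels, dtype=np.int64).copy()
    d_tot = np.zeros(m_max, dtype=np.int64)
    sizes = np.zeros(m_max, dtype=np.int64)
    for i, m in enumerate(labels):
        d_tot[m] += deg[i]
        sizes[m] += 1
    order = np.arange(g.n_nodes)
    for _ in range(max_sweeps):
        rng.shuffle(order)
        moved = False
        for n in order:
            n = int(n)
            a = int(labels[n])
            dn = int(deg[n])
            counts: dict = {}
            for e in g.adjacency[n]:
                me = int(labels[e])
                counts[me] = counts.get(me, 0) + 1
            l_na = counts.get(a, 0)
            best_gain, best_m = 0, a
            cands = sorted(counts)
            empties = np.flatnonzero(sizes == 0)
            if empties.size and sizes[a] > 1:
                cands.append(int(empties[0]))
            for b in cands:
                if b == a:
                    continue
                gain = 4 * L * (counts.get(b, 0) - l_na) - 2 * dn * (
                    int(d_tot[b]) - int(d_tot[a]) + dn
                )
                if gain > best_gain or (gain == best_gain > 0 and b < best_m):
                    best_gain, best_m = gain, b
            if best_gain > 0:
                labels[n] = best_m
                d_tot[a] -= dn
                d_tot[best_m] += dn
                sizes[a] -= 1
                sizes[best_m] += 1
                moved = True
        if not moved:
            break
    return labels


def solve_once(
    g: Graph,
    cfg: SolverConfig,
    rng: np.random.Generator | None = None,
    start: Partition | None = None,
) -> tuple[Partition, bool]:
    """One stage-1 attempt; returns ``(partition, proven_optimal)``.

    Below ``cfg.exact_threshold`` nodes the clique-partitioning integer
    program is solved; otherwise a randomised relocation local search is
    run from ``start`` (or a uniform random assignment).
    """
    if g.n_edges == 0:
        raise ValueError("cannot partition an edgeless graph")
    n = g.n_nodes
    m_max = cfg.resolved_m_max(n)
    if m_max <= 1:
        return Partition.single_module(g), True
    if n <= cfg.exact_threshold:
        labels, optimal = solve_exact_full(g, m_max, cfg.time_limit_s)
        if labels is not None:
            return Partition(g, labels).canonicalize(), optimal
        logger.warning("exact stage-1 solve failed; falling back to local search")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if start is not None:
        labels = start.labels.copy()
        if labels.max() >= m_max:
            raise ValueError("start partition uses more modules than m_max")
    else:
        labels = rng.integers(0, m_max, size=n)
    labels = local_search(g, labels, m_max, rng)
    return Partition(g, labels).canonicalize(), False


def initial_partition(g: Graph, cfg: SolverConfig) -> tuple[Partition, dict]:
    """Best partition over ``cfg.n_starts`` independent attempts.

    Returns the canonicalised best partition and an info dict with the
    integer comparison score, whether the solve was exact, and the number
    of attempts actually run (an exact solve is deterministic, so it is
    run once regardless of ``n_starts``).
    """
    if g.n_edges == 0:
        raise ValueError("cannot partition an edgeless graph")
    exact = g.n_nodes <= cfg.exact_threshold or cfg.resolved_m_max(g.n_nodes) <= 1
    if exact:
        part, optimal = solve_once(g, cfg)
        return part, {
            "score": modularity_score(g, part.labels),
            "exact": True,
            "proven_optimal": optimal,
            "attempts": 1,
        }
    ss = np.random.SeedSequence(cfg.seed)
    best_part, best_score = None, None
    for child in ss.spawn(cfg.n_starts):
        rng = np.random.default_rng(child)
        part, _ = solve_once(g, cfg, rng=rng)
        score = modularity_score(g, part.labels)
        if best_score is None or score > best_score:
            best_part, best_score = part, score
    return best_part, {
        "score": best_score,
        "exact": False,
        "proven_optimal": False,
        "attempts": cfg.n_starts,
    }
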