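"""Stage 2: iterative fix-and-release refinement of a partition.

Modules are visited in their canonical entry order.  For the module at
turn, its members are released in index-priority batches whose size is
capped by ``MAX_m^r = floor(U / Aver_m)`` (Aver_m = average intra-module
degree, inter-module links ignored; U defaults to 200).  Each released
batch is optimally — or, for large batches, locally — reassigned over the
existing modules with every other node frozen, and the incumbent is
updated after every solve.  Because the incumbent is always feasible in
the reduced problem, modularity never decreases.  One pass over all
modules is a major iteration; the loop stops when two successive major
iterations bring no improvement.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .config import SolverConfig
from .exact import solve_exact_reduced
from .graph import Graph
from .partition import Partition, modularity_score

logger = logging.getLogger(__name__)

__all__ = ["release_limit", "release_batches", "solve_reduced", "refine"]


def release_limit(
    g: Graph,
    p: Partition,
    module_id: int,
    u: float = 200.0,
    operator: str = "divide",
) -> int:
    """Per-module cap MAX_m^r on the number of simultaneously released nodes.

    ``Aver_m`` is the average degree inside the module's induced subgraph
    (inter-module links excluded).  With the default ``divide`` operator
    the cap is ``max(1, floor(u / Aver_m))``; a degree-0 module releases
    all its nodes at once.
    """
    members = p.members(module_id)
    if members.size == 0:
        raise ValueError(f"module {module_id} is empty")
    member_set = set(int(i) for i in members)
    intra = sum(
        1 for i, j in g.edges if int(i) in member_set and int(j) in member_set
    )
    aver = 2.0 * intra / members.size
    if aver == 0.0:
        return int(members.size)
    if operator == "divide":
        return max(1, math.floor(u / aver))
    if operator == "multiply":
        return max(1, math.floor(u * aver))
    raise ValueError(f"unknown release-cap operator {operator!r}")


def release_batches(p: Partition, module_id: int, cap: int) -> list[np.ndarray]:
    """Chunk a module's members into release batches of at most ``cap``.

    Members are sorted by internal node index ascending (smaller indices
    have higher priority) and chunked consecutively; every member appears
    in exactly one batch.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    members = np.sort(p.members(module_id))
    return [members[i : i + cap] for i in range(0, len(members), cap)]


def _restricted_local_search(
    g: Graph,
    labels: np.ndarray,
    released: np.ndarray,
    allowed: np.ndarray,
    max_rounds: int = 200,
) -> np.ndarray:
    """Relocation local search over the released nodes only."""
    L = g.n_edges
    deg = g.degrees
    labels = labels.copy()
    m = int(max(labels.max(), allowed.max())) + 1
    d_tot = np.bincount(labels, weights=deg, minlength=m).astype(np.int64)
    allowed = np.asarray(sorted(int(a) for a in allowed), dtype=np.int64)
    for _ in range(max_rounds):
        moved = False
        for n in released:
            n = int(n)
            a = int(labels[n])
            dn = int(deg[n])
            counts: dict = {}
            for e in g.adjacency[n]:
                me = int(labels[e])
                counts[me] = counts.get(me, 0) + 1
            l_na = counts.get(a, 0)
            best_gain, best_m = 0, a
            for b in allowed:
                b = int(b)
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
                moved = True
        if not moved:
            break
    return labels


def solve_reduced(
    g: Graph,
    incumbent: Partition,
    released: np.ndarray,
    cfg: SolverConfig,
    allowed: np.ndarray | None = None,
) -> Partition:
    """Re-optimise the released nodes with all other assignments fixed.

    Released nodes may join any module that is non-empty in the incumbent
    (no new modules are opened here).  The incumbent is feasible, so the
    returned partition never has lower modularity; a failed exact solve
    falls back to the incumbent with a warning.
    """
    released = np.asarray(released, dtype=np.int64)
    if released.size == 0:
        raise ValueError("released set is empty")
    labels = incumbent.labels
    if allowed is None:
        allowed = np.unique(labels)
    s_old = modularity_score(g, labels)
    if released.size <= cfg.exact_threshold_reduced:
        new = solve_exact_reduced(g, labels, released, allowed, cfg.time_limit_s)
        if new is None:
            return incumbent
    else:
        new = _restricted_local_search(g, labels, released, allowed)
    s_new = modularity_score(g, new)
    if s_new < s_old:  # numerically impossible by construction; belt and braces
        logger.error("reduced solve degraded modularity; keeping incumbent")
        return incumbent
    return Partition(g, new)


def refine(
    g: Graph, p0: Partition, cfg: SolverConfig | None = None
) -> tuple[Partition, dict]:
    """Run the full fix-and-release refinement on a starting partition.

    Returns the canonicalised refined partition and an info dict with
    ``q_history`` (modularity after each major iteration), ``score_trace``
    (integer-scaled modularity after every reduced solve — non-decreasing
    by construction) and the major-iteration count.
    """
    if cfg is None:
        cfg = SolverConfig()
    L = g.n_edges
    if L == 0:
        raise ValueError("cannot refine a partition of an edgeless graph")
    p = p0.canonicalize().relabel_nodes(g) if p0.graph is not g else p0.canonicalize()
    module_order = list(range(p.n_modules))
    score = modularity_score(g, p.labels)
    score_trace = [score]
    q_history: list[float] = []
    no_improve = 0
    k = 0
    while no_improve < 2:
        if k >= cfg.max_major_iters:
            logger.warning("stage 2 hit the major-iteration cap (%d)", cfg.max_major_iters)
            break
        score_before = score
        for m in module_order:
            if not np.any(p.labels == m):
                continue  # evacuated earlier in the pass
            cap = release_limit(g, p, m, u=cfg.u, operator=cfg.eq8_operator)
            for batch in release_batches(p, m, cap):
                p = solve_reduced(g, p, batch, cfg)
                score = modularity_score(g, p.labels)
                score_trace.append(score)
        k += 1
        q_history.append(score / (4.0 * L * L))
        no_improve = 0 if score > score_before else no_improve + 1
    return p.canonicalize(), {
        "q_history": q_history,
        "score_trace": score_trace,
        "n_major_iters": k,
    }
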