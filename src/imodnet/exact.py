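"""Exact integer-programming solves for modularity maximisation.

Two formulations, both solved with HiGHS through :func:`scipy.optimize.milp`:

* the full problem as a clique-partitioning program — one binary variable
  per node pair saying "same module", transitivity enforced by triangle
  inequalities, module-count cap via representative variables;
* the reduced fix-and-release problem — binary assignment variables for
  the released nodes over the existing modules, linked to continuous
  pairwise variables (integrality of the pair variables is implied).

Objective coefficients use the integer-scaled modularity
S = 4 L^2 Q = sum over same-module pairs (n,e) of (4 L A_ne - 2 d_n d_e)
plus a partition-independent constant, so the exact optimum of S is the
exact optimum of Q.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .graph import Graph

logger = logging.getLogger(__name__)

__all__ = ["solve_exact_full", "solve_exact_reduced"]


def _pair_weights(g: Graph, idx: np.ndarray) -> tuple[np.ndarray, list]:
    """Integer objective weight 4L·A - 2 d_n d_e for each pair of ``idx``."""
    L = g.n_edges
    d = g.degrees
    edge_set = {(int(i), int(j)) for i, j in g.edges}
    pairs = list(itertools.combinations(range(len(idx)), 2))
    w = np.empty(len(pairs), dtype=np.float64)
    for p, (a, b) in enumerate(pairs):
        i, j = int(idx[a]), int(idx[b])
        key = (i, j) if i < j else (j, i)
        adj = 1 if key in edge_set else 0
        w[p] = 4 * L * adj - 2 * d[i] * d[j]
    return w, pairs


def solve_exact_full(
    g: Graph, m_max: int, time_limit_s: float = 60.0
) -> tuple[np.ndarray | None, bool]:
    """Globally maximise modularity by clique partitioning.

    Returns ``(labels, proven_optimal)``; ``labels`` is ``None`` when the
    solver produced no feasible point within the time budget.
    """
    n = g.n_nodes
    if n == 0:
        return np.empty(0, dtype=np.int64), True
    if m_max <= 1:
        return np.zeros(n, dtype=np.int64), True
    idx = np.arange(n)
    w, pairs = _pair_weights(g, idx)
    npairs = len(pairs)
    pidx = {p: k for k, p in enumerate(pairs)}

    rows, cols, vals, ub = [], [], [], []
    r = 0
    for i, j, k in itertools.combinations(range(n), 3):
        ij, jk, ik = pidx[(i, j)], pidx[(j, k)], pidx[(i, k)]
        for signs in ((1, 1, -1), (1, -1, 1), (-1, 1, 1)):
            rows += [r, r, r]
            cols += [ij, jk, ik]
            vals += list(signs)
            ub.append(1.0)
            r += 1

    nvars = npairs
    use_cap = m_max < n
    if use_cap:
        # rep_i >= 1 - sum_{e<i} x_ei  =>  rep_i + sum x_ei >= 1; sum rep <= m_max
        nvars += n
        for i in range(n):
            rows.append(r)
            cols.append(npairs + i)
            vals.append(1.0)
            for e in range(i):
                rows.append(r)
                cols.append(pidx[(e, i)])
                vals.append(1.0)
            r += 1
        cap_lb = [1.0] * n

    c = np.zeros(nvars)
    c[:npairs] = -w  # milp minimises
    a = sparse.coo_matrix((vals, (rows, cols)), shape=(r, nvars)).tocsc()
    lo = np.full(r, -np.inf)
    hi = np.full(r, np.inf)
    hi[: len(ub)] = ub
    if use_cap:
        lo[len(ub) :] = cap_lb
    constraints = [LinearConstraint(a, lo, hi)]
    if use_cap:
        sel = np.zeros(nvars)
        sel[npairs:] = 1.0
        constraints.append(LinearConstraint(sel, 0, m_max))
    integrality = np.zeros(nvars)
    integrality[:npairs] = 1
    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(0, 1),
        options={"time_limit": time_limit_s, "presolve": True},
    )
    if res.x is None:
        logger.warning("exact solve returned no feasible point (status %s)", res.status)
        return None, False
    # union-find over pairs declared same-module
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (i, j) in enumerate(pairs):
        if res.x[k] > 0.5:
            parent[find(i)] = find(j)
    roots: dict = {}
    labels = np.empty(n, dtype=np.int64)
    for i in range(n):
        root = find(i)
        labels[i] = roots.setdefault(root, len(roots))
    return labels, res.status == 0


def solve_exact_reduced(
    g: Graph,
    labels: np.ndarray,
    released: np.ndarray,
    allowed_modules: np.ndarray,
    time_limit_s: float = 60.0,
) -> np.ndarray | None:
    """Optimal reassignment of ``released`` nodes over the existing modules.

    All other nodes keep their current module.  Returns a full label
    array, or ``None`` if the solver failed (caller keeps the incumbent).
    """
    L = g.n_edges
    d = g.degrees
    released = np.asarray(released, dtype=np.int64)
    mods = np.asarray(allowed_modules, dtype=np.int64)
    nr, nm = len(released), len(mods)
    if nr == 0 or nm == 0:
        return labels.copy()
    rel_set = set(int(i) for i in released)
    mpos = {int(m): k for k, m in enumerate(mods)}

    # fixed-node degree mass and released->fixed link counts per module
    fixed_mask = np.ones(len(labels), dtype=bool)
    fixed_mask[released] = False
    dfix = np.zeros(nm, dtype=np.int64)
    for i in np.flatnonzero(fixed_mask):
        k = mpos.get(int(labels[i]))
        if k is not None:
            dfix[k] += d[i]
    links_fix = np.zeros((nr, nm), dtype=np.int64)
    for a, n in enumerate(released):
        for e in g.adjacency[n]:
            if int(e) not in rel_set:
                k = mpos.get(int(labels[e]))
                if k is not None:
                    links_fix[a, k] += 1

    w, pairs = _pair_weights(g, released)
    npairs = len(pairs)
    ny = nr * nm
    nvars = ny + npairs

    c = np.zeros(nvars)
    for a in range(nr):
        n = int(released[a])
        c[a * nm : (a + 1) * nm] = -(4 * L * links_fix[a] - 2 * d[n] * dfix)
    c[ny:] = -w

    rows, cols, vals, lo, hi = [], [], [], [], []
    r = 0
    for a in range(nr):  # assignment: sum_m Y_am = 1
        rows += [r] * nm
        cols += list(range(a * nm, (a + 1) * nm))
        vals += [1.0] * nm
        lo.append(1.0)
        hi.append(1.0)
        r += 1
    for p, (a, b) in enumerate(pairs):
        xcol = ny + p
        for k in range(nm):
            ya, yb = a * nm + k, b * nm + k
            # x >= Y_a + Y_b - 1 ; x <= 1 - Y_a + Y_b ; x <= 1 + Y_a - Y_b
            rows += [r, r, r]
            cols += [xcol, ya, yb]
            vals += [1.0, -1.0, -1.0]
            lo.append(-1.0)
            hi.append(np.inf)
            r += 1
            rows += [r, r, r]
            cols += [xcol, ya, yb]
            vals += [1.0, 1.0, -1.0]
            lo.append(-np.inf)
            hi.append(1.0)
            r += 1
            rows += [r, r, r]
            cols += [xcol, ya, yb]
            vals += [1.0, -1.0, 1.0]
            lo.append(-np.inf)
            hi.append(1.0)
            r += 1

    a_mat = sparse.coo_matrix((vals, (rows, cols)), shape=(r, nvars)).tocsc()
    integrality = np.zeros(nvars)
    integrality[:ny] = 1  # pair variables integral by implication
    res = milp(
        c,
        constraints=[LinearConstraint(a_mat, lo, hi)],
        integrality=integrality,
        bounds=Bounds(0, 1),
        options={"time_limit": time_limit_s, "presolve": True},
    )
    if res.x is None:
        logger.warning("reduced exact solve failed (status %s); keeping incumbent", res.status)
        return None
    out = labels.copy()
    y = res.x[:ny].reshape(nr, nm)
    out[released] = mods[np.argmax(y, axis=1)]
    return out
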