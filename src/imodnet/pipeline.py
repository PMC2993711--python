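"""End-to-end pipeline: two-stage detection, repeats, and benchmarking."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .config import SolverConfig
from .graph import Graph
from .metrics import nmi
from .partition import Partition, modularity
from .stage1 import initial_partition
from .stage2 import refine

logger = logging.getLogger(__name__)

__all__ = ["RunRecord", "run_imod", "run_benchmark"]


@dataclass
class RunRecord:
    """Provenance of one detection run (or a best-of-repeats run)."""

    seed: int | None
    config: dict
    q_stage1: float = float("nan")
    q_history: list = field(default_factory=list)
    q_final: float = float("nan")
    m_final: int = 0
    n_major_iters: int = 0
    exact: bool = False
    proven_optimal: bool = False
    wall_time_s: float = 0.0
    repeat_qs: list = field(default_factory=list)


def _run_single(g: Graph, cfg: SolverConfig) -> tuple[Partition, RunRecord]:
    t0 = time.perf_counter()
    p1, info1 = initial_partition(g, cfg)
    q1 = modularity(g, p1)
    p2, info2 = refine(g, p1, cfg)
    rec = RunRecord(
        seed=cfg.seed,
        config=cfg.to_dict(),
        q_stage1=q1,
        q_history=info2["q_history"],
        q_final=modularity(g, p2),
        m_final=p2.n_modules,
        n_major_iters=info2["n_major_iters"],
        exact=info1["exact"],
        proven_optimal=info1["proven_optimal"],
        wall_time_s=time.perf_counter() - t0,
    )
    return p2, rec


def run_imod(
    g: Graph, cfg: SolverConfig | None = None, repeats: int = 1
) -> tuple[Partition, RunRecord]:
    """Run the two-stage pipeline; with ``repeats`` > 1, keep the best run.

    Repeats use independent seeds derived from ``cfg.seed`` and the record
    carries every repeat's final modularity (best and median are how
    benchmark results are conventionally reported).
    """
    if cfg is None:
        cfg = SolverConfig()
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if repeats == 1:
        p, rec = _run_single(g, cfg)
        rec.repeat_qs = [rec.q_final]
        return p, rec
    t0 = time.perf_counter()
    ss = np.random.SeedSequence(cfg.seed)
    best: tuple[Partition, RunRecord] | None = None
    qs: list[float] = []
    for child in ss.spawn(repeats):
        sub_seed = int(child.generate_state(1)[0] >> 1)
        p, rec = _run_single(g, cfg.replace(seed=sub_seed))
        qs.append(rec.q_final)
        if best is None or rec.q_final > best[1].q_final:
            best = (p, rec)
    p, rec = best
    rec.seed = cfg.seed
    rec.repeat_qs = qs
    rec.wall_time_s = time.perf_counter() - t0
    return p, rec


def run_benchmark(
    degree: float = 16.0,
    mu_grid=(0.1, 0.2, 0.3, 0.4, 0.5),
    n_networks: int = 100,
    cfg: SolverConfig | None = None,
    n: int = 128,
    groups: int = 4,
):
    """Planted-partition recovery experiment.

    For each mixing parameter in ``mu_grid``, generates ``n_networks``
    graphs, runs detection on each and scores agreement with the planted
    structure by NMI.  Returns a DataFrame with one row per mu.
    """
    import pandas as pd

    from .generators import gn_benchmark

    if cfg is None:
        cfg = SolverConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rows = []
    for mu in mu_grid:
        if not (0.0 <= mu <= 0.5):
            raise ValueError("mixing parameters must lie in [0, 0.5]")
        scores, q_vals = [], []
        for child in ss.spawn(n_networks):
            gen_seed = int(child.generate_state(1)[0] >> 1)
            bench = gn_benchmark(n=n, groups=groups, degree=degree, mu=mu, seed=gen_seed)
            p, rec = run_imod(bench.graph, cfg.replace(seed=gen_seed + 1))
            scores.append(nmi(p, bench.truth))
            q_vals.append(rec.q_final)
        rows.append(
            {
                "mu": mu,
                "n_networks": n_networks,
                "mean_nmi": float(np.mean(scores)),
                "std_nmi": float(np.std(scores)),
                "mean_q": float(np.mean(q_vals)),
            }
        )
        logger.info("mu=%.2f mean NMI %.4f", mu, rows[-1]["mean_nmi"])
    return pd.DataFrame(rows)
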