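"""Algorithm configuration shared by both pipeline stages."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace


@dataclass
class SolverConfig:
    """Parameters of the two-stage modularity optimisation.

    Attributes
    ----------
    n_starts : int
        Number of randomised stage-1 attempts (N^max); the best-Q
        attempt seeds stage 2.  Default 100.
    m_max : int or None
        Upper bound on the module index set.  ``None`` means
        ``max(2, ceil(N/3))`` capped at 50, chosen at run time.
    seed : int or None
        Master seed for every random stream.
    u : float
        Release budget U of the per-module cap ``MAX_m^r = floor(U / Aver_m)``,
        where Aver_m is the module's average intra-module degree.  Default 200.
    eq8_operator : str
        ``"divide"`` (default) or ``"multiply"`` — how U combines with
        the average intra-module degree in the release cap.
    exact_threshold : int
        Node count at or below which stage 1 solves the clique-partitioning
        integer program to proven optimality instead of multi-start local
        search.
    exact_threshold_reduced : int
        Released-batch size at or below which the reduced fix-and-release
        problem is solved exactly.
    time_limit_s : float
        Wall-clock budget per exact solve.
    max_major_iters : int
        Safety cap on stage-2 major iterations.
    """

    n_starts: int = 100
    m_max: int | None = None
    seed: int | None = None
    u: float = 200.0
    eq8_operator: str = "divide"
    exact_threshold: int = 16
    exact_threshold_reduced: int = 24
    time_limit_s: float = 60.0
    max_major_iters: int = 100

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.m_max is not None and self.m_max < 1:
            raise ValueError("m_max must be >= 1")
        if self.eq8_operator not in ("divide", "multiply"):
            raise ValueError("eq8_operator must be 'divide' or 'multiply'")
        if self.u <= 0:
            raise ValueError("U must be positive")

    def resolved_m_max(self, n_nodes: int) -> int:
        """Effective module-index-set size for a graph of ``n_nodes``."""
        if self.m_max is not None:
            return min(self.m_max, n_nodes)
        return min(max(2, math.ceil(n_nodes / 3)), 50, n_nodes)

    def replace(self, **kwargs) -> "SolverConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def echo(self) -> str:
        """Compact one-line echo for file headers and logs."""
        return " ".join(f"{k}={v}" for k, v in self.to_dict().items())
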