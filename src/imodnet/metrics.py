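"""Partition-similarity scoring: normalised mutual information (NMI).

The confusion-matrix form

    NMI = -2 sum_ij N_ij ln(N_ij N / (N_i N_j))
          / [ sum_i N_i ln(N_i / N) + sum_j N_j ln(N_j / N) ]

with the 0 ln 0 = 0 convention; this equals 2 I(A;B) / (H(A) + H(B)).
Ranges from 0 (independent) to 1 (identical up to relabeling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .partition import Partition

__all__ = ["ConfusionTable", "nmi"]


@dataclass(frozen=True)
class ConfusionTable:
    """Joint module-membership counts N_ij between two partitions."""

    counts: np.ndarray
    row_marginals: np.ndarray
    col_marginals: np.ndarray
    n: int

    @classmethod
    def from_partitions(cls, a: Partition, b: Partition) -> "ConfusionTable":
        if list(a.graph.nodes) != list(b.graph.nodes):
            raise ValueError("partitions cover different node sets")
        la = a.canonicalize().labels
        lb = b.canonicalize().labels
        ka, kb = int(la.max()) + 1, int(lb.max()) + 1
        counts = np.zeros((ka, kb), dtype=np.int64)
        np.add.at(counts, (la, lb), 1)
        return cls(
            counts=counts,
            row_marginals=counts.sum(axis=1),
            col_marginals=counts.sum(axis=0),
            n=len(la),
        )


def nmi(a: Partition, b: Partition) -> float:
    """Normalised mutual information between two partitions.

    Degenerate single-module cases follow the range semantics: two
    single-module partitions are identical (1.0); a single-module
    partition carries no information about a non-trivial one (0.0).
    """
    t = ConfusionTable.from_partitions(a, b)
    single_a = len(t.row_marginals) == 1
    single_b = len(t.col_marginals) == 1
    if single_a and single_b:
        return 1.0
    if single_a or single_b:
        return 0.0
    n = t.n
    nz = t.counts > 0
    cij = t.counts[nz].astype(float)
    outer = np.outer(t.row_marginals, t.col_marginals)[nz].astype(float)
    num = -2.0 * float(np.sum(cij * np.log(cij * n / outer)))
    ha = float(np.sum(t.row_marginals * np.log(t.row_marginals / n)))
    hb = float(np.sum(t.col_marginals * np.log(t.col_marginals / n)))
    value = num / (ha + hb)
    return min(1.0, max(0.0, value))
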