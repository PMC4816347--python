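"""Coexpression network construction (WGCNA-style).

A similarity matrix S becomes a weighted adjacency by soft thresholding,
a_ij = S_ij ** beta (beta = 6 by default, the WGCNA convention), which
preserves the ranking of similarities while shrinking weak ones toward 0.
A binary network is obtained instead by hard thresholding at a cutoff tau
(strictly greater-than).  Self-loops are never kept: the diagonal of every
adjacency is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .similarity import SimilarityMatrix

__all__ = [
    "WeightedGraph",
    "SoftThresholdConfig",
    "soft_threshold_adjacency",
    "hard_threshold",
    "concat_replicates",
]


@dataclass
class WeightedGraph:
    """Undirected network: symmetric adjacency in [0, 1], zero diagonal."""

    adjacency: np.ndarray
    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        n = a.shape[0]
        if a.ndim != 2 or a.shape != (n, n):
            raise ValueError("adjacency must be a square matrix")
        if not np.allclose(a, a.T, atol=1e-9):
            raise ValueError("adjacency must be symmetric")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")
        a = np.clip((a + a.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(a, 0.0)
        self.adjacency = a
        if not self.labels:
            self.labels = tuple(f"n{i + 1}" for i in range(n))
        elif len(self.labels) != n:
            raise ValueError("label count does not match adjacency size")
        else:
            self.labels = tuple(str(x) for x in self.labels)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @classmethod
    def empty(cls, n: int, labels=None) -> "WeightedGraph":
        return cls(np.zeros((n, n)), tuple(labels) if labels else ())

    @classmethod
    def full(cls, n: int, labels=None) -> "WeightedGraph":
        a = np.ones((n, n))
        np.fill_diagonal(a, 0.0)
        return cls(a, tuple(labels) if labels else ())

    def edge_count(self, tol: float = 0.0) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1) > tol))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.adjacency, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class SoftThresholdConfig:
    """Soft-threshold exponent; WGCNA default beta = 6."""

    beta: float = 6.0

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")


def soft_threshold_adjacency(
    S: SimilarityMatrix, cfg: SoftThresholdConfig | None = None
) -> WeightedGraph:
    """Raise similarities to the power beta; diagonal zeroed (no self-loops)."""
    cfg = cfg or SoftThresholdConfig()
    a = np.power(np.clip(S.matrix, 0.0, 1.0), cfg.beta)
    np.fill_diagonal(a, 0.0)
    return WeightedGraph(a, S.labels)


def hard_threshold(G: WeightedGraph, tau: float) -> WeightedGraph:
    """Binary graph with an edge wherever the weight is strictly above tau."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    return WeightedGraph((G.adjacency > tau).astype(float), G.labels)


def concat_replicates(replicates: list[pd.DataFrame]) -> pd.DataFrame:
    """Join replicate time courses end to end, replicate order preserved.

    The last timepoint of replicate i is followed by the first timepoint of
    replicate i + 1, so R replicates of T timepoints yield one series of
    R * T points per gene.  All replicates must share the gene set and the
    per-replicate length; genes are aligned to the first replicate's order.
    """
    if not replicates:
        raise ValueError("no replicates given")
    first = replicates[0]
    width = first.shape[1]
    genes = list(first.index)
    blocks = []
    for r, rep in enumerate(replicates, start=1):
        if set(rep.index) != set(genes):
            raise ValueError(f"replicate {r} gene set differs from replicate 1")
        if rep.shape[1] != width:
            raise ValueError(
                f"replicate {r} has {rep.shape[1]} timepoints, expected {width}"
            )
        block = rep.loc[genes]
        block = block.set_axis([f"r{r}:{c}" for c in block.columns], axis=1)
        blocks.append(block)
    return pd.concat(blocks, axis=1)
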