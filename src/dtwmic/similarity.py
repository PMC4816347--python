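"""Pairwise similarity measures on expression time series.

Four measures are exposed: Pearson correlation (PCC), the maximal
information coefficient (MIC), the DTW similarity DTW_s = 1/(1 + DTW_d),
and their combination

    DTW-MIC(T1, T2) = sqrt( (DTW_s(T1, T2)^2 + MIC(T1, T2)^2) / 2 ),

the root mean square of a shape/time-shift term (DTW_s) and a functional
dependence term (MIC).  DTW-MIC lies in [0, 1], between min and max of its
two components, and equals 1 only when both do.

`similarity_matrix` assembles the all-pairs symmetric matrix used for
network construction; for PCC it stores |PCC| so every measure lands in
[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dtw import dtw_distance, dtw_similarity
from .mine import MicParams, mic

__all__ = [
    "MEASURES",
    "SimilarityMatrix",
    "pcc",
    "dtw_mic",
    "similarity_matrix",
    "dtw_distance",
    "dtw_similarity",
    "mic",
    "MicParams",
]

MEASURES = ("pcc", "mic", "dtw", "dtwmic")


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValueError("input contains non-finite values")
    return xa, ya


def pcc(x, y, absolute: bool = False) -> float:
    """Sample Pearson correlation between two equal-length series.

    Parameters
    ----------
    absolute
        Return |PCC| (the unsigned WGCNA convention) instead of the signed
        value.

    Raises
    ------
    ValueError
        On length mismatch, n < 2, or a constant (zero-variance) series,
        where the coefficient is undefined.
    """
    xa, ya = _check_pair(x, y)
    if xa.size < 2:
        raise ValueError("PCC needs at least 2 points")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("PCC is undefined for constant series (zero variance)")
    xa = xa - xa.mean()
    ya = ya - ya.mean()
    r = float(xa @ ya / np.sqrt((xa @ xa) * (ya @ ya)))
    r = max(-1.0, min(1.0, r))
    return abs(r) if absolute else r


def dtw_mic(x, y, params: MicParams | None = None) -> float:
    """Root mean square of DTW_s and MIC, in [0, 1]."""
    xa, ya = _check_pair(x, y)
    ds = dtw_similarity(xa, ya)
    mc = mic(xa, ya, params)
    return float(np.sqrt(0.5 * (ds * ds + mc * mc)))


@dataclass
class SimilarityMatrix:
    """Symmetric gene-by-gene matrix of one similarity measure.

    Entries are in [0, 1] (|PCC| is stored for measure 'pcc'); the diagonal
    is 1 by convention for non-constant series.
    """

    measure: str
    matrix: np.ndarray
    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; expected one of {MEASURES}")
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("similarity matrix must be square")
        if not self.labels:
            self.labels = tuple(f"g{i + 1}" for i in range(n))
        if len(self.labels) != n:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if self.matrix.min() < -1e-12 or self.matrix.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels), columns=list(self.labels))


def _pairwise(measure: str, params: MicParams | None):
    if measure == "pcc":
        return lambda a, b: pcc(a, b, absolute=True)
    if measure == "mic":
        return lambda a, b: mic(a, b, params)
    if measure == "dtw":
        return dtw_similarity
    if measure == "dtwmic":
        return lambda a, b: dtw_mic(a, b, params)
    raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")


def similarity_matrix(
    data: pd.DataFrame | np.ndarray,
    measure: str = "dtwmic",
    params: MicParams | None = None,
) -> SimilarityMatrix:
    """All-pairs similarity of the rows of a gene-by-timepoint matrix.

    Returns a symmetric matrix with unit diagonal; a failure on any pair is
    re-raised naming the offending pair of row labels.
    """
    if isinstance(data, pd.DataFrame):
        labels = tuple(str(i) for i in data.index)
        values = data.to_numpy(dtype=float)
    else:
        values = np.asarray(data, dtype=float)
        labels = tuple(f"g{i + 1}" for i in range(values.shape[0]))
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 series")
    fn = _pairwise(measure, params)
    n = values.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                out[i, j] = out[j, i] = fn(values[i], values[j])
            except ValueError as exc:
                raise ValueError(
                    f"{measure} failed for pair ({labels[i]}, {labels[j]}): {exc}"
                ) from exc
    return SimilarityMatrix(measure=measure, matrix=out, labels=labels)
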