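"""Dynamic time warping distance and similarity.

The distance follows the classic symmetric2 recursion with absolute-difference
local cost,

    D(i, j) = min( D(i-1, j) + d(i, j),
                   D(i, j-1) + d(i, j),
                   D(i-1, j-1) + 2 d(i, j) ),     D(1, 1) = d(1, 1),

normalized by the summed series lengths, DTW_d = D(n, m) / (n + m).  The
diagonal weight of 2 makes the total path weight equal n + m for every
admissible path, so the normalization yields a per-step average cost and
distances between series of different lengths are comparable.

DTW_s = 1 / (1 + DTW_d) maps the distance to a similarity in (0, 1], equal to
1 exactly when the two series are identical up to warping cost zero.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dtw_distance", "dtw_similarity"]


def _dtw_cost_py(x: np.ndarray, y: np.ndarray) -> float:
    n = x.shape[0]
    m = y.shape[0]
    prev = np.empty(m)
    curr = np.empty(m)
    prev[0] = abs(x[0] - y[0])
    for j in range(1, m):
        prev[j] = prev[j - 1] + abs(x[0] - y[j])
    for i in range(1, n):
        curr[0] = prev[0] + abs(x[i] - y[0])
        for j in range(1, m):
            d = abs(x[i] - y[j])
            best = prev[j] + d
            cand = curr[j - 1] + d
            if cand < best:
                best = cand
            cand = prev[j - 1] + 2.0 * d
            if cand < best:
                best = cand
            curr[j] = best
        prev, curr = curr, prev
    return prev[m - 1]


try:  # pragma: no cover - plain-python fallback keeps results identical, only slower
    from numba import njit

    _dtw_cost = njit(cache=False)(_dtw_cost_py)
except Exception:  # pragma: no cover
    _dtw_cost = _dtw_cost_py


def _as_series(x, name: str = "series") -> np.ndarray:
    arr = np.ascontiguousarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def dtw_distance(x, y) -> float:
    """Normalized DTW distance between two series (symmetric2 step pattern).

    Parameters
    ----------
    x, y
        One-dimensional sequences of finite reals; lengths may differ.

    Returns
    -------
    float
        ``D(n, m) / (n + m)`` for the optimal warping path; 0 iff the optimal
        alignment has zero cost (in particular for ``x == y``).
    """
    xa = _as_series(x, "x")
    ya = _as_series(y, "y")
    return float(_dtw_cost(xa, ya)) / (xa.size + ya.size)


def dtw_similarity(x, y) -> float:
    """DTW similarity ``1 / (1 + DTW_d)``, in (0, 1]."""
    return 1.0 / (1.0 + dtw_distance(x, y))
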