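"""Maximal Information Coefficient (MIC).

MIC scores the association between two samples x, y by gridding their
scatterplot: for every grid of k columns by l rows with k*l below the budget
B(n) = n**alpha, the mutual information of the induced discretization is
maximized over grid placements and normalized by log min(k, l); MIC is the
largest normalized value over all admissible grid sizes.  A noiseless
functional relationship (with enough data) reaches the upper bound 1, while
independent samples score near 0.

The maximization uses the standard heuristic: one axis is equipartitioned
into l rows, and the column edges are chosen by dynamic programming over
"clumps" (maximal runs of x-consecutive points lying in a single row, with
x-ties kept together).  When there are many clumps, adjacent ones are merged
down to at most c*k superclumps before the DP.  Both axis orientations are
searched and the best cell wins.  With the default alpha = 0.6 and clump
factor c = 15 this matches the estimator popularized by the MINE statistics.

Only MIC is provided; the sibling MINE statistics (MAS, MEV, MCN) are out of
scope here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["MicParams", "mic"]

#: sample size below which the MIC estimate is considered unreliable
MIC_RELIABLE_N = 50


@dataclass(frozen=True)
class MicParams:
    """Tuning knobs of the MIC grid search.

    alpha
        Exponent of the grid-size budget ``B(n) = n**alpha``; grids are
        restricted to ``k * l <= B(n)``.  Must be in (0, 1].
    c
        Clump factor: at most ``c * k`` superclumps are kept when optimizing
        a k-column partition.  Must be >= 1.
    """

    alpha: float = 0.6
    c: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.c < 1.0:
            raise ValueError(f"c must be >= 1, got {self.c}")


def _equipartition(values: np.ndarray, l: int) -> np.ndarray:
    """Assign each point to one of <= l rows, balancing row sizes.

    Points sharing a value always land in the same row.  Returns the row id
    per point, aligned with `values`.
    """
    n = values.size
    order = np.argsort(values, kind="stable")
    sv = values[order]
    rows_sorted = np.empty(n, dtype=np.int64)
    i = 0
    curr = 0
    in_curr = 0
    desired = n / l
    while i < n:
        j = i + 1
        while j < n and sv[j] == sv[i]:
            j += 1
        size = j - i
        if (
            in_curr != 0
            and curr < l - 1
            and abs(in_curr + size - desired) >= abs(in_curr - desired)
        ):
            curr += 1
            in_curr = 0
            desired = (n - i) / (l - curr)
        rows_sorted[i:j] = curr
        in_curr += size
        i = j
    rows = np.empty(n, dtype=np.int64)
    rows[order] = rows_sorted
    return rows


def _clumps(x: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Clump sizes along the x axis given the row assignment.

    A clump is a maximal run of x-consecutive points with a common row;
    points with tied x values stay together (a tie group spanning several
    rows forms its own clump).  Returns the array of clump sizes in x order.
    """
    n = x.size
    order = np.argsort(x, kind="stable")
    sx = x[order]
    srow = rows[order]
    sizes: list[int] = []
    labels: list[int] = []  # row id, or -(group)-1 for mixed tie groups
    i = 0
    group = 0
    while i < n:
        j = i + 1
        while j < n and sx[j] == sx[i]:
            j += 1
        seg = srow[i:j]
        label = int(seg[0]) if np.all(seg == seg[0]) else -group - 1
        if labels and label >= 0 and labels[-1] == label:
            sizes[-1] += j - i
        else:
            sizes.append(j - i)
            labels.append(label)
        group += 1
        i = j
    # per-clump row counts need the point -> clump map
    bounds = np.cumsum(sizes)
    clump_of_sorted = np.repeat(np.arange(len(sizes)), sizes)
    counts = np.zeros((len(sizes), int(rows.max()) + 1), dtype=np.int64)
    np.add.at(counts, (clump_of_sorted, srow), 1)
    del bounds
    return counts


def _superclumps(counts: np.ndarray, k_hat: int) -> np.ndarray:
    """Merge adjacent clumps down to at most k_hat, balancing point counts."""
    m = counts.shape[0]
    if m <= k_hat:
        return counts
    sizes = counts.sum(axis=1)
    n = int(sizes.sum())
    out = np.zeros((k_hat, counts.shape[1]), dtype=np.int64)
    curr = 0
    in_curr = 0
    done = 0
    desired = n / k_hat
    for idx in range(m):
        size = int(sizes[idx])
        if (
            in_curr != 0
            and curr < k_hat - 1
            and abs(in_curr + size - desired) >= abs(in_curr - desired)
        ):
            curr += 1
            in_curr = 0
            desired = (n - done) / (k_hat - curr)
        out[curr] += counts[idx]
        in_curr += size
        done += size
    return out[: curr + 1]


def _xlogx(a: np.ndarray) -> np.ndarray:
    out = np.zeros_like(a, dtype=float)
    mask = a > 0
    out[mask] = a[mask] * np.log(a[mask])
    return out


def _best_mi_per_columns(counts: np.ndarray, k_max: int) -> np.ndarray:
    """Max mutual information over column partitions with <= k columns.

    `counts` is the superclump-by-row contingency table.  Returns an array
    ``mi[k]`` for k = 2..k_max (index 0 -> 2 columns), each the maximum of
    I(P; Q) in nats over partitions of the superclumps into at most k
    contiguous columns; maximizing I is equivalent to minimizing the total
    (unnormalized) conditional entropy sum_j n_j H(Q | column j).
    """
    m = counts.shape[0]
    n = int(counts.sum())
    cum = np.zeros((m + 1, counts.shape[1]), dtype=np.int64)
    np.cumsum(counts, axis=0, out=cum[1:])
    csum = cum.sum(axis=1)
    # seg[s, t] = n_(s,t] * H(Q | clumps s+1..t), for s < t
    seg_counts = cum[None, :, :] - cum[:, None, :]
    seg_tot = csum[None, :] - csum[:, None]
    seg = _xlogx(seg_tot.astype(float)) - _xlogx(seg_counts.astype(float)).sum(axis=2)

    hq = float(n * np.log(n) - _xlogx(cum[m].astype(float)).sum()) / n

    k_cap = min(k_max, m)
    # F[t] = min cost of partitioning first t clumps into exactly `cols` columns
    F = seg[0, : m + 1].copy()  # one column
    best = np.empty(max(k_max - 1, 1), dtype=float)
    running = F[m]
    for cols in range(2, k_cap + 1):
        cand = F[:, None] + seg  # cand[s, t]
        F = cand[:m, 1 : m + 1].min(axis=0)
        F = np.concatenate(([np.inf], F))
        running = min(running, F[m])
        best[cols - 2] = hq - running / n
    for cols in range(k_cap + 1, k_max + 1):
        best[cols - 2] = hq - running / n
    return np.maximum(best[: max(k_max - 1, 0)], 0.0)


def mic(x, y, params: MicParams | None = None) -> float:
    """MIC association between two equal-length samples, in [0, 1].

    Constant input yields 0 (no association can be detected) with a warning,
    as does any pairing against it.  Short series (n < 50) trigger a
    reliability warning but are still scored.

    Raises
    ------
    ValueError
        If the lengths differ, n < 4, or values are non-finite.
    """
    params = params or MicParams()
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    n = xa.size
    if n < 4:
        raise ValueError(f"MIC needs at least 4 points, got {n}")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise ValueError("MIC input contains non-finite values")
    if n < MIC_RELIABLE_N:
        warnings.warn(
            f"MIC on {n} points is unreliable; at least {MIC_RELIABLE_N} are recommended",
            stacklevel=2,
        )
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        warnings.warn("constant series carry no information; MIC set to 0", stacklevel=2)
        return 0.0

    budget = max(float(n) ** params.alpha, 4.0)
    best = 0.0
    for a, b in ((xa, ya), (ya, xa)):
        l = 2
        while 2 * l <= budget:
            k_max = int(budget / l)
            rows = _equipartition(b, l)
            n_rows = int(rows.max()) + 1
            if n_rows < 2:  # massive ties collapsed the partition
                l += 1
                continue
            counts = _clumps(a, rows)
            counts = _superclumps(counts, max(int(params.c * k_max), k_max))
            mi_k = _best_mi_per_columns(counts, k_max)
            for k in range(2, k_max + 1):
                denom = np.log(min(k, l))
                val = mi_k[k - 2] / denom
                if val > best:
                    best = val
            l += 1
    return float(min(best, 1.0))
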