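"""Null-model significance thresholds for DTW similarity.

How large can DTW_s get between series that share nothing but their value
range?  The null model answers by drawing 2N i.i.d. vectors uniform on
[m, M]^n_points, pairing them up, and collecting the N DTW_s values; their
mean is the no-information level used as a significance threshold, and a
Student-t bootstrap confidence interval quantifies its uncertainty.  An
observed similarity is called significant when it exceeds the null mean.

The bounds m < M are taken from the data under scrutiny (the global min and
max over the series being compared), so the null vectors live on the same
scale as the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dtw import dtw_similarity

__all__ = [
    "NullModelConfig",
    "NullModelResult",
    "null_dtw_threshold",
    "range_bounds",
    "is_significant",
]


@dataclass(frozen=True)
class NullModelConfig:
    """Parameters of the uniform-noise DTW null model.

    m, M_up
        Value bounds of the uniform draws (m < M_up).
    n_points
        Length of each null vector (default 100).
    N
        Number of null pairs, i.e. DTW_s samples (default 1000).
    B
        Bootstrap resamples for the confidence interval (default 1000).
    level
        Confidence level of the Student-t bootstrap interval (default 0.95).
    seed
        Seed of the generator driving both the vectors and the bootstrap.
    """

    m: float
    M_up: float
    n_points: int = 100
    N: int = 1000
    B: int = 1000
    level: float = 0.95
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.m < self.M_up:
            raise ValueError(f"need m < M_up, got m={self.m}, M_up={self.M_up}")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.N < 2 and self.B > 0:
            raise ValueError("confidence interval needs N >= 2")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")


@dataclass(frozen=True)
class NullModelResult:
    """Mean DTW_s under the null, its bootstrap CI, and the raw samples."""

    mean: float
    ci_low: float
    ci_high: float
    samples: np.ndarray = field(repr=False)


def range_bounds(series) -> tuple[float, float]:
    """Global (min, max) over all values of all given series."""
    series = list(series)
    if not series:
        raise ValueError("empty series list")
    lo = min(float(np.min(s)) for s in series)
    hi = max(float(np.max(s)) for s in series)
    return lo, hi


def null_dtw_threshold(cfg: NullModelConfig) -> NullModelResult:
    """Mean DTW_s between N pairs of uniform random vectors, with t-bootstrap CI.

    The "Student bootstrap" interval is a t-interval on bootstrap resamples
    of the mean: mean +/- t_{(1+level)/2, B-1} * sd(bootstrap means).
    """
    rng = np.random.default_rng(cfg.seed)
    eta = rng.uniform(cfg.m, cfg.M_up, size=(2 * cfg.N, cfg.n_points))
    samples = np.array(
        [dtw_similarity(eta[j], eta[j + cfg.N]) for j in range(cfg.N)]
    )
    mean = float(samples.mean())
    if cfg.B > 0 and cfg.N >= 2:
        idx = rng.integers(0, cfg.N, size=(cfg.B, cfg.N))
        boot_means = samples[idx].mean(axis=1)
        t_crit = stats.t.ppf(0.5 + cfg.level / 2.0, df=cfg.B - 1)
        half = float(t_crit * boot_means.std(ddof=1))
        ci_low, ci_high = mean - half, mean + half
    else:
        ci_low = ci_high = mean
    return NullModelResult(mean=mean, ci_low=ci_low, ci_high=ci_high, samples=samples)


def is_significant(value: float, result: NullModelResult) -> bool:
    """True iff the observed similarity strictly exceeds the null mean."""
    return value > result.mean
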