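"""Hamming, Ipsen-Mikhailov and HIM distances between networks.

For two undirected weighted graphs on the same node set the Hamming
distance is the normalized edge-wise difference

    H = sum_{i != j} |a_ij - b_ij| / (n (n - 1))   in [0, 1],

a purely local score: 0 for identical adjacencies, 1 for empty vs full.

The Ipsen-Mikhailov distance compares global structure through Laplacian
spectra.  With omega_i = sqrt(lambda_i) over the n - 1 trailing eigenvalues
of L = D - A (the "vibrational frequencies" of the graph), each graph gets
a Lorentzian spectral density

    rho(omega) = K sum_i gamma / ((omega - omega_i)^2 + gamma^2),

K chosen so that rho integrates to 1 on [0, inf), and

    IM = sqrt( integral_0^inf (rho_1 - rho_2)^2 domega ).

The half-width gamma is calibrated per node count so that the empty/full
pair — the most distant possible — scores exactly 1.  Isospectral graphs
score 0 by construction, which is expected behavior for a spectral metric.

HIM combines the two at equal weight, normalized back to [0, 1]:

    HIM = sqrt(H^2 + IM^2) / sqrt(2),

i.e. the Euclidean norm of the point (H, IM) in the H-by-IM plane divided
by sqrt(2); it is 0 only for graphs equal both edge-wise and spectrally and
1 only for the empty/full pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .network import WeightedGraph

__all__ = [
    "IMCalibration",
    "NetworkDistanceResult",
    "laplacian_spectrum",
    "calibrate_gamma",
    "ipsen_mikhailov",
    "hamming_distance",
    "him_distance",
]

#: quadrature absolute tolerance for the spectral density integrals
_QUAD_TOL = 1e-10


@dataclass(frozen=True)
class IMCalibration:
    """Lorentzian half-width gamma for a given node count.

    Satisfies IM(empty_n, full_n; gamma) = 1 to the calibration tolerance.
    """

    n: int
    gamma: float

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class NetworkDistanceResult:
    """The (H, IM, HIM) triple plus the H-by-IM-plane coordinates."""

    hamming: float
    im: float
    him: float
    plane_point: tuple[float, float]


def _check_same_nodes(G1: WeightedGraph, G2: WeightedGraph) -> None:
    if G1.n != G2.n:
        raise ValueError(f"node count mismatch: {G1.n} vs {G2.n}")
    if G1.labels != G2.labels:
        raise ValueError("node labels differ between the two graphs")


def hamming_distance(G1: WeightedGraph, G2: WeightedGraph) -> float:
    """Normalized sum of absolute adjacency differences, in [0, 1]."""
    _check_same_nodes(G1, G2)
    n = G1.n
    return float(np.abs(G1.adjacency - G2.adjacency).sum() / (n * (n - 1)))


def laplacian_spectrum(G: WeightedGraph) -> np.ndarray:
    """Eigenvalues of L = D - A, ascending; tiny negatives clamped to 0."""
    a = G.adjacency
    lap = np.diag(a.sum(axis=1)) - a
    lam = np.linalg.eigvalsh(lap)
    if lam[0] < -1e-9:
        raise ValueError(f"Laplacian has negative eigenvalue {lam[0]}")
    return np.clip(lam, 0.0, None)


def _omegas(spectrum: np.ndarray) -> np.ndarray:
    # drop the structural zero eigenvalue, keep the n - 1 others
    return np.sqrt(spectrum[1:])


def _density_pair(om1: np.ndarray, om2: np.ndarray, gamma: float) -> float:
    """integral_0^inf (rho_1 - rho_2)^2 for two frequency sets."""
    k1 = 1.0 / (np.pi / 2 + np.arctan(om1 / gamma)).sum()
    k2 = 1.0 / (np.pi / 2 + np.arctan(om2 / gamma)).sum()

    def diff(w: float) -> float:
        r1 = k1 * (gamma / ((w - om1) ** 2 + gamma**2)).sum()
        r2 = k2 * (gamma / ((w - om2) ** 2 + gamma**2)).sum()
        return (r1 - r2) ** 2

    w_max = float(max(om1.max(initial=0.0), om2.max(initial=0.0)))
    cut = w_max + 50.0 * gamma
    pts = np.unique(np.concatenate([om1, om2]))
    total, _ = quad(diff, 0.0, cut, points=list(pts), limit=400,
                    epsabs=_QUAD_TOL, epsrel=_QUAD_TOL)
    tail, _ = quad(diff, cut, np.inf, limit=200, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL)
    return total + tail


@lru_cache(maxsize=None)
def calibrate_gamma(n: int, tol: float = 1e-12) -> IMCalibration:
    """Solve IM(empty_n, full_n; gamma) = 1 for gamma by bracketed root search.

    The distance is monotone decreasing in gamma (narrow Lorentzians separate
    the spectra sharply), so a simple bracket expansion around [1e-3, 1]
    always encloses the root; cached per node count.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    om_empty = np.zeros(n - 1)
    om_full = np.full(n - 1, np.sqrt(float(n)))

    def f(gamma: float) -> float:
        return np.sqrt(_density_pair(om_empty, om_full, gamma)) - 1.0

    lo, hi = 1e-3, 1.0
    while f(lo) < 0 and lo > 1e-12:
        lo /= 10.0
    while f(hi) > 0 and hi < 1e6:
        hi *= 10.0
    if not (f(lo) > 0 > f(hi)):
        raise RuntimeError(f"gamma root not bracketed in [{lo}, {hi}] for n={n}")
    gamma = brentq(f, lo, hi, xtol=tol)
    return IMCalibration(n=n, gamma=float(gamma))


def ipsen_mikhailov(
    G1: WeightedGraph, G2: WeightedGraph, cal: IMCalibration | None = None
) -> float:
    """Calibrated Lorentzian spectral distance, in [0, 1]; 0 for isospectral pairs."""
    _check_same_nodes(G1, G2)
    if cal is None:
        cal = calibrate_gamma(G1.n)
    elif cal.n != G1.n:
        raise ValueError(f"calibration is for n={cal.n}, graphs have n={G1.n}")
    om1 = _omegas(laplacian_spectrum(G1))
    om2 = _omegas(laplacian_spectrum(G2))
    if np.allclose(om1, om2, atol=1e-12):
        return 0.0
    return float(np.sqrt(_density_pair(om1, om2, cal.gamma)))


def him_distance(
    G1: WeightedGraph, G2: WeightedGraph, cal: IMCalibration | None = None
) -> NetworkDistanceResult:
    """The HIM distance sqrt(H^2 + IM^2)/sqrt(2) with its components."""
    h = hamming_distance(G1, G2)
    im = ipsen_mikhailov(G1, G2, cal)
    him = float(np.sqrt(h * h + im * im) / np.sqrt(2.0))
    return NetworkDistanceResult(hamming=h, im=im, him=him, plane_point=(h, im))
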