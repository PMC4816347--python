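"""Self-contained synthetic fixtures and a toy time-course simulator.

The four worked examples exercise every piece of the pipeline without any
external data:

* E1 — five 100-point series A..E illustrating linear, logarithmic and
  trigonometric functional relations (plus a 20%-uniform-noise copy C of A),
  where MIC detects dependence that PCC misses.
* E2 — a damped oscillation r(i) = (1/10) i^(3/2) e^(-2i/25) sin(3i/20) and
  its shifted/noisy family r_s^[k], the testbed contrasting DTW_s with PCC
  under time shifts, and the input of the null-model thresholds.
* E3 — three series G1, G2, G3 with pairwise relations of different nature
  (time shift vs non-linear dependence) that only DTW-MIC scores highly.
* E4 — four small graphs (empty, full, one edge, four edges with a
  triangle) on 4 nodes, pairwise non-isospectral, for the H/IM/HIM metric.

Unadorned "log" in the E1/E3 closed forms is base 10; the time index is
1-based, i = 1..100.  Uniform noise is written eps(z) ~ U(-z, z), so
eps(0) is identically zero and deterministic fixtures stay deterministic.

`simulate_timecourse` is a deliberately small linear-dynamics generator —
not a reimplementation of any published kinetic simulator — that returns a
random ground-truth graph together with coupled, perturbed, noisy gene
trajectories so that inference -> network-distance scoring can be tested
end to end against a known truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import WeightedGraph

__all__ = [
    "e1_series",
    "e2_reference",
    "e2_series",
    "e3_series",
    "e4_graphs",
    "simulate_timecourse",
]

_I = np.arange(1, 101, dtype=float)


def _eps(rng: np.random.Generator, z: np.ndarray | float) -> np.ndarray:
    """Uniform noise eps(z) ~ U(-z, z), elementwise; eps(0) == 0."""
    z = np.abs(np.asarray(z, dtype=float))
    return rng.uniform(-1.0, 1.0, size=z.shape if z.shape else None) * z


def e1_series(seed: int | None = None) -> pd.DataFrame:
    """The five E1 series on i = 1..100 as a labelled matrix.

    A(i) = 0.01 i                        (linear)
    B(i) = log_100 i                     (logarithmic, B(1)=0, B(100)=1)
    C(i) = A(i) + eps(0.002 i)           (A with 20% uniform noise; seeded)
    D(i) = 0.5 cos(log10 i) + 0.65       (trigonometric-logarithmic)
    E(i) = 0 on i in [50, 70], D(i) - 0.15 elsewhere
    """
    rng = np.random.default_rng(seed)
    a = 0.01 * _I
    b = np.log(_I) / np.log(100.0)
    c = a + _eps(rng, 0.002 * _I)
    d = 0.5 * np.cos(np.log10(_I)) + 0.65
    e = np.where((_I >= 50) & (_I <= 70), 0.0, d - 0.15)
    return pd.DataFrame(
        [a, b, c, d, e], index=list("ABCDE"), columns=np.arange(1, 101)
    )


def e2_reference() -> np.ndarray:
    """The E2 reference series r(i) = (1/10) i^(3/2) e^(-2i/25) sin(3i/20)."""
    return 0.1 * _I**1.5 * np.exp(-2.0 * _I / 25.0) * np.sin(3.0 * _I / 20.0)


def e2_series(
    s: int, k: float, seed: int | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """The shifted/noisy E2 family member r_s^[k] on 100 points.

    r_s^[k](i) = eps(k) for i <= s, and r(i-s) + eps(k * r(i-s)) for
    s < i <= 100.  With k = 0 the series is deterministic (r_0^[0] = r
    exactly); for k > 0 the noise amplitude is proportional to the local
    signal, and flat uniform on (-k, k) on the pre-shift segment.
    """
    if not 0 <= s <= 99:
        raise ValueError(f"shift must be in 0..99, got {s}")
    if k < 0:
        raise ValueError(f"noise level must be >= 0, got {k}")
    if rng is None:
        rng = np.random.default_rng(seed)
    r = e2_reference()
    out = np.zeros(100)
    if k > 0 and s > 0:
        out[:s] = _eps(rng, np.full(s, float(k)))
    tail = r[: 100 - s]
    out[s:] = tail + (_eps(rng, k * tail) if k > 0 else 0.0)
    return out


def e3_series() -> pd.DataFrame:
    """The three deterministic E3 series on i = 1..100.

    G1(i) = 2 for i <= 30, then 2 + (i-30)/20 * sin((i-30) pi / 70)
    G2(i) = 3 + 2 sin(i pi / 100)
    G3(i) = 2 + log10 | 1/10 + sin(3 (G2(i) - 3)) |
    """
    g2 = 3.0 + 2.0 * np.sin(_I * np.pi / 100.0)
    g1 = np.where(
        _I <= 30, 2.0, 2.0 + (_I - 30.0) / 20.0 * np.sin((_I - 30.0) * np.pi / 70.0)
    )
    g3 = 2.0 + np.log10(np.abs(0.1 + np.sin(3.0 * (g2 - 3.0))))
    return pd.DataFrame(
        [g1, g2, g3], index=["G1", "G2", "G3"], columns=np.arange(1, 101)
    )


def e4_graphs() -> dict[str, WeightedGraph]:
    """The four E4 graphs on 4 labelled nodes, pairwise non-isospectral.

    E: empty; F: full (6 edges); A: the single edge 1-2; B: the four edges
    {1-2, 2-3, 1-3, 3-4}, containing the triangle 1-2-3.  All weights 1.
    """
    labels = ("1", "2", "3", "4")

    def from_edges(edges):
        a = np.zeros((4, 4))
        for u, v in edges:
            a[u - 1, v - 1] = a[v - 1, u - 1] = 1.0
        return WeightedGraph(a, labels)

    return {
        "E": WeightedGraph.empty(4, labels),
        "F": WeightedGraph.full(4, labels),
        "A": from_edges([(1, 2)]),
        "B": from_edges([(1, 2), (2, 3), (1, 3), (3, 4)]),
    }


def simulate_timecourse(
    n_genes: int,
    n_timepoints: int,
    edge_density: float = 0.3,
    noise_sd: float = 0.1,
    seed: int | None = None,
    process_sd: float = 0.3,
) -> tuple[WeightedGraph, pd.DataFrame]:
    """Random ground-truth graph plus coupled linear-dynamics trajectories.

    Each gene g follows Euler-discretized linear dynamics with internal
    (process) noise,

        x_g(t+1) = x_g(t) + dt * ( -lambda_g x_g(t)
                                   + c * mean_{h ~ g} x_h(t)
                                   + b_g * 1[t < T/2] )
                   + N(0, process_sd),

    with per-gene decay rates lambda_g ~ U(0.3, 1.0) and signed perturbation
    inputs |b_g| ~ U(0.5, 1.5) (up- or down-regulation) active on the first
    half of the timepoints and removed at the midpoint (relaxation back to
    baseline).  The internal noise makes each gene's trajectory individual,
    so unconnected genes decorrelate, while diffusive coupling (c = 0.7)
    along the ground-truth edges pulls neighboring trajectories together;
    connected genes therefore score higher under any of the similarity
    measures.  I.i.d. Gaussian observation noise of standard deviation
    `noise_sd` is added on top.  Fully reproducible given `seed`.

    Returns
    -------
    (truth, data)
        The ground-truth graph and the gene-by-timepoint expression matrix.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if n_timepoints < 4:
        raise ValueError("need at least 4 timepoints")
    if not 0.0 <= edge_density <= 1.0:
        raise ValueError("edge_density must be in [0, 1]")
    if noise_sd < 0 or process_sd < 0:
        raise ValueError("noise levels must be >= 0")
    rng = np.random.default_rng(seed)
    upper = rng.random((n_genes, n_genes)) < edge_density
    adj = np.triu(upper, 1).astype(float)
    adj = adj + adj.T
    labels = tuple(f"g{i + 1}" for i in range(n_genes))
    truth = WeightedGraph(adj, labels)

    lam = rng.uniform(0.3, 1.0, n_genes)
    b = rng.uniform(0.5, 1.5, n_genes) * rng.choice([-1.0, 1.0], n_genes)
    deg = np.maximum(adj.sum(axis=1), 1.0)
    dt = 0.2
    c = 0.7
    x = np.zeros((n_genes, n_timepoints))
    state = np.zeros(n_genes)
    for t in range(n_timepoints):
        drive = b if t < n_timepoints // 2 else 0.0
        state = (
            state
            + dt * (-lam * state + c * (adj @ state) / deg + drive)
            + rng.normal(0.0, process_sd, n_genes)
        )
        x[:, t] = state
    x += rng.normal(0.0, noise_sd, size=x.shape)
    data = pd.DataFrame(x, index=list(labels), columns=np.arange(n_timepoints))
    return truth, data
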