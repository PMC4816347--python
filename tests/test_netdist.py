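"""Hamming / Ipsen-Mikhailov / HIM: spectra, calibration, metric properties."""

import numpy as np
import pytest

from dtwmic import (
    WeightedGraph,
    calibrate_gamma,
    hamming_distance,
    him_distance,
    ipsen_mikhailov,
    laplacian_spectrum,
)
from dtwmic.netdist import _density_pair, _omegas


def _graph_from_edges(edges, n):
    a = np.zeros((n, n))
    for u, v in edges:
        a[u, v] = a[v, u] = 1.0
    return WeightedGraph(a)


class TestLaplacianSpectrum:
    def test_empty_graph(self):
        assert np.allclose(laplacian_spectrum(WeightedGraph.empty(5)), np.zeros(5))

    def test_complete_graph(self):
        n = 6
        spec = laplacian_spectrum(WeightedGraph.full(n))
        assert np.allclose(spec, [0.0] + [float(n)] * (n - 1))

    def test_path_graph_three_nodes(self):
        # hand eigendecomposition of the 3-node path Laplacian: {0, 1, 3}
        g = _graph_from_edges([(0, 1), (1, 2)], 3)
        assert np.allclose(laplacian_spectrum(g), [0.0, 1.0, 3.0])


class TestHamming:
    def test_identity(self, e4):
        for g in e4.values():
            assert hamming_distance(g, g) == 0.0

    def test_printed_e4_values(self, e4):
        assert hamming_distance(e4["A"], e4["E"]) == pytest.approx(1 / 6, abs=1e-15)
        assert hamming_distance(e4["B"], e4["F"]) == pytest.approx(1 / 3, abs=1e-15)

    def test_empty_vs_full_is_one(self):
        assert hamming_distance(
            WeightedGraph.empty(7), WeightedGraph.full(7)
        ) == pytest.approx(1.0)

    def test_node_mismatch(self, e4):
        with pytest.raises(ValueError, match="node count"):
            hamming_distance(e4["A"], WeightedGraph.empty(5))


class TestCalibration:
    @pytest.mark.parametrize("n", [4, 10, 20])
    def test_defining_property(self, n):
        cal = calibrate_gamma(n)
        assert cal.gamma > 0
        im = ipsen_mikhailov(WeightedGraph.empty(n), WeightedGraph.full(n), cal)
        assert abs(im - 1.0) <= 1e-6

    def test_against_grid_scan_and_bisection(self):
        # brute-force oracle: scan gamma in [1e-3, 1] for the sign change of
        # IM(empty, full) - 1, then plain bisection of the bracketing cell
        n = 4
        om_e, om_f = np.zeros(n - 1), np.full(n - 1, 2.0)

        def f(g):
            return np.sqrt(_density_pair(om_e, om_f, g)) - 1.0

        grid = np.linspace(1e-3, 1.0, 201)
        vals = np.array([f(g) for g in grid])
        (idx,) = np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
        assert idx.size == 1
        lo, hi = grid[idx[0]], grid[idx[0] + 1]
        for _ in range(30):
            mid = (lo + hi) / 2
            if np.sign(f(mid)) == np.sign(f(lo)):
                lo = mid
            else:
                hi = mid
        assert abs(calibrate_gamma(n).gamma - (lo + hi) / 2) <= 1e-6


class TestIpsenMikhailov:
    def test_zero_for_identical(self, e4):
        cal = calibrate_gamma(4)
        for g in e4.values():
            assert ipsen_mikhailov(g, g, cal) == 0.0

    def test_against_simpson_quadrature(self, e4):
        # independent oracle: fixed-step composite Simpson on a wide window
        cal = calibrate_gamma(4)
        om1 = _omegas(laplacian_spectrum(e4["A"]))
        om2 = _omegas(laplacian_spectrum(e4["E"]))
        g = cal.gamma

        def rho(om, w):
            k = 1.0 / (np.pi / 2 + np.arctan(om / g)).sum()
            return k * (g / ((w[:, None] - om[None, :]) ** 2 + g * g)).sum(axis=1)

        def simpson_im(steps):
            w = np.linspace(0.0, om1.max() + 400.0 * g, steps + 1)
            y = (rho(om1, w) - rho(om2, w)) ** 2
            h = w[1] - w[0]
            integral = h / 3 * (y[0] + y[-1] + 4 * y[1:-1:2].sum() + 2 * y[2:-1:2].sum())
            return np.sqrt(integral)

        im = ipsen_mikhailov(e4["A"], e4["E"], cal)
        assert im == pytest.approx(simpson_im(200_000), abs=1e-6)
        # quadrature stability: halving the step does not move the oracle
        assert abs(simpson_im(200_000) - simpson_im(400_000)) < 1e-6

    def test_isospectral_nonisomorphic_pair_scores_zero(self):
        # Laplacian-cospectral non-isomorphic graphs on 6 nodes (distinct
        # degree sequences), found by exhaustive enumeration; spectral
        # distances cannot separate them -- expected behavior, and exactly
        # why HIM also carries the Hamming term.
        g1 = _graph_from_edges([(0, 2), (0, 3), (0, 4), (0, 5), (1, 4), (1, 5), (2, 3)], 6)
        g2 = _graph_from_edges([(0, 2), (0, 4), (0, 5), (1, 2), (1, 4), (1, 5), (2, 3)], 6)
        assert np.allclose(laplacian_spectrum(g1), laplacian_spectrum(g2), atol=1e-9)
        assert not np.array_equal(g1.adjacency, g2.adjacency)
        assert ipsen_mikhailov(g1, g2) == 0.0
        res = him_distance(g1, g2)
        assert res.hamming > 0.0 and res.him > 0.0

    def test_wrong_calibration_rejected(self, e4):
        with pytest.raises(ValueError, match="calibration"):
            ipsen_mikhailov(e4["A"], e4["E"], calibrate_gamma(5))


class TestHim:
    def test_zero_for_identical_and_one_for_extremes(self, e4):
        assert him_distance(e4["A"], e4["A"]).him == 0.0
        res = him_distance(e4["E"], e4["F"])
        assert res.him == pytest.approx(1.0, abs=1e-6)

    def test_combination_and_plane_point(self, e4):
        rng = np.random.default_rng(9)
        for _ in range(5):
            a = rng.random((5, 5))
            a, b = (a + a.T) / 2, rng.random((5, 5))
            b = (b + b.T) / 2
            np.fill_diagonal(a, 0.0)
            np.fill_diagonal(b, 0.0)
            res = him_distance(WeightedGraph(a), WeightedGraph(b))
            assert 2.0 * res.him**2 == pytest.approx(
                res.hamming**2 + res.im**2, abs=1e-12
            )
            assert res.plane_point == (res.hamming, res.im)
            assert 0.0 <= res.him <= 1.0

    def test_composition_on_e4(self, e4):
        res = him_distance(e4["A"], e4["E"])
        assert res.hamming == pytest.approx(1 / 6)
        assert res.him == pytest.approx(
            np.sqrt(res.hamming**2 + res.im**2) / np.sqrt(2.0), abs=1e-15
        )
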