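"""Soft/hard thresholding and replicate concatenation."""

import numpy as np
import pandas as pd
import pytest

from dtwmic import (
    SoftThresholdConfig,
    WeightedGraph,
    concat_replicates,
    hard_threshold,
    similarity_matrix,
    soft_threshold_adjacency,
)


def _random_similarity(n=6, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(n, 40))
    return similarity_matrix(data, "dtw")


class TestSoftThreshold:
    def test_beta_one_is_identity_off_diagonal(self):
        sm = _random_similarity()
        net = soft_threshold_adjacency(sm, SoftThresholdConfig(beta=1.0))
        off = ~np.eye(sm.matrix.shape[0], dtype=bool)
        assert np.allclose(net.adjacency[off], sm.matrix[off])
        assert np.all(np.diag(net.adjacency) == 0.0)

    def test_power_values(self):
        sm = _random_similarity()
        m = sm.matrix.copy()
        m[0, 1] = m[1, 0] = 0.5
        m[0, 2] = m[2, 0] = 1.0
        sm.matrix = m
        net = soft_threshold_adjacency(sm)  # default beta = 6
        assert net.adjacency[0, 1] == pytest.approx(0.5**6)
        assert net.adjacency[0, 1] == pytest.approx(0.015625)
        assert net.adjacency[0, 2] == 1.0  # 1 is a fixed point for any beta

    def test_preserves_ranking(self):
        sm = _random_similarity(seed=3)
        net = soft_threshold_adjacency(sm, SoftThresholdConfig(beta=6.0))
        iu = np.triu_indices(sm.matrix.shape[0], 1)
        order_before = np.argsort(sm.matrix[iu])
        order_after = np.argsort(net.adjacency[iu])
        assert np.array_equal(order_before, order_after)

    def test_round_trip_via_beta_root(self):
        sm = _random_similarity(seed=5)
        beta = 6.0
        net = soft_threshold_adjacency(sm, SoftThresholdConfig(beta=beta))
        off = ~np.eye(sm.matrix.shape[0], dtype=bool)
        back = np.power(net.adjacency[off], 1.0 / beta)
        assert np.allclose(back, sm.matrix[off], atol=1e-12)

    def test_invalid_beta(self):
        with pytest.raises(ValueError, match="positive"):
            SoftThresholdConfig(beta=0.0)


class TestHardThreshold:
    def test_strict_inequality(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.2
        a[0, 2] = a[2, 0] = 0.5
        a[1, 2] = a[2, 1] = 0.9
        g = WeightedGraph(a)
        assert hard_threshold(g, 0.5).edge_count() == 1  # only 0.9 > 0.5
        assert hard_threshold(g, 0.0).edge_count() == 3
        assert hard_threshold(g, 1.0).edge_count() == 0

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        a = rng.random((5, 5))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        g = WeightedGraph(a)
        once = hard_threshold(g, 0.4)
        twice = hard_threshold(once, 0.4)
        assert np.array_equal(once.adjacency, twice.adjacency)

    def test_invalid_tau(self):
        g = WeightedGraph(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="tau"):
            hard_threshold(g, 1.5)


class TestWeightedGraph:
    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            WeightedGraph(np.array([[0.0, 1.0], [0.5, 0.0]]))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            WeightedGraph(np.full((2, 2), 2.0))
        with pytest.raises(ValueError, match="label count"):
            WeightedGraph(np.zeros((2, 2)), labels=("a", "b", "c"))

    def test_diagonal_forced_to_zero(self):
        a = np.eye(3) * 0.5
        assert np.all(WeightedGraph(a).adjacency == 0.0)


class TestConcatReplicates:
    @staticmethod
    def _replicate(r, genes=("g1", "g2"), width=10, seed=0):
        rng = np.random.default_rng(seed + r)
        return pd.DataFrame(
            rng.normal(size=(len(genes), width)),
            index=list(genes),
            columns=np.arange(width),
        )

    @pytest.mark.parametrize("n_reps, width, expected", [(34, 10, 340), (10, 10, 100)])
    def test_lengths(self, n_reps, width, expected):
        reps = [self._replicate(r, width=width) for r in range(n_reps)]
        joined = concat_replicates(reps)
        assert joined.shape == (2, expected)

    def test_single_replicate_unchanged(self):
        rep = self._replicate(0)
        joined = concat_replicates([rep])
        assert np.array_equal(joined.to_numpy(), rep.to_numpy())

    def test_order_preserved(self):
        reps = [self._replicate(r, width=3) for r in range(2)]
        joined = concat_replicates(reps)
        assert np.array_equal(joined.to_numpy()[:, :3], reps[0].to_numpy())
        assert np.array_equal(joined.to_numpy()[:, 3:], reps[1].to_numpy())

    def test_mismatches_rejected(self):
        with pytest.raises(ValueError, match="gene set"):
            concat_replicates(
                [self._replicate(0), self._replicate(1, genes=("g1", "g3"))]
            )
        with pytest.raises(ValueError, match="timepoints"):
            concat_replicates([self._replicate(0), self._replicate(1, width=7)])
        with pytest.raises(ValueError, match="no replicates"):
            concat_replicates([])
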