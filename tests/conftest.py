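"""Shared fixtures: example data and (cached) null-model runs."""

import numpy as np
import pytest

from dtwmic import (
    NullModelConfig,
    e1_series,
    e2_reference,
    e2_series,
    e3_series,
    e4_graphs,
    null_dtw_threshold,
    range_bounds,
)


@pytest.fixture(scope="session")
def e1():
    return e1_series(seed=0)


@pytest.fixture(scope="session")
def e3():
    return e3_series()


@pytest.fixture(scope="session")
def e4():
    return e4_graphs()


@pytest.fixture(scope="session")
def e2_ref():
    return e2_reference()


@pytest.fixture(scope="session")
def null_results():
    """Null-model thresholds for the three noise levels, computed once.

    Bounds follow the stated construction: min/max over the realized family
    r_s^[k], integer shifts s = 0..40, with seeded noise for k > 0.
    """
    out = {}
    for k in (0, 1, 2):
        rng = np.random.default_rng(100 + k)
        family = [e2_series(s, k, rng=rng) for s in range(41)]
        m, m_up = range_bounds(family)
        out[k] = null_dtw_threshold(
            NullModelConfig(m=m, M_up=m_up, n_points=100, N=1000, seed=1)
        )
    return out
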