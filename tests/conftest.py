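import numpy as np
import pytest

from mvcpm import (
    BlockOperator,
    SBMConfig,
    connection_probability_matrix,
    generate_multiview_sbm,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_sbm():
    """3-view disconnected-cluster SBM on 45 nodes (fast, exactly recoverable)."""
    cfg = SBMConfig(
        n_views=3,
        cluster_sizes_per_view=((15, 15, 15),) * 3,
        prob_matrix=connection_probability_matrix("P1", 45),
        prob_scale_n=45,
        seed=7,
    )
    return generate_multiview_sbm(cfg)


@pytest.fixture
def random_weighted_graph(rng):
    """Dense random symmetric weighted adjacency on 30 nodes."""
    n = 30
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


def make_operator(adjacencies, beta_couple=1.0):
    return BlockOperator.from_adjacencies(adjacencies, beta_couple=beta_couple)
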