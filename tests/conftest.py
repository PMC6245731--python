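import numpy as np
import pytest

from cruspark.synthetic import make_cru_layout, simulate_blinks


@pytest.fixture(scope="session")
def compact_layout():
    """Single compact 3x3 cluster of 9 RyRs."""
    return make_cru_layout(n_ryr=9, n_subclusters=1, seed=1)


@pytest.fixture(scope="session")
def three_cluster_layout():
    """27 RyRs split into three 9-RyR blobs, 120 nm edge-to-edge gaps."""
    return make_cru_layout(n_ryr=27, n_subclusters=3, gap_nm=120, seed=3)


@pytest.fixture(scope="session")
def three_cluster_blinks(three_cluster_layout):
    return simulate_blinks(three_cluster_layout, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
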