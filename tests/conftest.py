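import numpy as np
import pytest

from slnet import CohortSpec
from slnet.connectivity import ConnectivityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_spec():
    """Small, fast cohort for pipeline-level tests."""
    return CohortSpec(
        n_per_group=3, n_channels=5, fs=256.0, epoch_seconds=2.0,
        n_epochs=2, base_coupling=0.3, effect_size=0.0, noise_sd=0.5, seed=42,
    )


def random_connectivity(rng, n, low=0.05, high=0.95):
    """Random symmetric positive-weight SL-like matrix with zero diagonal."""
    w = rng.uniform(low, high, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, [f"ch{i}" for i in range(n)])


@pytest.fixture
def three_node():
    """The hand-checkable 3-node graph: w12=0.5, w13=0.2, w23=0.1."""
    w = np.array([
        [0.0, 0.5, 0.2],
        [0.5, 0.0, 0.1],
        [0.2, 0.1, 0.0],
    ])
    return ConnectivityMatrix(w, ["a", "b", "c"])
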