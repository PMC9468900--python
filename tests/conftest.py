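import numpy as np
import pytest

from brainsgm import (
    ConnectomeGraph,
    SGMParameters,
    SyntheticSpec,
    default_grid,
    generate_connectome,
)


@pytest.fixture(scope="session")
def small_graph() -> ConnectomeGraph:
    """Packaged small fixture: synthetic N=20 distance-dependent connectome."""
    return generate_connectome(SyntheticSpec(n_regions=20, geometry_seed=42, sparsity=0.8))


@pytest.fixture(scope="session")
def zero_delay_graph(small_graph) -> ConnectomeGraph:
    return ConnectomeGraph(
        small_graph.region_labels, small_graph.C, np.zeros_like(small_graph.D)
    )


@pytest.fixture()
def two_node_graph() -> ConnectomeGraph:
    return ConnectomeGraph(
        ["A", "B"],
        np.array([[0.0, 1.0], [1.0, 0.0]]),
        np.array([[0.0, 1000.0], [1000.0, 0.0]]),
    )


@pytest.fixture(scope="session")
def grid() -> np.ndarray:
    return default_grid()


@pytest.fixture()
def mid_params() -> SGMParameters:
    return SGMParameters()


def random_graph(n: int, seed: int, zero_delay: bool = False) -> ConnectomeGraph:
    """Dense random connectome helper used by oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.1, 1.0, size=(n, n))
    C = (W + W.T) / 2
    np.fill_diagonal(C, 0.0)
    if zero_delay:
        D = np.zeros((n, n))
    else:
        P = rng.uniform(10.0, 150.0, size=(n, n))
        D = (P + P.T) / 2
        np.fill_diagonal(D, 0.0)
    return ConnectomeGraph([f"R{i+1:03d}" for i in range(n)], C, D)
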