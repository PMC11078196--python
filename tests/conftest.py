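import numpy as np
import pytest

from hyperdyn import Hypergraph, generate_er_hypergraph


@pytest.fixture
def small_hypergraph() -> Hypergraph:
    """5-node fixture with overlapping edges of sizes 2, 3 and 4."""
    return Hypergraph(
        num_nodes=5,
        edges_by_size={
            2: [(0, 1), (1, 2), (3, 4)],
            3: [(0, 1, 2), (2, 3, 4)],
            4: [(0, 1, 2, 3)],
        },
    )


@pytest.fixture
def er_hypergraph() -> Hypergraph:
    return generate_er_hypergraph(20, {2: 0.1, 3: 0.01, 4: 0.001}, rng_seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
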