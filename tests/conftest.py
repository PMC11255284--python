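import numpy as np
import pytest

from nldual import MultilayerNetwork


@pytest.fixture
def toy_net() -> MultilayerNetwork:
    """Three nodes, two layers, one edge of each class.

    Edges: intralayer (0,I)-(1,I), replica (0,I)-(0,II), interlayer
    (1,I)-(2,II).  Nodewise multidegrees are [3, 2, 1] (the replica edge
    counts twice for node 0) and layerwise [4, 2] (the intralayer edge counts
    twice for layer I).
    """
    return MultilayerNetwork(
        3, 2, [((0, 0), (1, 0)), ((0, 0), (0, 1)), ((1, 0), (2, 1))]
    )


@pytest.fixture
def weighted_toy_net() -> MultilayerNetwork:
    """Same topology as ``toy_net`` but with non-unit weights."""
    return MultilayerNetwork(
        3,
        2,
        [
            ((0, 0), (1, 0), 2.5),
            ((0, 0), (0, 1), 0.5),
            ((1, 0), (2, 1), 1.0),
        ],
    )


def random_network(N, M, n_edges, nature, seed):
    """Small random network helper used by property-style tests."""
    from nldual import admissible_slots
    from nldual.generators import _random_network

    S = admissible_slots(N, M, nature)
    n_edges = min(n_edges, S)
    return _random_network(N, M, 0.0, np.random.default_rng(seed), nature, n_edges)
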