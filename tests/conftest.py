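import itertools

import numpy as np
import pytest

from egonet.network_model import EgoNetwork, validate_network
from egonet.synthetic_data import SimConfig, generate_population


def ego_adjacency(peer_edges):
    """5x5 adjacency with ego tied to all four peers plus given peer-peer edges."""
    a = np.zeros((5, 5), dtype=int)
    a[0, 1:] = a[1:, 0] = 1
    for i, j in peer_edges:
        a[i, j] = a[j, i] = 1
    return a


PEER_PAIRS = [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)]


def all_peer_configurations():
    """All 64 peer-peer tie patterns of a four-peer ego network."""
    for bits in itertools.product((0, 1), repeat=6):
        yield ego_adjacency([e for b, e in zip(bits, PEER_PAIRS) if b])


@pytest.fixture
def star():
    return ego_adjacency([])


@pytest.fixture
def complete():
    return ego_adjacency(PEER_PAIRS)


@pytest.fixture
def bridge_network():
    """Peer 1 tied to peers 2 and 3; peer 4 isolated among peers."""
    return ego_adjacency([(1, 2), (1, 3)])


@pytest.fixture(scope="session")
def small_population():
    """A 300-ego default-condition population shared across tests."""
    return generate_population(SimConfig(n_egos=300), seed=20250925)


@pytest.fixture(scope="session")
def small_triples(small_population):
    return small_population.triples
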