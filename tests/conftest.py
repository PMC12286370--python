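import numpy as np
import pytest

from swipenet import DirectedBipartiteNetwork, from_edge_list

NET_A_EDGES = [("m1", "w1"), ("m2", "w1"), ("w1", "m1")]
NET_A_NODES = [("w1", "F"), ("m1", "M"), ("m2", "M")]


@pytest.fixture
def net_a():
    """One woman, two men; m1->w1, m2->w1, w1->m1 (one match)."""
    return from_edge_list(NET_A_EDGES, NET_A_NODES)


@pytest.fixture
def net_b():
    """Two women, two men; m1->w1, m2->w1, w1->m1, w2->m1."""
    edges = [("m1", "w1"), ("m2", "w1"), ("w1", "m1"), ("w2", "m1")]
    nodes = [("w1", "F"), ("w2", "F"), ("m1", "M"), ("m2", "M")]
    return from_edge_list(edges, nodes)


def random_net(rng, n_women=None, n_men=None, p=0.4):
    """A random directed bipartite network (each possible tie i.i.d.)."""
    n_w = n_women or int(rng.integers(1, 8))
    n_m = n_men or int(rng.integers(1, 8))
    return DirectedBipartiteNetwork(
        women=[f"w{i}" for i in range(n_w)],
        men=[f"m{i}" for i in range(n_m)],
        M_F=(rng.random((n_w, n_m)) < p).astype(np.int8),
        M_M=(rng.random((n_m, n_w)) < p).astype(np.int8),
    )


@pytest.fixture
def random_net_factory():
    return random_net
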