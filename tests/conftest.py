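import networkx as nx
import pytest

from srnanet.network import Network


def random_network(n, p, seed, directed=False):
    g = nx.gnp_random_graph(n, p, seed=seed, directed=directed)
    g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in range(n)})
    return Network(g)


@pytest.fixture
def path_abc():
    """Undirected path a - b - c."""
    return Network.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def k3():
    return Network.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def star5():
    """Star K1,4 centered on 'hub'."""
    return Network.from_edges([("hub", f"leaf{i}") for i in range(4)])
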