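import networkx as nx
import pytest


def k5_pair_with_bridge() -> nx.Graph:
    """Two K5 cliques joined by a single bridge edge a4-b0.

    Bridge endpoints have degree 5, everyone else degree 4.  Inside a clique
    every adjacent pair shares 3 common neighbours, so non-bridge weights are
    3/4 and weights involving a bridge endpoint are 3/5 from its side; the
    bridge edge itself has weight 0 in both directions.
    """
    g = nx.Graph()
    for prefix in ("a", "b"):
        members = [f"{prefix}{i}" for i in range(5)]
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(members[i], members[j])
    g.add_edge("a4", "b0")
    return g


@pytest.fixture
def two_k5() -> nx.Graph:
    return k5_pair_with_bridge()


@pytest.fixture
def triangle() -> nx.Graph:
    return nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3() -> nx.Graph:
    return nx.Graph([("a", "b"), ("b", "c")])


@pytest.fixture
def k4() -> nx.Graph:
    return nx.complete_graph(["a", "b", "c", "d"])


@pytest.fixture
def c4() -> nx.Graph:
    return nx.cycle_graph(["a", "b", "c", "d"])


@pytest.fixture
def star4() -> nx.Graph:
    """K_{1,3}: centre c with leaves x, y, z."""
    return nx.Graph([("c", "x"), ("c", "y"), ("c", "z")])
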