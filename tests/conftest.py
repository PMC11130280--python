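import networkx as nx
import pytest

from hcicnet import fixtures


@pytest.fixture(scope="session")
def fig1():
    return fixtures.fig1_network()


@pytest.fixture(scope="session")
def fig5():
    return fixtures.fig5_network()


@pytest.fixture(scope="session")
def fig4():
    return fixtures.fig4_network()


@pytest.fixture(scope="session")
def expectations():
    return fixtures.expectations()


@pytest.fixture(scope="session")
def er50():
    """Seeded sparse random graph used by several property tests."""
    return fixtures.synthetic_graph("erdos-renyi", seed=11, n=50, p=0.1)


@pytest.fixture(
    params=[
        ("erdos-renyi", dict(n=10, p=0.3)),
        ("erdos-renyi", dict(n=12, p=0.5)),
        ("barabasi-albert", dict(n=12, m=2)),
        ("watts-strogatz", dict(n=12, k=4, beta=0.2)),
    ],
    ids=["er-sparse", "er-dense", "ba", "ws"],
)
def small_graph(request):
    model, params = request.param
    return fixtures.synthetic_graph(model, seed=3, **params)


def path_graph(n: int) -> nx.Graph:
    return nx.relabel_nodes(nx.path_graph(n), str)


def star_graph(k: int) -> nx.Graph:
    """Star with center '0' and k leaves."""
    return nx.relabel_nodes(nx.star_graph(k), str)


def complete_graph(n: int) -> nx.Graph:
    return nx.relabel_nodes(nx.complete_graph(n), str)


def cycle_graph(n: int) -> nx.Graph:
    return nx.relabel_nodes(nx.cycle_graph(n), str)
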