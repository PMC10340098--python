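import networkx as nx
import pytest
from hypothesis import settings, HealthCheck

from netdr.network import WeightedNetwork, GeneModule, build_module

settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_network(edges):
    """(a, b, w) triples -> WeightedNetwork, bypassing file I/O."""
    return WeightedNetwork.from_edges(edges)


def make_module(edges, seeds, kind="DAPN"):
    net = make_network(edges)
    return build_module(net, seeds, kind=kind)


@pytest.fixture
def path_net():
    """A - B - C path, unit weights."""
    return make_network([("A", "B", 1.0), ("B", "C", 1.0)])


@pytest.fixture
def triangle_module():
    """Complete module on a unit-weight triangle."""
    return make_module(
        [("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 1.0)], {"A", "B", "C"}
    )


@pytest.fixture
def star_module():
    """K1,3 star, center H."""
    return make_module(
        [("H", "L1", 1.0), ("H", "L2", 1.0), ("H", "L3", 1.0)], {"H"}
    )


def random_weighted_module(rng, n_nodes, p=0.35):
    """Random connected-ish weighted graph as a module over all its nodes."""
    while True:
        g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(0, 2**31 - 1)))
        if g.number_of_edges() == 0:
            continue
        g.remove_nodes_from(list(nx.isolates(g)))
        if g.number_of_nodes() >= 2:
            break
    edges = [
        (f"g{u:02d}", f"g{v:02d}", float(rng.uniform(0.1, 1.0))) for u, v in g.edges()
    ]
    nodes = {a for a, _, _ in edges} | {b for _, b, _ in edges}
    return make_module(edges, nodes)
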