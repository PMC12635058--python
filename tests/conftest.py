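import pytest

from danglecent import builtin_graph
from danglecent.synthetic import GeneratorSpec, generate


@pytest.fixture
def five_node():
    """5-node / 5-edge worked-example graph, labels 0..4."""
    return builtin_graph("five_node")


@pytest.fixture
def six_node():
    """6-node / 10-edge worked-example graph, labels 1..6."""
    return builtin_graph("six_node")


def random_graphs(count, n_max=12, p=0.3, seed0=0):
    """Deterministic stream of seeded Erdos-Renyi graphs for oracle checks."""
    for k in range(count):
        n = 3 + (k % (n_max - 2))
        yield generate(GeneratorSpec("erdos_renyi", n=n, p=p, seed=seed0 + k))


def power_method_domain(graph):
    """True when plain power iteration is guaranteed to converge: the graph
    is connected and non-bipartite, so the Perron eigenvalue is simple and
    strictly dominant in magnitude."""
    import networkx as nx

    g = graph.to_networkx()
    return graph.n_edges > 0 and nx.is_connected(g) and not nx.is_bipartite(g)
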