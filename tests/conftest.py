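import networkx as nx
import pytest


def _graph(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


@pytest.fixture
def path3():
    """A - B - C."""
    return _graph([("A", "B"), ("B", "C")])


@pytest.fixture
def star3():
    """Center C0 with leaves L1..L3."""
    return _graph([("C0", "L1"), ("C0", "L2"), ("C0", "L3")])


@pytest.fixture
def k3():
    return nx.complete_graph(["A", "B", "C"])


@pytest.fixture
def k4():
    return nx.complete_graph(["A", "B", "C", "D"])


@pytest.fixture
def c4():
    """4-cycle A - B - C - D - A."""
    return _graph([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])


@pytest.fixture
def shared_edge_triangles():
    """Two triangles sharing edge B-C: nodes A,B,C,D."""
    return _graph([("A", "B"), ("A", "C"), ("B", "C"), ("B", "D"), ("C", "D")])


@pytest.fixture
def bowtie():
    """Two triangles sharing the single vertex V."""
    return _graph(
        [("A", "B"), ("A", "V"), ("B", "V"), ("C", "D"), ("C", "V"), ("D", "V")]
    )


def random_graphs(n_graphs, max_n, seed, min_n=2):
    """Random Erdos-Renyi graphs with string node labels."""
    import numpy as np

    rng = np.random.default_rng(seed)
    graphs = []
    while len(graphs) < n_graphs:
        n = int(rng.integers(min_n, max_n + 1))
        p = float(rng.uniform(0.15, 0.8))
        g = nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        graphs.append(nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes}))
    return graphs
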