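import itertools

import pytest

from pullnet import InteractionNetwork


def build_network(edges, extra_nodes=()):
    net = InteractionNetwork()
    for a, b in edges:
        net.add_edge(a, b)
    net.graph.add_nodes_from(extra_nodes)
    return net


@pytest.fixture
def two_triangles():
    """Two disjoint triangles {A,B,C} and {D,E,F}; m = 6."""
    return build_network(
        [("A", "B"), ("B", "C"), ("A", "C"), ("D", "E"), ("E", "F"), ("D", "F")]
    )


@pytest.fixture
def bridged_triangles(two_triangles):
    """Two triangles joined by the bridge C-D; m = 7."""
    net = two_triangles.copy()
    net.add_edge("C", "D")
    return net


@pytest.fixture
def complete_k10():
    return build_network(itertools.combinations("ABCDEFGHIJ", 2))


@pytest.fixture
def path_graph():
    """Path A-B-C-D."""
    return build_network([("A", "B"), ("B", "C"), ("C", "D")])
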