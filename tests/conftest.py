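import pytest

from ppinet.graph_core import Network


def build_network(edges, nodes=()):
    """Network from (a, b) or (a, b, confidence) tuples plus extra nodes."""
    net = Network()
    for node in nodes:
        net.add_node(node)
    for edge in edges:
        if len(edge) == 2:
            net.add_edge(edge[0], edge[1], 1.0)
        else:
            net.add_edge(*edge)
    return net


@pytest.fixture
def triangle_plus_isolated():
    return build_network([("A", "B"), ("B", "C"), ("A", "C")], nodes=["D"])


@pytest.fixture
def path_abc():
    return build_network([("A", "B"), ("B", "C")])


@pytest.fixture
def clique():
    def make(size, prefix="N"):
        names = [f"{prefix}{i}" for i in range(size)]
        return build_network(
            [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
        )

    return make
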