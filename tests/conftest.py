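from __future__ import annotations

import networkx as nx
import pytest

from comorbnet import PPINetwork


def make_net(edges, nodes=()) -> PPINetwork:
    """Wrap an edge list (plus optional isolated nodes) as a PPINetwork."""
    g = nx.Graph()
    g.add_edges_from((a, b, {"combined_score": 950}) for a, b in edges)
    g.add_nodes_from(nodes)
    return PPINetwork(graph=g, threshold=0.0)


@pytest.fixture
def worked_example_net() -> PPINetwork:
    """The fixed 5-node screening example: a triangle A-B-C with a
    pendant path A-D-E."""
    return make_net([("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("D", "E")])


@pytest.fixture
def path3_net() -> PPINetwork:
    return make_net([("A", "B"), ("B", "C")])
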