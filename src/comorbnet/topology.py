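"""Per-node topological parameters of the PPI network.

Four parameters are computed for every node, following the Cytoscape
NetworkAnalyzer conventions so all values are comparable on [0, 1] scales
(degree excepted):

degree
    number of distinct neighbors on the simple graph.
betweenness centrality
    fraction of shortest paths between other node pairs passing through
    the node, normalized by ``(n-1)(n-2)/2`` where ``n`` is the
    whole-network node count (a path midpoint scores 1.0); exact
    shortest-path counting, no sampling.
closeness centrality
    ``(c-1) / sum of geodesic distances`` to the ``c`` members of the
    node's connected component — component-local, so disconnected graphs
    still yield values in [0, 1]; a node alone in its component scores 0.
clustering coefficient
    realized fraction of the ``k(k-1)/2`` possible edges among a node's
    ``k`` neighbors; defined as 0 for degree < 2 so every node carries
    four comparable values into the median-screening step.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import networkx as nx

from .network import PPINetwork

__all__ = [
    "NodeTopology",
    "degree",
    "betweenness",
    "closeness",
    "clustering",
    "topology_table",
    "write_topology_table",
]

GraphLike = Union[PPINetwork, nx.Graph]

#: Parameter names in the order they are screened and reported.
PARAMETERS = ("degree", "betweenness", "closeness", "clustering")


def _as_graph(net: GraphLike) -> nx.Graph:
    return net.graph if isinstance(net, PPINetwork) else net


def degree(net: GraphLike) -> dict[str, int]:
    """Neighbor counts on the simple graph."""
    g = _as_graph(net)
    return {n: int(d) for n, d in g.degree()}


def betweenness(net: GraphLike) -> dict[str, float]:
    """Exact normalized betweenness centrality (Brandes accumulation)."""
    g = _as_graph(net)
    if g.number_of_nodes() < 3:
        return {n: 0.0 for n in g.nodes}
    return {
        n: float(v)
        for n, v in nx.betweenness_centrality(g, normalized=True).items()
    }


def closeness(net: GraphLike) -> dict[str, float]:
    """Component-local closeness centrality (no Wasserman–Faust scaling)."""
    g = _as_graph(net)
    return {
        n: float(v)
        for n, v in nx.closeness_centrality(g, wf_improved=False).items()
    }


def clustering(net: GraphLike) -> dict[str, float]:
    """Local clustering coefficient; 0 for nodes of degree < 2."""
    g = _as_graph(net)
    return {n: float(v) for n, v in nx.clustering(g).items()}


@dataclass(frozen=True)
class NodeTopology:
    """The four screened parameters of one node."""

    node: str
    degree: int
    betweenness: float
    closeness: float
    clustering: float

    def value(self, parameter: str) -> float:
        if parameter not in PARAMETERS:
            raise KeyError(f"unknown topological parameter {parameter!r}")
        return float(getattr(self, parameter))


def topology_table(net: GraphLike) -> list[NodeTopology]:
    """All four parameters per node, ordered by descending degree then symbol."""
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot tabulate topology of an empty network")
    deg = degree(g)
    bet = betweenness(g)
    clo = closeness(g)
    clu = clustering(g)
    rows = [
        NodeTopology(
            node=n,
            degree=deg[n],
            betweenness=bet[n],
            closeness=clo[n],
            clustering=clu[n],
        )
        for n in g.nodes
    ]
    rows.sort(key=lambda r: (-r.degree, r.node))
    return rows


def write_topology_table(rows: list[NodeTopology], path: str | Path) -> None:
    """Write the per-node parameter table as TSV."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["gene_symbol", "betweenness", "closeness", "degree", "clustering"]
        )
        for r in rows:
            w.writerow(
                [
                    r.node,
                    f"{r.betweenness:.9f}",
                    f"{r.closeness:.9f}",
                    r.degree,
                    f"{r.clustering:.9f}",
                ]
            )
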