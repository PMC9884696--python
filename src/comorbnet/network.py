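"""Confidence-thresholded protein–protein interaction networks.

Interactions arrive as a STRING-dialect edge list (protein A, protein B,
combined score on the 0–1000 scale; 900 corresponds to confidence 0.9).
The network is the simple undirected graph induced on the risk-gene set by
edges at or above the confidence threshold; reciprocal/duplicate rows
collapse to one edge keeping the maximum score, self-interactions are
rejected, and risk genes left without any retained edge are dropped (and
reported) so the node set mirrors the connected portion of the risk set.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx

from .genesets import RiskGeneSet, normalize_symbol

log = logging.getLogger(__name__)

__all__ = [
    "Interaction",
    "PPINetwork",
    "EmptyNetworkError",
    "read_edge_list",
    "read_id_mapping",
    "build_network",
    "write_graphml",
    "write_sif",
    "write_edge_table",
]

ScoreBoundary = Literal["ge", "gt"]


class EdgeListParseError(ValueError):
    """An edge-list file violated the expected layout."""


class EmptyNetworkError(ValueError):
    """No edge survived thresholding; the confidence cut may be too strict."""


@dataclass(frozen=True)
class Interaction:
    """One undirected interaction candidate with a STRING combined score."""

    gene_a: str
    gene_b: str
    combined_score: int

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-interaction {self.gene_a!r}")
        if not 0 <= self.combined_score <= 1000:
            raise ValueError(
                f"combined_score {self.combined_score} outside [0, 1000]"
            )

    @property
    def pair(self) -> tuple[str, str]:
        a, b = sorted((self.gene_a, self.gene_b))
        return a, b


@dataclass
class PPINetwork:
    """Simple undirected graph over gene symbols with per-edge scores."""

    graph: nx.Graph
    threshold: float
    dropped_genes: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def subnetwork(self, nodes: Iterable[str]) -> "PPINetwork":
        """Induced subgraph on *nodes* (isolates within it are kept)."""
        sub = self.graph.subgraph(nodes).copy()
        return PPINetwork(graph=sub, threshold=self.threshold)


def _split_fields(line: str) -> list[str]:
    if "\t" in line:
        return [f.strip() for f in line.rstrip("\n").split("\t")]
    return line.split()


def read_edge_list(
    path: str | Path,
    id_mapping: Mapping[str, str] | None = None,
) -> list[Interaction]:
    """Parse a STRING-dialect edge list (TSV or whitespace separated).

    Reciprocal and duplicate rows collapse to one candidate per unordered
    pair keeping the maximum score.  Self-loops are rejected and logged.
    An optional *id_mapping* (protein id -> gene symbol) is applied before
    normalization.  A header row is detected by a non-numeric third field.
    """
    path = Path(path)
    best: dict[tuple[str, str], int] = {}
    n_self = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_fields(line)
            if len(fields) < 3:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected 3 columns, got "
                    f"{len(fields)}"
                )
            raw_a, raw_b, raw_score = fields[0], fields[1], fields[2]
            try:
                score = int(float(raw_score))
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise EdgeListParseError(
                    f"{path}: line {lineno}: non-numeric score {raw_score!r}"
                ) from None
            if not 0 <= score <= 1000:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: score {score} outside [0, 1000]"
                )
            if id_mapping is not None:
                raw_a = id_mapping.get(raw_a, raw_a)
                raw_b = id_mapping.get(raw_b, raw_b)
            a, b = normalize_symbol(raw_a), normalize_symbol(raw_b)
            if not a or not b:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: blank protein identifier"
                )
            if a == b:
                n_self += 1
                log.info("%s: line %d: self-loop %s rejected", path, lineno, a)
                continue
            key = (a, b) if a < b else (b, a)
            if score > best.get(key, -1):
                best[key] = score
    if n_self:
        log.info("%s: rejected %d self-loop row(s)", path, n_self)
    return [
        Interaction(a, b, s) for (a, b), s in sorted(best.items())
    ]


def read_id_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping protein ids to gene symbols."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {
            "protein_id",
            "gene_symbol",
        }.issubset(reader.fieldnames):
            raise EdgeListParseError(
                f"{path}: expected columns protein_id, gene_symbol"
            )
        for row in reader:
            mapping[row["protein_id"].strip()] = row["gene_symbol"].strip()
    return mapping


def build_network(
    interactions: Sequence[Interaction],
    risk_genes: RiskGeneSet | Iterable[str] | None,
    threshold: float = 0.9,
    *,
    score_boundary: ScoreBoundary = "ge",
    keep_isolates: bool = False,
) -> PPINetwork:
    """Build the thresholded PPI network induced on the risk genes.

    *threshold* is on the [0, 1] confidence scale; an edge is retained when
    its combined score meets ``threshold * 1000`` under *score_boundary*
    (``"ge"``, the STRING highest-confidence convention, or strict
    ``"gt"``).  Risk genes without a single retained edge are dropped and
    reported unless *keep_isolates* is set.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if score_boundary not in ("ge", "gt"):
        raise ValueError("score_boundary must be 'ge' or 'gt'")

    if risk_genes is None:
        members: set[str] | None = None
    elif isinstance(risk_genes, RiskGeneSet):
        members = set(risk_genes.genes)
    else:
        members = set(risk_genes)

    cutoff = threshold * 1000.0
    best: dict[tuple[str, str], int] = {}
    for it in interactions:
        key = it.pair
        if it.combined_score > best.get(key, -1):
            best[key] = it.combined_score

    graph = nx.Graph()
    for (a, b), score in sorted(best.items()):
        if members is not None and (a not in members or b not in members):
            continue
        if score >= cutoff if score_boundary == "ge" else score > cutoff:
            graph.add_edge(a, b, combined_score=score)

    connected = set(graph.nodes)
    dropped = (members - connected) if members is not None else set()
    if keep_isolates and members is not None:
        graph.add_nodes_from(sorted(members - connected))
        dropped = set()

    if graph.number_of_edges() == 0 and not keep_isolates:
        raise EmptyNetworkError(
            f"no interaction survived the confidence threshold {threshold}; "
            "review the threshold or the identifier space"
        )
    log.info(
        "network: %d nodes, %d edges at confidence %s %.3g; %d risk gene(s) "
        "dropped as isolated",
        graph.number_of_nodes(),
        graph.number_of_edges(),
        ">=" if score_boundary == "ge" else ">",
        threshold,
        len(dropped),
    )
    return PPINetwork(graph=graph, threshold=threshold, dropped_genes=dropped)


def write_graphml(net: PPINetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))


def write_sif(net: PPINetwork, path: str | Path) -> None:
    """Write the network in SIF (node, interaction type, node) format."""
    with Path(path).open("w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\tpp\t{b}\n")
        for node in sorted(nx.isolates(net.graph)):
            fh.write(f"{node}\n")


def write_edge_table(net: PPINetwork, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_a", "gene_b", "combined_score"])
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            w.writerow([a, b, net.graph.edges[a, b]["combined_score"]])
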