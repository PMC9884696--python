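"""Iterative median-threshold screening for core risk genes.

Each round computes the four topological parameters on its input network,
takes the per-parameter median, and keeps the nodes lying strictly above
the median on EVERY screened parameter.  The subgraph induced by the kept
nodes feeds the next round, with all parameters recomputed there — values
from the parent network are never reused.  Iteration stops when the round
budget is spent, when a round keeps every node (converged), or when a
round keeps nothing, in which case the previous round's selection is
reported as the core (discarding everything would be uninformative).

With all-distinct parameter values a strict-median cut keeps at most
``floor(n/2)`` nodes, so each effective round at most halves the network;
on vertex-transitive graphs every node sits exactly at the median and the
selection is empty by symmetry.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .network import PPINetwork
from .topology import PARAMETERS, NodeTopology, topology_table

log = logging.getLogger(__name__)

__all__ = [
    "ScreeningRound",
    "ScreeningResult",
    "round_medians",
    "screen_round",
    "iterate_screening",
    "write_rounds_table",
]

MedianBoundary = Literal["gt", "ge"]


@dataclass
class ScreeningRound:
    """One screening iteration: its medians, selection and sizes."""

    index: int
    medians: dict[str, float]
    selected: set[str]
    input_size: int
    output_size: int


@dataclass
class ScreeningResult:
    """The full screening trajectory and the surviving core genes."""

    rounds: list[ScreeningRound]
    core_genes: set[str]
    stop_reason: Literal["rounds-exhausted", "converged", "empty-selection"]


def round_medians(topo: Sequence[NodeTopology]) -> dict[str, float]:
    """Per-parameter medians (mean of the two middle order statistics
    for even node counts)."""
    if not topo:
        raise ValueError("cannot take medians of an empty topology table")
    return {
        p: float(np.median([row.value(p) for row in topo])) for p in PARAMETERS
    }


def screen_round(
    net: PPINetwork,
    parameters: Sequence[str] = PARAMETERS,
    *,
    median_boundary: MedianBoundary = "gt",
    index: int = 1,
) -> ScreeningRound:
    """Select the nodes above the median on every screened parameter."""
    unknown = set(parameters) - set(PARAMETERS)
    if unknown:
        raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
    if not parameters:
        raise ValueError("at least one parameter is required")
    topo = topology_table(net)
    medians = round_medians(topo)

    def above(row: NodeTopology) -> bool:
        if median_boundary == "gt":
            return all(row.value(p) > medians[p] for p in parameters)
        return all(row.value(p) >= medians[p] for p in parameters)

    selected = {row.node for row in topo if above(row)}
    rnd = ScreeningRound(
        index=index,
        medians=medians,
        selected=selected,
        input_size=len(topo),
        output_size=len(selected),
    )
    log.info(
        "round %d: %d -> %d nodes (medians: %s)",
        index,
        rnd.input_size,
        rnd.output_size,
        ", ".join(f"{p}={medians[p]:.6g}" for p in parameters),
    )
    return rnd


def iterate_screening(
    net: PPINetwork,
    rounds: int = 3,
    parameters: Sequence[str] = PARAMETERS,
    *,
    median_boundary: MedianBoundary = "gt",
) -> ScreeningResult:
    """Apply :func:`screen_round` up to *rounds* times on induced subgraphs."""
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    current = net
    history: list[ScreeningRound] = []
    stop: str = "rounds-exhausted"
    core: set[str] = set(current.graph.nodes)
    for i in range(1, rounds + 1):
        rnd = screen_round(
            current, parameters, median_boundary=median_boundary, index=i
        )
        history.append(rnd)
        if not rnd.selected:
            # keep the previous round's (possibly initial) node set
            stop = "empty-selection"
            break
        core = set(rnd.selected)
        if rnd.selected == set(current.graph.nodes):
            stop = "converged"
            break
        current = current.subnetwork(rnd.selected)
    result = ScreeningResult(rounds=history, core_genes=core, stop_reason=stop)  # type: ignore[arg-type]
    log.info(
        "screening stopped after %d round(s) (%s): %d core gene(s)",
        len(history),
        stop,
        len(core),
    )
    return result


def write_rounds_table(result: ScreeningResult, path: str | Path) -> None:
    """Write the per-round medians, sizes and selections as TSV."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "round",
                "input_size",
                "output_size",
                *(f"median_{p}" for p in PARAMETERS),
                "selected_genes",
            ]
        )
        for rnd in result.rounds:
            w.writerow(
                [
                    rnd.index,
                    rnd.input_size,
                    rnd.output_size,
                    *(f"{rnd.medians[p]:.9g}" for p in PARAMETERS),
                    ",".join(sorted(rnd.selected)),
                ]
            )
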