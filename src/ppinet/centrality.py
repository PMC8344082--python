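"""Degree / betweenness centrality and hub-bottleneck selection.

A *hub* is a node in the top fraction of the degree distribution, a
*bottleneck* one in the top fraction by betweenness centrality, and a
*hub-bottleneck* sits in both top sets.  The default fraction is 10%,
applied to the whole node set; centrality itself is computed on the main
connected component by default, since betweenness is only meaningful
within a component.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .graph_core import Network, components_summary

logger = logging.getLogger(__name__)

__all__ = [
    "CentralityRecord",
    "HubBottleneckSet",
    "degree_map",
    "betweenness_map",
    "centrality_records",
    "select_hub_bottlenecks",
    "write_centrality_table",
]


@dataclass(frozen=True)
class CentralityRecord:
    """Per-node degree (K) and normalized betweenness centrality (BC)."""

    node: str
    degree: int
    betweenness: float


@dataclass(frozen=True)
class HubBottleneckSet:
    """Top-fraction degree and betweenness sets and their intersection.

    ``hub_bottlenecks`` is ordered by degree descending (ties broken
    lexicographically), mirroring a degree-ranked centrality table.
    """

    hubs: frozenset[str]
    bottlenecks: frozenset[str]
    hub_bottlenecks: tuple[str, ...]
    fraction: float


def degree_map(net: Network) -> dict[str, int]:
    """Map each node to its incident-edge count (isolated nodes map to 0)."""
    return {n: d for n, d in net.graph.degree()}


def betweenness_map(net: Network, normalized: bool = True) -> dict[str, float]:
    """Shortest-path (Brandes) betweenness centrality per node.

    Edges are treated as unweighted hops; equal-length shortest paths
    split credit equally.  With ``normalized`` the raw pair count is
    divided by (n-1)(n-2)/2 where n is the node count of the analyzed
    graph, so values lie in [0, 1].
    """
    return nx.betweenness_centrality(net.graph, normalized=normalized)


def centrality_records(
    net: Network,
    main_component_only: bool = True,
) -> list[CentralityRecord]:
    """Degree and normalized betweenness for every node of the analyzed graph.

    By default the analysis restricts to the main connected component (the
    normalization constant then uses that component's node count); pass
    ``main_component_only=False`` to analyze the whole graph.  Records are
    sorted by degree descending, ties lexicographic.
    """
    target = net
    if main_component_only and net.n_nodes:
        target = net.subgraph(components_summary(net).main_component)
    deg = degree_map(target)
    bc = betweenness_map(target, normalized=True)
    recs = [CentralityRecord(n, deg[n], bc[n]) for n in target.nodes]
    recs.sort(key=lambda r: (-r.degree, r.node))
    return recs


def _top_by(records: list[CentralityRecord], key, count: int) -> set[str]:
    """Top ``count`` records by ``key`` descending, expanded to include all
    records tied with the boundary value."""
    if count <= 0 or not records:
        return set()
    ranked = sorted(records, key=lambda r: (-key(r), r.node))
    boundary = key(ranked[min(count, len(ranked)) - 1])
    chosen = {r.node for r in ranked if key(r) > boundary}
    chosen |= {r.node for r in ranked if key(r) == boundary}
    if len(chosen) > count:
        logger.info(
            "top-fraction boundary tie: %d candidates for %d slots", len(chosen), count
        )
    return chosen


def select_hub_bottlenecks(
    records: list[CentralityRecord],
    fraction: float = 0.10,
) -> HubBottleneckSet:
    """Intersect the top-fraction-by-degree and top-fraction-by-betweenness sets.

    ``floor(fraction * n)`` nodes are taken from each ranking (plus any
    records tied with the boundary value, which are never arbitrarily
    excluded); the returned hub-bottlenecks are the common nodes, ordered
    by degree descending.

    Raises
    ------
    ValueError
        If ``fraction`` is outside (0, 1] or ``records`` is empty.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    count = math.floor(fraction * len(records))
    hubs = _top_by(records, lambda r: r.degree, count)
    bottlenecks = _top_by(records, lambda r: r.betweenness, count)
    common = hubs & bottlenecks
    deg = {r.node: r.degree for r in records}
    ordered = tuple(sorted(common, key=lambda n: (-deg[n], n)))
    return HubBottleneckSet(frozenset(hubs), frozenset(bottlenecks), ordered, fraction)


def write_centrality_table(records: list[CentralityRecord], path: str | Path) -> None:
    """Write the degree-ranked centrality table (rank, gene, K, BC)."""
    with Path(path).open("w") as fh:
        fh.write("rank\tgene\tK\tBC\n")
        for rank, rec in enumerate(records, start=1):
            fh.write(f"{rank}\t{rec.node}\t{rec.degree}\t{rec.betweenness:.4f}\n")
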