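"""MCODE-style molecular complex detection.

Reimplements the three-stage MCODE clustering algorithm for undirected
simple graphs:

1. **Vertex weighting** — each vertex is weighted by its core-clustering
   coefficient: the density of the highest k-core of its closed
   neighborhood, multiplied by that core's k.  Weighting by the highest
   k-core rather than the raw neighborhood damps the effect of loosely
   attached neighbors.
2. **Complex prediction** — starting from the highest-weighted unvisited
   vertex, a complex grows outward over neighbors whose weight is within
   ``node_score_cutoff`` of the seed weight (weight >= seed_weight *
   (1 - node_score_cutoff)).  A vertex joins at most one complex.
3. **Post-processing** — complexes that do not contain a ``k_core``-core
   are discarded; *haircut* iteratively removes members with fewer than
   two within-complex edges; optional *fluff* adds boundary neighbors
   whose closed-neighborhood density exceeds ``fluff_density_cutoff``.

Complexes are scored density x size and ranked descending; a clique of
size s scores exactly s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .graph_core import Network

__all__ = [
    "MCODEParams",
    "Complex",
    "vertex_weights",
    "predict_complexes",
    "score_complex",
    "write_complexes",
]


@dataclass(frozen=True)
class MCODEParams:
    """Tunable MCODE parameters (plugin-default values).

    node_score_cutoff (often called VWP, vertex weight percentage) controls
    how far below the seed weight a neighbor may fall and still join;
    degree_cutoff zeroes the weight of sparsely connected vertices;
    k_core is the minimum core a surviving complex must contain.
    """

    node_score_cutoff: float = 0.2
    degree_cutoff: int = 2
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.2
    max_depth: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.node_score_cutoff < 1.0):
            raise ValueError("node_score_cutoff must be in [0, 1)")
        if self.degree_cutoff < 0:
            raise ValueError("degree_cutoff must be >= 0")
        if self.k_core < 2:
            raise ValueError("k_core must be >= 2")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass(frozen=True)
class Complex:
    """A detected complex: member set, density x size score, and rank."""

    members: frozenset[str]
    score: float
    rank: int

    @property
    def size(self) -> int:
        return len(self.members)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return g.number_of_edges() / (n * (n - 1) / 2)


def score_complex(net: Network, members: Iterable[str]) -> float:
    """Score a node subset as density x size.

    Density counts edges within the induced subgraph over the
    ``|V|(|V|-1)/2`` possible pairs (the graph is simple, so self-loops
    never contribute).

    Raises
    ------
    ValueError
        If the member set has fewer than 2 nodes or contains unknown nodes.
    """
    members = set(members)
    if len(members) < 2:
        raise ValueError("a complex needs at least 2 members")
    unknown = members - net.nodes
    if unknown:
        raise ValueError(f"members not in network: {sorted(unknown)}")
    sub = net.graph.subgraph(members)
    return _density(sub) * len(members)


def _highest_k_core(g: nx.Graph) -> tuple[int, nx.Graph]:
    """The maximum-k k-core of ``g`` and its k (0-core = g itself)."""
    if g.number_of_nodes() == 0:
        return 0, g
    core_nums = nx.core_number(g)
    k_max = max(core_nums.values())
    core = g.subgraph([n for n, k in core_nums.items() if k >= k_max])
    return k_max, core


def vertex_weights(net: Network, params: MCODEParams = MCODEParams()) -> dict[str, float]:
    """Core-clustering-coefficient vertex weights.

    weight(v) = k_max * density(highest k-core of the closed neighborhood
    of v); vertices whose graph degree is below ``degree_cutoff`` get 0.
    """
    g = net.graph
    weights: dict[str, float] = {}
    for v in g.nodes:
        if g.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        closed = g.subgraph(set(g.neighbors(v)) | {v})
        k_max, core = _highest_k_core(closed)
        weights[v] = k_max * _density(core)
    return weights


def _grow_complex(
    g: nx.Graph,
    weights: dict[str, float],
    seed: str,
    visited: set[str],
    params: MCODEParams,
) -> set[str]:
    """Breadth-first expansion from ``seed`` over weight-admissible neighbors."""
    threshold = weights[seed] * (1.0 - params.node_score_cutoff)
    members = {seed}
    frontier = [seed]
    depth = 0
    while frontier and depth < params.max_depth:
        nxt: list[str] = []
        for u in sorted(frontier):
            for w in sorted(g.neighbors(u)):
                if w in members or w in visited:
                    continue
                if weights[w] >= threshold:
                    members.add(w)
                    nxt.append(w)
        frontier = nxt
        depth += 1
    return members


def _haircut(g: nx.Graph, members: set[str]) -> set[str]:
    """Iteratively strip members with fewer than 2 within-complex edges.

    Equivalent to taking the 2-core of the induced subgraph.
    """
    sub = g.subgraph(members)
    return set(nx.k_core(sub, 2).nodes)


def _fluff(g: nx.Graph, members: set[str], cutoff: float) -> set[str]:
    """Add boundary neighbors whose closed-neighborhood density exceeds cutoff."""
    added = set()
    for v in sorted(members):
        for w in g.neighbors(v):
            if w in members or w in added:
                continue
            closed = g.subgraph(set(g.neighbors(w)) | {w})
            if _density(closed) > cutoff:
                added.add(w)
    return members | added


def predict_complexes(
    net: Network,
    params: MCODEParams = MCODEParams(),
) -> list[Complex]:
    """Run the full MCODE pipeline and return ranked complexes.

    Seeds are taken in descending weight order (ties broken by node name);
    grown members are marked visited so complexes stay pairwise disjoint
    (fluffed nodes, when enabled, may overlap).  Output is sorted by score
    descending, ties by larger size then lexicographically smallest member.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        return []
    weights = vertex_weights(net, params)
    order = sorted(g.nodes, key=lambda v: (-weights[v], v))
    visited: set[str] = set()
    raw: list[set[str]] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0.0:
            continue
        members = _grow_complex(g, weights, seed, visited, params)
        visited |= members
        raw.append(members)

    processed: list[set[str]] = []
    for members in raw:
        sub = g.subgraph(members)
        if sub.number_of_nodes() == 0:
            continue
        if max(nx.core_number(sub).values(), default=0) < params.k_core:
            continue
        if params.haircut:
            members = _haircut(g, members)
        if params.fluff:
            members = _fluff(g, members, params.fluff_density_cutoff)
        if len(members) < 2:
            continue
        processed.append(members)

    scored = [(score_complex(net, m), m) for m in processed]
    scored.sort(key=lambda sm: (-sm[0], -len(sm[1]), min(sm[1])))
    return [
        Complex(frozenset(m), s, rank)
        for rank, (s, m) in enumerate(scored, start=1)
    ]


def write_complexes(complexes: list[Complex], path: str | Path) -> None:
    """Write the ranked complexes TSV (rank, score, size, members)."""
    with Path(path).open("w") as fh:
        fh.write("rank\tscore\tsize\tmembers\n")
        for c in complexes:
            fh.write(f"{c.rank}\t{c.score:.4f}\t{c.size}\t{','.join(sorted(c.members))}\n")


def write_cluster_assignments(complexes: list[Complex], path: str | Path) -> None:
    """Per-node cluster-assignment TSV (node, cluster rank)."""
    with Path(path).open("w") as fh:
        fh.write("node\tcluster\n")
        rows = sorted(
            (node, c.rank) for c in complexes for node in c.members
        )
        for node, rank in rows:
            fh.write(f"{node}\t{rank}\n")
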