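"""Graph data model and edge-list I/O for confidence-scored interaction networks.

The central object is :class:`Network`, an undirected simple graph whose
nodes are uppercase gene symbols and whose edges carry a STRING-style
combined confidence score in [0, 1].  Construction enforces the invariants
the rest of the pipeline relies on: no self-loops, no parallel edges
(duplicates collapse keeping the maximum confidence), and every endpoint
registered as a node.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "ComponentSummary",
    "NetworkFormatError",
    "load_edge_list",
    "load_sif",
    "write_edge_list",
    "components_summary",
]


class NetworkFormatError(ValueError):
    """Raised when an edge-list or SIF file violates the expected dialect."""


def _normalize_symbol(raw: str) -> str:
    return raw.strip().upper()


@dataclass
class Network:
    """Undirected simple graph with per-edge confidence scores.

    Wraps a :class:`networkx.Graph`; every mutation goes through
    :meth:`add_edge` / :meth:`add_node` so the invariants (simple graph,
    uppercase symbols, confidence in [0, 1], keep-max duplicate collapse)
    hold at all times.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_node(self, symbol: str) -> str:
        sym = _normalize_symbol(symbol)
        if not sym:
            raise ValueError("empty gene symbol")
        self.graph.add_node(sym)
        return sym

    def add_edge(self, a: str, b: str, confidence: float = 1.0) -> None:
        """Insert an edge, collapsing duplicates by keeping the max confidence.

        Self-loops are rejected with ``ValueError`` (callers decide whether
        to drop them silently or warn).
        """
        ua, ub = _normalize_symbol(a), _normalize_symbol(b)
        if not ua or not ub:
            raise ValueError("empty gene symbol")
        if ua == ub:
            raise ValueError(f"self-loop on {ua!r}")
        if not (0.0 <= confidence <= 1.0):
            raise ValueError(f"confidence {confidence} outside [0, 1]")
        if self.graph.has_edge(ua, ub):
            prev = self.graph.edges[ua, ub]["confidence"]
            self.graph.edges[ua, ub]["confidence"] = max(prev, confidence)
        else:
            self.graph.add_edge(ua, ub, confidence=confidence)

    def confidence(self, a: str, b: str) -> float:
        return self.graph.edges[_normalize_symbol(a), _normalize_symbol(b)]["confidence"]

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Yield canonical (a, b, confidence) triples with a < b."""
        for u, v, c in self.graph.edges(data="confidence"):
            a, b = sorted((u, v))
            yield a, b, c

    def subgraph(self, members: Iterable[str]) -> "Network":
        members = {_normalize_symbol(m) for m in members}
        return Network(self.graph.subgraph(members).copy())

    def copy(self) -> "Network":
        return Network(self.graph.copy())


@dataclass(frozen=True)
class ComponentSummary:
    """Connected-component structure of a network.

    ``sizes`` is the multiset of component sizes; ``main_component`` the
    node set of the largest component (ties broken by the lexicographically
    smallest member).
    """

    sizes: Counter
    main_component: frozenset[str]

    @property
    def n_isolated(self) -> int:
        return self.sizes[1]

    @property
    def main_size(self) -> int:
        return len(self.main_component)


def components_summary(net: Network) -> ComponentSummary:
    """Partition the node set into connected components.

    The component sizes always sum to the node count; an empty network
    yields an empty summary.
    """
    comps = [frozenset(c) for c in nx.connected_components(net.graph)]
    sizes = Counter(len(c) for c in comps)
    if not comps:
        return ComponentSummary(sizes, frozenset())
    main = min(
        (c for c in comps if len(c) == max(sizes)),
        key=lambda c: min(c),
    )
    return ComponentSummary(sizes, main)


def _looks_like_header(fields: list[str]) -> bool:
    # Header detection: third column not parseable as a float.
    try:
        float(fields[2])
    except ValueError:
        return True
    return False


def load_edge_list(
    path: str | Path,
    score_threshold: float = 0.4,
    keep_isolated: bool = True,
) -> Network:
    """Read a STRING-export-style TSV into a confidence-filtered :class:`Network`.

    Parameters
    ----------
    path:
        Tab-separated file with at least three columns (nodeA, nodeB,
        combined confidence score in [0, 1]).  A header row is auto-detected
        by a non-numeric third field.  Lines starting with ``#`` and blank
        lines are ignored.
    score_threshold:
        Edges are kept only when their confidence is *strictly greater*
        than this value (the study's convention: score > 0.4).
    keep_isolated:
        When true, endpoints of filtered or self-loop rows remain in the
        node set as isolated nodes; when false only endpoints of surviving
        edges are kept.

    Raises
    ------
    NetworkFormatError
        On malformed rows (fewer than 3 columns, unparsable score, score
        outside [0, 1]), naming the offending line number.
    OSError
        If the file cannot be read.
    """
    path = Path(path)
    net = Network()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, got {len(fields)}"
                )
            if lineno == 1 and _looks_like_header(fields):
                continue
            a, b = _normalize_symbol(fields[0]), _normalize_symbol(fields[1])
            try:
                score = float(fields[2])
            except ValueError as exc:
                raise NetworkFormatError(
                    f"{path}:{lineno}: unparsable score {fields[2]!r}"
                ) from exc
            if not (0.0 <= score <= 1.0):
                raise NetworkFormatError(
                    f"{path}:{lineno}: score {score} outside [0, 1]"
                )
            if a == b:
                logger.warning("%s:%d: dropping self-loop on %s", path, lineno, a)
                if keep_isolated:
                    net.add_node(a)
                continue
            if keep_isolated:
                net.add_node(a)
                net.add_node(b)
            if score > score_threshold:
                net.add_edge(a, b, score)
    if not keep_isolated:
        net.graph.remove_nodes_from(list(nx.isolates(net.graph)))
    return net


def load_sif(path: str | Path, default_confidence: float = 1.0) -> Network:
    """Read a simple SIF file (``A <relation> B`` rows, whitespace-separated).

    Confidence defaults to ``default_confidence`` since SIF carries none.
    """
    path = Path(path)
    net = Network()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: SIF row needs 'source relation target'"
                )
            a, targets = fields[0], fields[2:]
            for b in targets:
                if _normalize_symbol(a) == _normalize_symbol(b):
                    logger.warning("%s:%d: dropping self-loop on %s", path, lineno, a)
                    net.add_node(a)
                    continue
                net.add_edge(a, b, default_confidence)
    return net


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write the canonical edge-list TSV: ``nodeA<TAB>nodeB<TAB>confidence``.

    Rows are sorted lexicographically with nodeA < nodeB so the format
    round-trips bit-identically.  Isolated nodes are appended as
    ``node<TAB><TAB>`` rows so the node set survives a round trip.
    """
    path = Path(path)
    rows = sorted(net.edges())
    connected = {n for a, b, _ in rows for n in (a, b)}
    with path.open("w") as fh:
        for a, b, c in rows:
            fh.write(f"{a}\t{b}\t{c:.6g}\n")
        for node in sorted(net.nodes - connected):
            fh.write(f"{node}\t\t\n")


def read_canonical_edge_list(path: str | Path) -> Network:
    """Read back the canonical dialect written by :func:`write_edge_list`."""
    path = Path(path)
    net = Network()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 3 and fields[1] == "" and fields[2] == "":
                net.add_node(fields[0])
                continue
            if len(fields) < 3:
                raise NetworkFormatError(f"{path}:{lineno}: malformed row")
            net.add_edge(fields[0], fields[1], float(fields[2]))
    return net
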