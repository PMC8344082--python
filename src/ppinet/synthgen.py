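"""Deterministic synthetic-data generators for pipeline benchmarking.

Real inputs to this pipeline come from interaction databases and
expression repositories; these generators produce structurally equivalent
stand-ins with *known* ground truth: an Erdős–Rényi background graph with
planted dense complexes, flat annotation terms with planted enrichment in
a chosen gene set, and a differential-expression top table with specified
up-/down-regulation effect sizes and Gaussian noise.  Every generator is a
pure function of its arguments including the integer seed, and each
dataset is emitted alongside a :class:`SynthTruth` record of what was
planted.

:func:`generate_benchmark` bundles all of them at the scale of a typical
disease-gene STRING query: 100 nodes, one dominant dense complex of 19
members, and six designated high-centrality connector nodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests
import pandas as pd

from .expression_actions import ActionEdge
from .enrichment import TermAnnotation
from .graph_core import Network

__all__ = [
    "SynthTruth",
    "generate_network",
    "generate_annotations",
    "generate_expression",
    "generate_benchmark",
]


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth emitted alongside every generated dataset."""

    planted_complexes: tuple[frozenset[str], ...] = ()
    enriched_terms: frozenset[str] = frozenset()
    up_genes: frozenset[str] = frozenset()
    down_genes: frozenset[str] = frozenset()
    hub_nodes: frozenset[str] = frozenset()
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "planted_complexes": [sorted(c) for c in self.planted_complexes],
            "enriched_terms": sorted(self.enriched_terms),
            "up_genes": sorted(self.up_genes),
            "down_genes": sorted(self.down_genes),
            "hub_nodes": sorted(self.hub_nodes),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _node_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _confidence(rng: np.random.Generator) -> float:
    # Uniform above the conventional 0.4 cutoff so no generated edge is filtered.
    return float(rng.uniform(0.41, 1.0))


def generate_network(
    n: int,
    background_p: float,
    planted: Sequence[tuple[int, float]] = (),
    seed: int = 0,
) -> tuple[Network, SynthTruth]:
    """Erdős–Rényi background with planted dense subgraphs.

    Parameters
    ----------
    n:
        Total node count; planted blocks are carved from the front of the
        node list, disjointly.
    background_p:
        Bernoulli probability for each node pair not already wired by a
        planted block.
    planted:
        ``(size, density)`` pairs; each block's internal pairs are wired
        independently with probability ``density`` (density 1.0 plants an
        exact clique).
    seed:
        Single integer governing all randomness; identical arguments give
        byte-identical edge lists.

    Edge confidences are drawn uniform(0.41, 1.0) so every generated edge
    survives the conventional 0.4 confidence filter.
    """
    if not (0.0 <= background_p <= 1.0):
        raise ValueError("background_p must lie in [0, 1]")
    if sum(size for size, _ in planted) > n:
        raise ValueError("planted sizes exceed n")
    rng = np.random.default_rng(seed)
    names = _node_names(n)
    net = Network()
    for name in names:
        net.add_node(name)

    blocks: list[frozenset[str]] = []
    start = 0
    planted_pairs: set[tuple[str, str]] = set()
    for size, density in planted:
        if size > n:
            raise ValueError(f"planted size {size} exceeds n={n}")
        members = names[start : start + size]
        start += size
        blocks.append(frozenset(members))
        for a, b in combinations(members, 2):
            planted_pairs.add((a, b))
            if rng.random() < density:
                net.add_edge(a, b, _confidence(rng))

    if background_p > 0:
        for a, b in combinations(names, 2):
            if (a, b) in planted_pairs:
                continue
            if rng.random() < background_p:
                net.add_edge(a, b, _confidence(rng))

    truth = SynthTruth(planted_complexes=tuple(blocks), seed=seed)
    return net, truth


def generate_annotations(
    n_terms: int,
    universe: Sequence[str],
    enriched_in: Sequence[str] = (),
    enrichment_strength: float = 1.0,
    seed: int = 0,
    n_enriched: int = 0,
    term_size_range: tuple[int, int] = (5, 25),
) -> tuple[list[TermAnnotation], SynthTruth]:
    """Flat annotation terms with a planted enrichment signal.

    The first ``n_enriched`` terms draw a fraction ``enrichment_strength``
    of their genes from ``enriched_in`` (the rest uniformly from the
    remainder of the universe); background terms sample genes uniformly
    from the whole universe.  Term sizes are uniform over
    ``term_size_range`` and capped at the universe size.
    """
    universe = sorted(set(universe))
    enriched_in = sorted(set(enriched_in))
    if set(enriched_in) - set(universe):
        raise ValueError("enriched_in must be a subset of the universe")
    if not (0.0 <= enrichment_strength <= 1.0):
        raise ValueError("enrichment_strength must lie in [0, 1]")
    if n_enriched > n_terms:
        raise ValueError("n_enriched cannot exceed n_terms")
    rng = np.random.default_rng(seed)
    rest = [g for g in universe if g not in set(enriched_in)]
    terms: list[TermAnnotation] = []
    enriched_ids: list[str] = []
    lo, hi = term_size_range
    for i in range(n_terms):
        term_id = f"TERM{i + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(universe))
        if i < n_enriched and enriched_in:
            k_in = min(int(round(enrichment_strength * size)), len(enriched_in))
            k_out = min(size - k_in, len(rest))
            genes = list(rng.choice(enriched_in, size=k_in, replace=False))
            if k_out > 0:
                genes += list(rng.choice(rest, size=k_out, replace=False))
            enriched_ids.append(term_id)
        else:
            genes = list(rng.choice(universe, size=size, replace=False))
        terms.append(TermAnnotation(term_id, f"synthetic process {i + 1}", frozenset(genes)))
    truth = SynthTruth(enriched_terms=frozenset(enriched_ids), seed=seed)
    return terms, truth


def generate_expression(
    genes: Sequence[str],
    up: tuple[Sequence[str], float] = ((), 0.0),
    down: tuple[Sequence[str], float] = ((), 0.0),
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, SynthTruth]:
    """GEO2R-style top table with planted up-/down-regulated genes.

    Members of the up (down) set draw logFC ~ Normal(+mean, noise_sd)
    (Normal(-mean, noise_sd)); all other genes draw from Normal(0,
    noise_sd).  P-values are the two-sided z-probability of the observed
    logFC under the null Normal(0, noise_sd), and adj.P.Val applies
    Benjamini-Hochberg.  Columns follow the GEO2R top-table dialect.
    """
    up_set, up_mean = set(up[0]), float(up[1])
    down_set, down_mean = set(down[0]), float(down[1])
    if up_set & down_set:
        raise ValueError("up and down gene sets must be disjoint")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    genes = sorted(set(genes))
    means = np.array(
        [up_mean if g in up_set else -down_mean if g in down_set else 0.0 for g in genes]
    )
    logfc = rng.normal(means, noise_sd)
    pvals = 2.0 * norm.sf(np.abs(logfc) / noise_sd)
    padj = multipletests(pvals, method="fdr_bh")[1] if len(genes) else np.array([])
    df = pd.DataFrame(
        {
            "ID": [f"probe_{i + 1}" for i in range(len(genes))],
            "adj.P.Val": padj,
            "P.Value": pvals,
            "t": logfc / noise_sd,
            "logFC": logfc,
            "Gene.symbol": genes,
        }
    )
    truth = SynthTruth(
        up_genes=frozenset(up_set), down_genes=frozenset(down_set), seed=seed
    )
    return df, truth


def generate_benchmark(
    seed: int = 0,
    n_nodes: int = 100,
    complex_size: int = 19,
    complex_density: float = 0.9,
    background_p: float = 0.03,
    n_hubs: int = 6,
    hubs_in_complex: int = 5,
    spokes_per_hub: int = 25,
    n_terms: int = 30,
    n_enriched_terms: int = 3,
    enrichment_strength: float = 1.0,
    up_mean: float = 4.51,
    down_mean: float = 4.11,
    noise_sd: float = 0.5,
) -> dict:
    """Full four-input benchmark dataset at disease-query scale.

    Produces a 100-node network with one planted dense 19-member complex
    and six designated connector nodes (five inside the complex, one
    outside) wired to many background nodes so they dominate both the
    degree and the betweenness rankings; annotation terms enriched in the
    complex; a top table up-/down-regulating disjoint halves of the
    complex (one member is deliberately left off the expression platform);
    and a typed action overlay among complex members.

    Returns a dict with keys ``network``, ``terms``, ``top_table``,
    ``actions``, ``truth``.
    """
    if hubs_in_complex > min(n_hubs, complex_size):
        raise ValueError("hubs_in_complex inconsistent with n_hubs/complex_size")
    net, truth_net = generate_network(
        n_nodes, background_p, [(complex_size, complex_density)], seed=seed
    )
    rng = np.random.default_rng(seed + 1)
    names = _node_names(n_nodes)
    complex_members = sorted(truth_net.planted_complexes[0])
    outside = [g for g in names if g not in set(complex_members)]
    hubs = complex_members[:hubs_in_complex] + outside[: n_hubs - hubs_in_complex]
    # Connector wiring: spokes into the background give the designated hubs
    # both high degree and high betweenness (leaves route through them).
    spoke_pool = outside[n_hubs - hubs_in_complex :]
    for i, hub in enumerate(hubs):
        k = spokes_per_hub + (5 if i >= hubs_in_complex else 0)
        k = min(k, len(spoke_pool))
        targets = rng.choice(spoke_pool, size=k, replace=False)
        for t in targets:
            if not net.graph.has_edge(hub, t):
                net.add_edge(hub, t, _confidence(rng))

    terms, truth_ann = generate_annotations(
        n_terms,
        universe=names,
        enriched_in=complex_members,
        enrichment_strength=enrichment_strength,
        seed=seed + 2,
        n_enriched=n_enriched_terms,
        term_size_range=(8, 18),
    )

    # One complex member is left off the expression platform on purpose:
    # real platforms rarely cover every queried gene.
    measured = sorted(set(names) - {complex_members[-1]})
    half = (complex_size - 1) // 2
    up_genes = [g for g in complex_members[:-1]][:half]
    down_genes = [g for g in complex_members[:-1]][half:]
    top_table, truth_expr = generate_expression(
        measured,
        up=(up_genes, up_mean),
        down=(down_genes, down_mean),
        noise_sd=noise_sd,
        seed=seed + 3,
    )

    actions = _generate_actions(net, complex_members, rng)

    truth = SynthTruth(
        planted_complexes=truth_net.planted_complexes,
        enriched_terms=truth_ann.enriched_terms,
        up_genes=truth_expr.up_genes,
        down_genes=truth_expr.down_genes,
        hub_nodes=frozenset(hubs),
        seed=seed,
    )
    return {
        "network": net,
        "terms": terms,
        "top_table": top_table,
        "actions": actions,
        "truth": truth,
    }


def _generate_actions(
    net: Network, members: Sequence[str], rng: np.random.Generator
) -> list[ActionEdge]:
    """Type a random action for each within-complex interaction."""
    kinds = ("activation", "inhibition", "expression")
    member_set = set(members)
    edges = []
    for a, b, _ in sorted(net.edges()):
        if a in member_set and b in member_set:
            kind = kinds[int(rng.integers(0, 3))]
            edges.append(ActionEdge(a, b, kind, float(rng.uniform(0.0, 1.0))))
    return edges
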