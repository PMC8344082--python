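"""Hypergeometric term enrichment with Holm correction and kappa grouping.

Given a query gene set (typically the members of a detected complex) and a
flat term-to-genes annotation (GMT), each term is tested with a two-sided
hypergeometric (enrichment/depletion) test, p-values are adjusted with the
Holm step-down (Bonferroni step-down) procedure, and related terms are
collapsed into functional groups by Cohen's kappa agreement between their
gene-membership vectors — terms whose kappa reaches the grouping threshold
(default 0.5) seed a group, and groups sharing at least half their members
merge to a fixpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TermAnnotation",
    "EnrichmentResult",
    "TermGroup",
    "read_gmt",
    "write_gmt",
    "hypergeom_pvalue",
    "holm_adjust",
    "enrich",
    "kappa_pairwise",
    "group_terms",
    "write_enrichment_table",
]


@dataclass(frozen=True)
class TermAnnotation:
    """A flat annotation term: id, human-readable name, annotated gene set."""

    term_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id}: empty gene set")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term test outcome; ``direction`` reports the smaller tail."""

    term_id: str
    overlap: int
    p_raw: float
    p_adjusted: float
    direction: str  # "enriched" | "depleted"


@dataclass(frozen=True)
class TermGroup:
    """A kappa-derived functional group of terms.

    ``leading_term`` is the member with the lowest adjusted p-value.
    """

    group_id: int
    members: frozenset[str]
    leading_term: str


def read_gmt(path: str | Path) -> list[TermAnnotation]:
    """Parse a GMT file: ``term_id<TAB>description<TAB>gene1<TAB>gene2...``."""
    terms: list[TermAnnotation] = []
    seen: set[str] = set()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if not fields or not fields[0].strip():
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT row needs id, description, genes")
            term_id = fields[0].strip()
            if term_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            seen.add(term_id)
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            terms.append(TermAnnotation(term_id, fields[1].strip(), genes))
    return terms


def write_gmt(terms: Sequence[TermAnnotation], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.name, *sorted(t.genes)]) + "\n")


def hypergeom_pvalue(
    overlap: int,
    query_size: int,
    term_size: int,
    universe_size: int,
    sided: str = "two",
) -> float:
    """Hypergeometric tail probability for a query/term overlap.

    With X ~ Hypergeom(universe_size, term_size, query_size):
    ``upper`` = P(X >= overlap), ``lower`` = P(X <= overlap), and
    ``two`` = min(1, 2 * min(upper, lower)).

    Raises
    ------
    ValueError
        On inconsistent counts or an unknown sidedness.
    """
    if not (0 <= overlap <= min(query_size, term_size)):
        raise ValueError(
            f"overlap {overlap} inconsistent with query {query_size}, term {term_size}"
        )
    if max(term_size, query_size) > universe_size:
        raise ValueError("term/query cannot exceed the universe")
    if overlap < query_size + term_size - universe_size:
        raise ValueError("overlap below the feasible minimum")
    if sided == "upper":
        return min(float(hypergeom.sf(overlap - 1, universe_size, term_size, query_size)), 1.0)
    if sided == "lower":
        return min(float(hypergeom.cdf(overlap, universe_size, term_size, query_size)), 1.0)
    if sided == "two":
        upper = float(hypergeom.sf(overlap - 1, universe_size, term_size, query_size))
        lower = float(hypergeom.cdf(overlap, universe_size, term_size, query_size))
        return min(1.0, 2.0 * min(upper, lower))
    raise ValueError(f"unknown sidedness {sided!r}")


def holm_adjust(pvals: Sequence[float]) -> list[float]:
    """Holm step-down ("Bonferroni step-down") adjusted p-values.

    Returned in the original input order; monotone non-decreasing along
    the sorted sequence and capped at 1.
    """
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="holm")[1])


def enrich(
    query: Iterable[str],
    terms: Sequence[TermAnnotation],
    universe: Iterable[str] | None = None,
    sided: str = "two",
) -> list[EnrichmentResult]:
    """Test every term against the query gene set.

    The universe defaults to the union of all annotated genes; the query
    is intersected with the universe before testing.  Results come back in
    the input term order with Holm-adjusted p-values.
    """
    if universe is None:
        universe_set = set().union(*(t.genes for t in terms)) if terms else set()
    else:
        universe_set = set(universe)
    query_set = set(query) & universe_set
    results = []
    for t in terms:
        term_genes = t.genes & universe_set
        k = len(query_set & term_genes)
        upper = hypergeom_pvalue(k, len(query_set), len(term_genes),
                                 len(universe_set), "upper")
        lower = hypergeom_pvalue(k, len(query_set), len(term_genes),
                                 len(universe_set), "lower")
        p = hypergeom_pvalue(k, len(query_set), len(term_genes),
                             len(universe_set), sided)
        direction = "enriched" if upper <= lower else "depleted"
        results.append((t.term_id, k, p, direction))
    adj = holm_adjust([r[2] for r in results])
    return [
        EnrichmentResult(tid, k, p, pa, d)
        for (tid, k, p, d), pa in zip(results, adj)
    ]


def kappa_pairwise(
    terms: Sequence[TermAnnotation],
    universe: Iterable[str],
) -> np.ndarray:
    """Cohen's kappa between the binary gene-membership vectors of each term pair.

    Membership is evaluated over ``universe``; the matrix is symmetric with
    unit diagonal.  When chance agreement is exact (both vectors constant),
    kappa is defined as 1 for identical vectors and 0 otherwise.
    """
    universe_list = sorted(set(universe))
    if not universe_list:
        raise ValueError("universe must be non-empty")
    n = len(universe_list)
    idx = {g: i for i, g in enumerate(universe_list)}
    m = np.zeros((len(terms), n), dtype=float)
    for ti, t in enumerate(terms):
        extra = t.genes - idx.keys()
        if extra:
            raise ValueError(f"term {t.term_id}: genes outside universe: {sorted(extra)[:3]}")
        for g in t.genes:
            m[ti, idx[g]] = 1.0

    both = m @ m.T                      # a: in both terms
    sizes = m.sum(axis=1)
    a = both
    b = sizes[:, None] - both           # in row term only
    c = sizes[None, :] - both           # in column term only
    d = n - a - b - c
    po = (a + d) / n
    pe = (sizes[:, None] * sizes[None, :]
          + (n - sizes[:, None]) * (n - sizes[None, :])) / n**2
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (po - pe) / (1.0 - pe)
    degenerate = np.isclose(pe, 1.0)
    kappa[degenerate] = np.where(np.isclose(po[degenerate], 1.0), 1.0, 0.0)
    np.fill_diagonal(kappa, 1.0)
    return kappa


def _merge_to_fixpoint(groups: list[frozenset[str]], merge_fraction: float) -> list[frozenset[str]]:
    """Merge groups sharing >= merge_fraction of the smaller group's members."""
    groups = sorted(set(groups), key=lambda g: (sorted(g)))
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                inter = len(groups[i] & groups[j])
                if inter and inter / min(len(groups[i]), len(groups[j])) >= merge_fraction:
                    merged = groups[i] | groups[j]
                    groups = [g for k, g in enumerate(groups) if k not in (i, j)]
                    groups.append(merged)
                    groups.sort(key=lambda g: sorted(g))
                    changed = True
                    break
            if changed:
                break
    return groups


def group_terms(
    kappa: np.ndarray,
    terms: Sequence[TermAnnotation],
    results: Sequence[EnrichmentResult],
    threshold: float = 0.5,
    group_min: int = 2,
    group_max: int = 8,
    fusion: bool = True,
    merge_fraction: float = 0.5,
) -> list[TermGroup]:
    """Collapse terms into kappa-linked functional groups.

    Each term seeds an initial group containing itself plus its highest-
    kappa partners at ``kappa >= threshold`` (at most ``group_max`` members;
    negative kappas are floored at 0 for the decision).  Groups sharing at
    least ``merge_fraction`` of the smaller group's members merge
    iteratively to a fixpoint; groups smaller than ``group_min`` are
    dropped.  With ``fusion``, terms annotating identical gene sets are
    first collapsed to the one with the lowest adjusted p.  Each surviving
    group's leading term is its lowest-adjusted-p member.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    if group_min < 1:
        raise ValueError("group_min must be >= 1")
    if not len(terms):
        return []
    padj = {r.term_id: r.p_adjusted for r in results}
    order = {t.term_id: i for i, t in enumerate(terms)}

    keep = list(range(len(terms)))
    if fusion:
        by_genes: dict[frozenset[str], list[int]] = {}
        for i, t in enumerate(terms):
            by_genes.setdefault(t.genes, []).append(i)
        keep = sorted(
            min(ix, key=lambda i: (padj.get(terms[i].term_id, 1.0), terms[i].term_id))
            for ix in by_genes.values()
        )

    k = np.maximum(kappa, 0.0)
    initial: list[frozenset[str]] = []
    for i in keep:
        partners = [j for j in keep if j != i and k[i, j] >= threshold]
        partners.sort(key=lambda j: (-k[i, j], terms[j].term_id))
        members = [terms[i].term_id] + [terms[j].term_id for j in partners[: group_max - 1]]
        initial.append(frozenset(members))

    merged = _merge_to_fixpoint(initial, merge_fraction)
    merged = [g for g in merged if len(g) >= group_min]
    merged.sort(key=lambda g: min(padj.get(t, 1.0) for t in g))
    out = []
    for gid, members in enumerate(merged, start=1):
        leader = min(members, key=lambda t: (padj.get(t, 1.0), order.get(t, 0), t))
        out.append(TermGroup(gid, members, leader))
    return out


def write_enrichment_table(
    results: Sequence[EnrichmentResult],
    groups: Sequence[TermGroup],
    path: str | Path,
) -> None:
    """Enrichment TSV: term, overlap, p_raw, p_holm, direction, group, leading."""
    term_group = {t: g.group_id for g in groups for t in g.members}
    leaders = {g.leading_term for g in groups}
    with Path(path).open("w") as fh:
        fh.write("term\toverlap\tp_raw\tp_holm\tdirection\tgroup\tleading\n")
        for r in sorted(results, key=lambda r: (r.p_adjusted, r.term_id)):
            gid = term_group.get(r.term_id, "")
            lead = "yes" if r.term_id in leaders else "no"
            fh.write(
                f"{r.term_id}\t{r.overlap}\t{r.p_raw:.6g}\t{r.p_adjusted:.6g}"
                f"\t{r.direction}\t{gid}\t{lead}\n"
            )
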