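"""Expression top-table integration and typed action-edge overlay.

Converts limma/GEO2R-style log2 fold changes to signed fold changes
(|FC| = 2^|logFC|, sign following logFC), max-normalizes within the up-
and down-regulated classes separately, flags significance at p <= 0.05,
overlays typed regulatory actions (activation / inhibition / expression),
and reports the overlap between the network's central nodes and a complex
of interest as two percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ExpressionRecord",
    "ActionEdge",
    "ACTION_TYPES",
    "logfc_to_fc",
    "normalize_fc",
    "read_top_table",
    "load_action_file",
    "write_action_file",
    "central_overlap_report",
    "merge_gene_report",
]

ACTION_TYPES = frozenset({"activation", "inhibition", "expression"})

# GEO2R/limma top tables drift in how they label columns; accept the common variants.
_GENE_COLUMNS = ("Gene.symbol", "Gene symbol", "GENE_SYMBOL", "SYMBOL", "gene", "Gene")
_P_COLUMNS = ("P.Value", "P.value", "pvalue", "p", "P")
_ADJP_COLUMNS = ("adj.P.Val", "adj.P.val", "padj", "adj_p", "FDR")


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's differential-expression summary.

    ``fc`` is the signed fold change (|fc| = 2^|logfc|, sign(fc) =
    sign(logfc)); ``fc_norm`` the within-direction max-normalized
    magnitude; ``significant`` flags p <= the chosen threshold.
    """

    gene: str
    logfc: float
    fc: float
    fc_norm: float | None
    p: float
    significant: bool


@dataclass(frozen=True)
class ActionEdge:
    """A typed, scored regulatory action between two genes."""

    source: str
    target: str
    action: str
    score: float

    def __post_init__(self) -> None:
        if self.action not in ACTION_TYPES:
            raise ValueError(f"unknown action {self.action!r}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


def logfc_to_fc(logfc: float) -> float:
    """Signed fold change from a log2 fold change.

    Returns 2**logfc for logfc >= 0 and -(2**(-logfc)) otherwise, so a
    two-fold repression maps to -2.0.  Odd-symmetric (f(-x) = -f(x)) except
    at 0, where the >= branch gives f(0) = 1.
    """
    if logfc >= 0:
        return 2.0 ** logfc
    return -(2.0 ** (-logfc))


def normalize_fc(
    records: Sequence[ExpressionRecord],
    strategy: str = "max",
) -> list[ExpressionRecord]:
    """Normalize fold-change magnitudes within each direction class.

    ``max`` (default) divides |FC| by the largest |FC| of the same sign,
    so each class's extreme maps to exactly 1.0; ``sum`` divides by the
    class total.  An empty direction class is left untouched.
    """
    if strategy not in ("max", "sum"):
        raise ValueError(f"unknown normalization strategy {strategy!r}")
    up = [r for r in records if r.fc > 0]
    down = [r for r in records if r.fc < 0]
    denom = {}
    for key, cls in (("up", up), ("down", down)):
        if cls:
            mags = [abs(r.fc) for r in cls]
            denom[key] = max(mags) if strategy == "max" else sum(mags)
    out = []
    for r in records:
        key = "up" if r.fc > 0 else "down"
        if key in denom and denom[key] > 0:
            out.append(replace(r, fc_norm=abs(r.fc) / denom[key]))
        else:
            out.append(r)
    return out


def _pick_column(df: pd.DataFrame, candidates: Sequence[str], what: str) -> str:
    for c in candidates:
        if c in df.columns:
            return c
    raise ValueError(f"top-table lacks a {what} column (looked for {candidates})")


def read_top_table(
    path: str | Path,
    p_threshold: float = 0.05,
    use_adjusted_p: bool = False,
) -> list[ExpressionRecord]:
    """Read a GEO2R-style top table into expression records.

    Requires gene-symbol, logFC and P-value columns (several common
    spellings accepted, extra columns ignored).  Rows without a gene
    symbol are dropped; for duplicated symbols the smallest-p row wins.
    Significance is called at ``p <= p_threshold`` on the raw p-value, or
    on the adjusted one with ``use_adjusted_p``.
    """
    df = pd.read_csv(path, sep="\t")
    gene_col = _pick_column(df, _GENE_COLUMNS, "gene symbol")
    if "logFC" not in df.columns:
        raise ValueError("top-table lacks a logFC column")
    p_col = _pick_column(df, _ADJP_COLUMNS if use_adjusted_p else _P_COLUMNS, "p-value")
    df = df.dropna(subset=[gene_col, "logFC", p_col])
    df = df.sort_values(p_col, kind="stable").drop_duplicates(subset=gene_col)
    records = []
    for _, row in df.iterrows():
        gene = str(row[gene_col]).strip().upper()
        lfc = float(row["logFC"])
        p = float(row[p_col])
        records.append(
            ExpressionRecord(
                gene=gene,
                logfc=lfc,
                fc=logfc_to_fc(lfc),
                fc_norm=None,
                p=p,
                significant=p <= p_threshold,
            )
        )
    records.sort(key=lambda r: r.gene)
    return records


def load_action_file(
    path: str | Path,
    score_threshold: float | None = None,
) -> list[ActionEdge]:
    """Parse a typed action TSV (source, target, action, score).

    A header row is auto-detected (non-numeric fourth field).  Unknown
    action labels or scores outside [0, 1] raise ``ValueError`` naming the
    line.  With ``score_threshold``, only rows with score >= threshold are
    kept.
    """
    path = Path(path)
    edges: list[ActionEdge] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            if lineno == 1:
                try:
                    float(fields[3])
                except ValueError:
                    continue  # header
            try:
                score = float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable score {fields[3]!r}") from exc
            action = fields[2].strip().lower()
            try:
                edge = ActionEdge(
                    fields[0].strip().upper(), fields[1].strip().upper(), action, score
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if score_threshold is None or score >= score_threshold:
                edges.append(edge)
    return edges


def write_action_file(edges: Iterable[ActionEdge], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("source\ttarget\taction\tscore\n")
        for e in sorted(edges, key=lambda e: (e.source, e.target, e.action)):
            fh.write(f"{e.source}\t{e.target}\t{e.action}\t{e.score:.4f}\n")


def central_overlap_report(
    hub_bottlenecks: Iterable[str],
    complex_members: Iterable[str],
) -> tuple[int, int]:
    """Percent of central nodes inside the complex, and vice versa.

    Returns ``(pct_centrals_in_cluster, pct_cluster_from_centrals)`` =
    (100*|H∩C|/|H|, 100*|H∩C|/|C|), each rounded to the nearest integer.

    Raises
    ------
    ValueError
        If either set is empty.
    """
    hubs = set(hub_bottlenecks)
    cluster = set(complex_members)
    if not hubs or not cluster:
        raise ValueError("both node sets must be non-empty")
    common = len(hubs & cluster)
    return (
        round(100.0 * common / len(hubs)),
        round(100.0 * common / len(cluster)),
    )


def merge_gene_report(
    genes: Iterable[str],
    records: Sequence[ExpressionRecord],
    cluster_members: Iterable[str] = (),
    hub_bottlenecks: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-gene merged report over ``genes`` (typically a complex's members).

    Genes absent from the top-table appear with status ``not identified``
    rather than being dropped — a gene can sit in the network yet be
    missing from the expression platform.
    """
    by_gene = {r.gene: r for r in records}
    cluster = {g.upper() for g in cluster_members}
    hubs = {g.upper() for g in hub_bottlenecks}
    rows = []
    for gene in sorted({g.strip().upper() for g in genes}):
        rec = by_gene.get(gene)
        rows.append(
            {
                "gene": gene,
                "status": "identified" if rec else "not identified",
                "logFC": rec.logfc if rec else float("nan"),
                "FC": rec.fc if rec else float("nan"),
                "FC_norm": (rec.fc_norm if rec and rec.fc_norm is not None else float("nan")),
                "p": rec.p if rec else float("nan"),
                "significant": bool(rec.significant) if rec else False,
                "in_cluster": gene in cluster,
                "is_hub_bottleneck": gene in hubs,
            }
        )
    return pd.DataFrame(rows)
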