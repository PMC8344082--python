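"""End-to-end orchestration of the network-analysis stages.

:func:`run_pipeline` chains the stages in study order — confidence-filtered
network construction, component summary, centrality and hub-bottleneck
calling, MCODE complex detection, enrichment of the rank-1 complex, action
overlay, expression integration, and the central-node/cluster overlap
report — writing one TSV per stage plus a run manifest.  Any stage whose
input file is absent is skipped with a log line; the remaining outputs are
still produced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .centrality import (
    centrality_records,
    select_hub_bottlenecks,
    write_centrality_table,
)
from .complex_detection import (
    MCODEParams,
    predict_complexes,
    write_cluster_assignments,
    write_complexes,
)
from .enrichment import (
    enrich,
    group_terms,
    kappa_pairwise,
    read_gmt,
    write_enrichment_table,
)
from .expression_actions import (
    central_overlap_report,
    load_action_file,
    merge_gene_report,
    normalize_fc,
    read_top_table,
    write_action_file,
)
from .graph_core import components_summary, load_edge_list, write_edge_list

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults reproduce the study settings.

    Confidence filter > 0.4, top-10% hub/bottleneck fraction, MCODE plugin
    defaults, kappa grouping at >= 0.5 with group sizes 2..8, and p <= 0.05
    significance.
    """

    edge_list: str = ""
    gmt: str | None = None
    top_table: str | None = None
    action_file: str | None = None
    out_dir: str = "ppinet_out"
    score_threshold: float = 0.4
    hub_fraction: float = 0.10
    mcode: MCODEParams = field(default_factory=MCODEParams)
    kappa_threshold: float = 0.5
    group_min: int = 2
    group_max: int = 8
    significance: float = 0.05
    action_score_threshold: float | None = None
    main_component_only: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not self.edge_list:
            raise ValueError("config: edge_list path is required")
        if not (0.0 <= self.score_threshold <= 1.0):
            raise ValueError("config: score_threshold outside [0, 1]")
        if not (0.0 < self.hub_fraction <= 1.0):
            raise ValueError("config: hub_fraction outside (0, 1]")
        if not (0.0 <= self.kappa_threshold <= 1.0):
            raise ValueError("config: kappa_threshold outside [0, 1]")
        if not (0.0 <= self.significance <= 1.0):
            raise ValueError("config: significance outside [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "mcode" in d and isinstance(d["mcode"], dict):
            d["mcode"] = MCODEParams(**d["mcode"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and write the report bundle.

    Returns a dict of in-memory stage results (network, summary, records,
    hub-bottleneck set, complexes, enrichment, overlap percentages) for
    programmatic use; files land under ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage: network construction (threshold > %g)", config.score_threshold)
    net = load_edge_list(config.edge_list, config.score_threshold, keep_isolated=True)
    summary = components_summary(net)
    with (out / "network_summary.tsv").open("w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"nodes\t{net.n_nodes}\n")
        fh.write(f"edges\t{net.n_edges}\n")
        fh.write(f"isolated_nodes\t{summary.n_isolated}\n")
        fh.write(f"main_component_nodes\t{summary.main_size}\n")
        fh.write(
            f"main_component_edges\t{net.subgraph(summary.main_component).n_edges}\n"
        )
        sizes = ",".join(
            f"{s}x{c}" for s, c in sorted(summary.sizes.items(), reverse=True)
        )
        fh.write(f"component_sizes\t{sizes}\n")
    write_edge_list(net, out / "network_edges.tsv")

    logger.info("stage: centrality")
    records = centrality_records(net, main_component_only=config.main_component_only)
    write_centrality_table(records, out / "centrality.tsv")
    hb = select_hub_bottlenecks(records, config.hub_fraction)
    with (out / "hub_bottlenecks.tsv").open("w") as fh:
        fh.write("gene\trole\n")
        for n in sorted(hb.hubs - set(hb.hub_bottlenecks)):
            fh.write(f"{n}\thub\n")
        for n in sorted(hb.bottlenecks - set(hb.hub_bottlenecks)):
            fh.write(f"{n}\tbottleneck\n")
        for n in hb.hub_bottlenecks:
            fh.write(f"{n}\thub-bottleneck\n")

    logger.info("stage: complex detection (MCODE)")
    complexes = predict_complexes(net, config.mcode)
    write_complexes(complexes, out / "complexes.tsv")
    write_cluster_assignments(complexes, out / "cluster_assignments.tsv")
    top_members: frozenset[str] = complexes[0].members if complexes else frozenset()

    results = groups = None
    if config.gmt and Path(config.gmt).exists():
        logger.info("stage: enrichment of rank-1 complex")
        terms = read_gmt(config.gmt)
        results = enrich(top_members, terms)
        kappa = kappa_pairwise(
            terms, set().union(*(t.genes for t in terms)) if terms else set()
        )
        groups = group_terms(
            kappa,
            terms,
            results,
            threshold=config.kappa_threshold,
            group_min=config.group_min,
            group_max=config.group_max,
        )
        write_enrichment_table(results, groups, out / "enrichment.tsv")
    else:
        logger.info("stage: enrichment skipped (no GMT input)")

    actions = None
    if config.action_file and Path(config.action_file).exists():
        logger.info("stage: action overlay")
        actions = load_action_file(config.action_file, config.action_score_threshold)
        overlay = [
            a for a in actions if a.source in top_members and a.target in top_members
        ]
        write_action_file(overlay, out / "actions_cluster1.tsv")
    else:
        logger.info("stage: actions skipped (no action file)")

    expr = None
    if config.top_table and Path(config.top_table).exists():
        logger.info("stage: expression integration")
        expr = read_top_table(config.top_table, p_threshold=config.significance)
        expr = normalize_fc(expr)
        report = merge_gene_report(
            top_members or net.nodes,
            expr,
            cluster_members=top_members,
            hub_bottlenecks=hb.hub_bottlenecks,
        )
        report.to_csv(out / "expression_report.tsv", sep="\t", index=False,
                      float_format="%.6g")
    else:
        logger.info("stage: expression skipped (no top-table)")

    overlap = None
    if hb.hub_bottlenecks and top_members:
        pct_central, pct_cluster = central_overlap_report(
            hb.hub_bottlenecks, top_members
        )
        overlap = (pct_central, pct_cluster)
        with (out / "overlap_report.tsv").open("w") as fh:
            fh.write("metric\tpercent\n")
            fh.write(f"centrals_in_cluster1\t{pct_central}\n")
            fh.write(f"cluster1_from_centrals\t{pct_cluster}\n")

    manifest = {
        "ppinet_version": __version__,
        "config": config.to_dict(),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "network": net,
        "summary": summary,
        "centrality": records,
        "hub_bottlenecks": hb,
        "complexes": complexes,
        "enrichment": results,
        "groups": groups,
        "actions": actions,
        "expression": expr,
        "overlap": overlap,
    }
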