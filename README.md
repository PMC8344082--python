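# ppinet

Topology and annotation analysis of disease-centred protein–protein
interaction (PPI) networks, for bioinformaticians who want the standard
"network → central genes → complexes → enrichment → expression" workflow
as a reproducible, scriptable library instead of a chain of GUI tools.

Given a confidence-scored interaction edge list, a GMT annotation, a
differential-expression top table and a typed action file, `ppinet`:

1. builds an undirected simple **network**, keeping edges with combined
   confidence score > 0.4 and summarizing connected components;
2. computes **degree** K and normalized **betweenness centrality**
   BC(v) = Σ_{s≠v≠t} σ_st(v)/σ_st ÷ ((n−1)(n−2)/2), and calls
   **hub-bottlenecks** — the intersection of the top 10% by K and the top
   10% by BC;
3. detects dense **protein complexes** with a full reimplementation of the
   MCODE algorithm (k-core based vertex weighting, seeded growth at
   weight ≥ seed·(1−VWP), 2-core filter, haircut/fluff post-processing),
   scored density × size;
4. tests the rank-1 complex for **term enrichment** with a two-sided
   hypergeometric test, Holm (Bonferroni step-down) correction, and
   ClueGO-style grouping of terms by Cohen's kappa ≥ 0.5 between their
   gene-membership vectors;
5. overlays typed **actions** (activation / inhibition / expression) and
   integrates **fold changes** (signed FC = ±2^|logFC|, max-normalized
   within the up- and down-regulated classes), flagging p ≤ 0.05;
6. reports the **central-node/cluster overlap**: 100·|H∩C|/|H| and
   100·|H∩C|/|C| for hub-bottleneck set H and top complex C.

A synthetic-data module generates all four inputs with known planted
ground truth (dense complexes, connector hubs, enriched terms, up/down
genes), so the whole pipeline is testable offline.

## Worked example

Generate a benchmark dataset (100 genes, one planted 19-member complex at
density 0.9, six designated connector hubs) and run the full pipeline:

```sh
ppinet synth --seed 7 --out-dir data
ppinet run --edge-list data/edges.tsv --gmt data/annotations.gmt \
           --top-table data/top_table.tsv --action-file data/actions.tsv \
           --out-dir results
```

which prints

```
report bundle written to results
centrals_in_cluster1	89%
cluster1_from_centrals	42%
```

and writes one TSV per stage. The network summary shows a single
100-node component with 450 edges above the 0.4 confidence cutoff. The
centrality table starts

```
rank	gene	K	BC
1	G003	44	0.1730
2	G004	43	0.1612
3	G002	42	0.1525
```

— the planted connector hubs (G001–G005, G020) dominate both rankings and
appear among the called hub-bottlenecks. `complexes.tsv` ranks the
recovered complexes:

```
rank	score	size	members
1	17.4444	19	G001,G002,G003,...
2	3.0000	3	G020,G058,G099
```

The rank-1 complex is exactly the planted 19-gene module (score 17.44 =
density 0.918 × 19). Its enrichment against the generated annotation
recovers the three planted terms as one kappa-linked functional group:

```
term	overlap	p_raw	p_holm	direction	group	leading
TERM0002	15	5.93e-14	1.78e-12	enriched	1	yes
TERM0003	14	9.72e-13	2.82e-11	enriched	1	no
TERM0001	12	1.61e-10	4.52e-09	enriched	1	no
```

Finally `overlap_report.tsv` quantifies how central genes concentrate in
the top complex: here 89% of the hub-bottlenecks lie in the rank-1
complex, and 42% of that complex's members are central genes.

Every stage is also available as its own subcommand (`net`, `centrality`,
`mcode`, `enrich`, `express`, `synth`), and as plain library functions:

```python
import ppinet as p

net = p.load_edge_list("data/edges.tsv", score_threshold=0.4)
records = p.centrality_records(net)
hubs = p.select_hub_bottlenecks(records, fraction=0.10)
complexes = p.predict_complexes(net)
print(p.central_overlap_report(hubs.hub_bottlenecks, complexes[0].members))
```

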