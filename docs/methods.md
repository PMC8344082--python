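# Methods

`ppinet` reimplements, as a tested library and CLI, a topology-plus-annotation
analysis workflow for disease-centred protein–protein interaction (PPI)
networks: build a confidence-filtered interaction graph, call hub-bottleneck
genes from degree and betweenness, detect dense protein complexes with an
MCODE-style clustering, characterize the top complex with kappa-grouped
hypergeometric term enrichment, overlay typed regulatory actions, and
integrate differential-expression fold changes. A synthetic-data module
generates all four inputs with known ground truth so every stage can be
validated without live database queries.

## Network model

The network is an undirected simple graph. Nodes are gene symbols, uppercased
and whitespace-stripped on ingest because interaction databases and
expression platforms drift in capitalization. Edges carry a combined
confidence score in [0, 1]; edges are kept only when the score is *strictly*
greater than the threshold (default 0.4, the conventional "medium
confidence" cutoff). Duplicate records for the same pair collapse to one
edge keeping the maximum confidence — conservative and deterministic.
Self-loop rows are dropped with a warning; their endpoint survives as an
isolated node, since an isolated node still counts toward the network's
composition summary.

Connected components are summarized as a size multiset plus the main
(largest) component; a size tie is broken toward the component containing
the lexicographically smallest symbol, purely for determinism.

## Centrality and hub-bottlenecks

Degree K is the incident-edge count. Betweenness centrality BC is
shortest-path (Brandes) betweenness with equal credit split among equal
shortest paths, normalized by (n−1)(n−2)/2 so BC ∈ [0, 1]; n is the node
count of the analyzed graph. Centrality is computed on the main connected
component by default — betweenness across components is identically zero
and would only dilute normalization — with a flag for whole-graph analysis.

Hubs are the top ⌊fraction·n⌋ nodes by K, bottlenecks the top ⌊fraction·n⌋
by BC (fraction default 0.10). Records tied with the boundary value are all
included rather than arbitrarily cut, and the inflation is logged.
Hub-bottlenecks are the intersection, reported in degree-descending order.
Whether the 10% applies to the whole node set or only to the analyzed
component is configurable (`main_component_only`); the selection count
always derives from the records actually passed in.

## Complex detection (MCODE)

The detector follows the three MCODE stages for simple graphs.

*Vertex weighting.* For each vertex v, take the closed neighborhood N[v],
find its highest k-core (the maximal subgraph of minimum degree k with k
maximal), and set weight(v) = k · density(core), where density =
edges / (|V|·(|V|−1)/2). Vertices with graph degree below `degree_cutoff`
(default 2) get weight 0. A member of an isolated s-clique therefore weighs
s−1.

*Complex prediction.* Seeds are unvisited vertices in descending weight
order (ties by name). From a seed, growth proceeds breadth-first over
neighbors whose weight is ≥ seed_weight · (1 − node_score_cutoff)
(`node_score_cutoff` default 0.2), up to `max_depth` levels. Every grown
vertex is marked visited, so complexes are pairwise disjoint.

*Post-processing.* A complex is discarded unless it contains a k-core with
k ≥ `k_core` (default 2). *Haircut* (default on) iteratively removes
members with fewer than two within-complex edges — equivalently, keeps the
2-core. *Fluff* (default off) adds boundary neighbors whose
closed-neighborhood density exceeds `fluff_density_cutoff`; fluffed nodes
may belong to several complexes. Complexes smaller than two members are
dropped.

Complexes are scored density × size, so a clique of size s scores exactly
s, and ranked by score descending, then larger size, then smallest member
symbol. The parameter defaults are the original plugin's published
defaults; all are exposed in configuration.

## Enrichment, Holm correction, kappa grouping

Each annotation term (a flat gene set from a GMT file; no ontology-graph
traversal) is tested against the query set with the hypergeometric
distribution over a gene universe, defaulting to all genes carrying at
least one annotation. The two-sided (enrichment/depletion) p-value doubles
the smaller tail, capped at 1 — the simplest defensible two-sided
convention; single tails are available. P-values are adjusted with the Holm
step-down procedure (equivalently "Bonferroni step-down"), which is
uniformly more powerful than single-step Bonferroni while controlling the
family-wise error rate.

Term similarity is Cohen's kappa between the binary gene-membership vectors
of two terms over the universe. Negative kappas are floored at zero for
grouping decisions (the raw matrix keeps true values). Each term seeds an
initial group of itself plus its highest-kappa partners at kappa ≥ the
threshold (default 0.5), capped at the maximum group size (default 8);
groups sharing at least 50% of the smaller group's members merge
iteratively to a fixpoint; groups below the minimum size (default 2) are
dropped. The min/max levels bound group sizes during kappa grouping, and
the 50% merge rule follows the grouping convention of the kappa-based
enrichment tools this mirrors. With *term fusion* (default on), terms
annotating identical gene sets collapse to the lowest-adjusted-p
representative before grouping. Each group's leading term is its
lowest-adjusted-p member.

## Expression integration and actions

A limma/GEO2R-style top table supplies per-gene log2 fold changes and
p-values (several common column spellings are accepted; for duplicated
symbols the smallest-p probe wins). The signed fold-change convention maps
logFC ≥ 0 to 2^logFC and logFC < 0 to −2^(−logFC), the community
convention for reporting "x-fold down". Fold-change magnitudes are then
max-normalized *within* the up-regulated and down-regulated classes
separately, so each class's extreme maps to exactly 1.0 (a sum-to-one
strategy is available). Significance is flagged at p ≤ 0.05 on the raw
p-value by default, with an adjusted-p option. Genes queried but absent
from the platform are reported as "not identified", never silently dropped.

Typed action edges (activation, inhibition, expression; kappa-style score
in [0, 1]) are validated on load against that closed vocabulary and can be
score-filtered. The central-overlap report gives
100·|H∩C|/|H| and 100·|H∩C|/|C| for the hub-bottleneck set H and complex
C, each rounded to the nearest integer.

## Synthetic data: what it emulates, what it does not

`generate_network` plants dense blocks (size, within-density) in an
Erdős–Rényi background; edge confidences are uniform(0.41, 1.0) so every
generated edge survives the default filter. `generate_annotations` plants
terms oversampling a chosen gene set at a given strength among uniform
background terms. `generate_expression` draws logFC ~ Normal(±mean,
noise_sd) for planted up/down genes and Normal(0, noise_sd) otherwise,
with p-values from the two-sided z-probability and Benjamini–Hochberg
adjusted values, in GEO2R column layout. All generators are pure functions
of their arguments including the single integer seed, and every dataset is
emitted with a ground-truth sidecar.

`generate_benchmark` composes the four inputs at the scale of a typical
disease-gene query: 100 nodes, one planted 19-member complex at density
0.9, background p = 0.03, and six designated connector nodes (five inside
the complex, one outside) wired with ~25 spokes each into the background so
they dominate both the degree and the betweenness rankings. The enriched
terms draw their genes entirely from the planted complex (sizes 8–18):
sibling annotation terms describing one process annotate near-subsets of
its gene set, which is exactly the similarity structure a kappa ≥ 0.5
grouping presumes — terms enriched in the same set but sampled
independently at lower strength would be discarded by the grouping stage
as mutually dissimilar, which is correct behavior but a poor emulation of
curated sibling terms. One complex member is deliberately left off the
expression platform to exercise the "not identified" path. The up/down
effect sizes default to log2 FC 4.51 and 4.11 — the magnitude scale of a
strongly regulated receptor/ligand pair — with noise SD 0.5.

What the benchmark does *not* emulate: the evidence-channel composition of
real confidence scores, scale-free degree structure of whole interactomes,
ontology DAG structure, probe-level microarray noise, or correlated genes.
Passing tests therefore demonstrate algorithmic correctness and end-to-end
recoverability of planted structure at realistic scale, not performance on
any real interactome snapshot.

## Numerical and procedural choices

- Betweenness agrees with a brute-force all-shortest-paths enumeration to
  1e−9 on hundreds of random graphs of ≤ 7 nodes (the oracle enumerates
  every shortest path explicitly).
- Hypergeometric tails agree with exact integer enumeration to 1e−12 over
  every feasible configuration with universe ≤ 30.
- Kappa with exact chance agreement (both membership vectors constant) is
  defined as 1 for identical vectors, else 0.
- All orderings that could be implementation-defined (seed selection,
  group merging, report rows) are tie-broken lexicographically, making
  every pipeline output byte-reproducible for a given config.
- Problem sizes in the validation suite — 200 oracle graphs, 20-replicate
  recovery batches, a 100-node end-to-end benchmark — were chosen to
  exercise each stage at the magnitude of a realistic disease query while
  keeping the whole suite quick to run routinely.

## Known limitations

- Reproducing a specific published network requires the identical database
  snapshot (interaction sets and confidence scores change between
  releases); the package validates against planted synthetic truth instead.
- MCODE here targets simple unweighted graphs; confidence scores filter
  edges but do not weight the clustering itself.
- The enrichment module treats terms as flat gene sets; parent/child
  relations beyond identical-set fusion are out of scope.
- The expression module consumes a precomputed top table; it does not
  re-derive differential expression from raw microarray data.
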