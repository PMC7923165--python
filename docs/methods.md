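# Methods

This note records the statistical and algorithmic choices behind `p2n`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Identity and input model

Proteins are identified by UniProt-style accession throughout; gene
symbols are display-only and never used for joins, because pathway
databases and target tables disagree on symbols far more often than on
accessions. Isoform suffixes (`P16885-2`) are stripped on input by
default (configurable) and logged. A target list is one condition's set
of proteins responding to perturbation of the focal kinase; each entry
carries 1-based phosphosite positions (possibly none), an evidence class
— `phosphosite` (site resolved) or `presence` (identified through
interaction with phosphorylated partners) — and a regulation direction.
Normalization keeps only targets whose phosphorylation *increases* with
active kinase, so conditions assayed with opposite perturbation designs
become comparable; the two evidence classes are treated identically in
all downstream statistics, since both indicate kinase-dependent
involvement. Curated a-posteriori additions (e.g. known direct substrates
missed by the screen) enter through configuration and are flagged
`manual`; similarly, the curated extension of the phospho-tyrosine
modifier list is consumed as a file, never recomputed.

## Enrichment and pathway selection

Over-representation uses the one-sided Fisher exact test, i.e. the
hypergeometric upper tail P(X ≥ k) with universe N, targets-in-universe
K, pathway size n and overlap k (scipy's `hypergeom.sf`). Choices that
were genuinely open:

- **Universe.** All accessions of the *source database* (per-database
  universes when several are loaded). The detected proteome would be an
  alternative background, but it differs per experiment and is usually
  unavailable; the database universe is reproducible and is recorded in
  the output metadata.
- **Sidedness and correction.** One-sided (over-representation), raw
  p-values with α = 0.05. A two-sided variant and Benjamini–Hochberg
  correction are available behind flags; correction is off by default
  because selection feeds a *coverage* step rather than a final claim of
  significance.
- **Enrichment score.** ES = −log₁₀ p; the base is configurable but
  base 10 makes scores readable as orders of magnitude.
- **Selection rule.** Within each source database: keep all significant
  pathways, then walk the remaining pathways by ascending p (ties: larger
  overlap, then lexicographic id) and add any pathway containing a
  still-uncovered target, until no further target can be covered. Greedy
  by ascending p prefers the most statistically supported covering
  pathway; targets in no pathway at all are reported as uncovered rather
  than silently dropped.
- **Clustering.** Bidirectional agglomerative clustering of the dense
  (fill-zero) pathway × condition ES matrix, Euclidean distance, complete
  linkage — the defaults of the common statistical environments — with
  scipy's deterministic observation-order tie-break, so constant matrices
  still yield reproducible trees.

## Network construction

The per-condition network is the union of the selected pathways' member
sets, wired with every database interaction whose two endpoints fall in
that set. Interactions spanning two different selected pathways are
*included* (their provenance may be empty of any single common pathway):
embedding pathways into one network is precisely what creates the shared
signaling core, and excluding cross-pathway edges would sever it.
Cleanup removes self-loops, merges duplicate directed edges (provenance
and source-database sets unioned; an activate-vs-inhibit conflict demotes
the sign to `unknown` and is logged) and drops isolated nodes. The random
baseline draws pseudo-targets uniformly without replacement from the
database universe (sample size defaulting to the mean target-list size
across conditions, which is what "size-matched" means here) and runs the
*identical* enrichment → selection → build pipeline, so any topological
contrast reflects the input lists, not the machinery.

## Topology

Scale-freeness is assessed as the classical network analyzers do: a
least-squares line on (log₁₀ degree, log₁₀ frequency) over the nonzero
histogram bins of the undirected-projection total degree ("node
connectivity"), reported as exponent and R². Maximum-likelihood exponent
estimation is deliberately out of scope — the log-log correlation is the
criterion being reproduced. At least three distinct positive degrees are
required; a regular graph raises a fit-undefined error. Characteristic
path length is the mean directed shortest-path hop count over reachable
ordered pairs (weighted paths belong to propagation, not here);
disconnection is handled by averaging over reachable pairs only, and a
network with no reachable pair reports the length as undefined. Closeness
of the focal node is harmonic — Σ 1/d(v,u) over reachable u, normalized
by n−1 — because the harmonic form stays meaningful on disconnected
directed graphs where the arithmetic mean diverges. Betweenness is
directed and normalized. Because "average path length through a node" is
ambiguous, both readings are computed: the mean distance from the node to
reachable nodes, and the mean d(s,t) over ordered pairs for which the
node lies on at least one shortest path (d(s,v) + d(v,t) = d(s,t)).

## Fusion and rewiring

Alignment is by identity: nodes correspond by accession, edges by their
ordered (source, target) pair with minimal edge properties — sign and
provenance are ignored so that the same interaction imported from two
databases is never counted as a rewiring event. Presence sets (which
input networks contain an element) drive the labels: present in all →
`common`; confined to one configured side or one origin →
`exclusive-to-X`; anything else → `shared-by-subset`. The per-node
rewiring score between two sides is the Jaccard distance of incident
directed edge sets, 1 − |E_a∩E_b|/|E_a∪E_b| ∈ [0,1]: transparent,
symmetric under side swap, 0 for identical incidence and 1 for disjoint
incidence. Hubs can reach high scores through sheer degree, so a
degree-corrected variant (score × √min(|E_a|,|E_b|)) is exposed behind a
flag; the default remains the plain Jaccard distance because ranking, not
absolute magnitude, is the intended use. Nodes with no incident edge on
either side are excluded from the report rather than given an arbitrary
score. Proximal subnetworks are induced subgraphs on seed proteins plus
their in- and out-neighbors, all annotations preserved.

## Propagation

Edge weights under the `random_walk` scheme are w(u→v) = log₂ outdeg(u):
the weight of a path is then exactly the number of bits of surprisal of
the unbiased random walk that follows it, so the minimum-weight path is
the maximum-probability walk, and hub-avoiding detours through forced
(out-degree-1) steps can beat shorter hops through promiscuous hubs —
the desired behaviour when ranking mechanistic hypotheses. Yen's
algorithm (networkx `shortest_simple_paths`) yields loopless paths in
nondecreasing weight; we keep the k best (default 5) plus every path
within ε (default 1.0, i.e. within one bit — a factor 2 of walk
probability) of the optimum. Enumeration continues through the tie class
at the k-th position so that equal-weight alternatives are broken
lexicographically and results are fully deterministic; a 1e-9 tolerance
guards float comparison. Targets that are direct successors of the
source always contribute their one-edge path regardless of weight rank,
mirroring how direct substrates are treated as established rather than
hypothesized. Comparative runs use `all_pathways` mode — one shared
prior-knowledge network built from the whole database for every
condition — because condition-specific networks change target
reachability and would confound the comparison; `enriched_only` mode is
available when per-condition confidence matters more. An optional filter
(`end_at_modifier`, default off) keeps only paths whose penultimate node
is an annotated phospho-tyrosine modifier, a plausibility constraint on
the terminal phosphorylation step that is offered for exploration rather
than imposed. GO-group restriction keeps targets *directly* annotated
with a term of the configured group; annotation propagation up the GO
graph is not performed.

## Synthetic data: what it emulates, and what it does not

The generator provides ground truth for every stage under full
determinism: sub-stream seeds derive from (master seed, purpose label,
index) via BLAKE2, so streams are independent and adding a stage never
perturbs another stage's draws.

- **Interactome:** an undirected Barabási–Albert graph (n = 2000, m = 3
  by default) with each edge given a random orientation (reciprocated
  with probability 0.1) and a sign at ratios 0.45/0.25/0.30
  activate/inhibit/unknown. Preferential attachment was chosen over
  configuration-model sampling because the needed property is the
  scale-free contrast with an Erdős–Rényi baseline, and the generator is
  pluggable. The sign ratios and reciprocation are plausibility dressing;
  no stage's statistics depend on them.
- **Pathways:** 40 randomized breadth-limited snowball samples of 20–60
  nodes, so members always induce a connected subgraph, as curated
  pathways do. Three pathways are planted as enriched; they snowball from
  a designated focal node — the highest-degree hub — so they overlap
  around its signaling core, emulating the fact that one kinase's
  target-enriched pathways genuinely share components (the published
  B-cell-receptor and actin tables share NRAS, RAC1, MAPK1/3). This also
  provides the focal source node the propagation stage requires.
- **Targets:** 150 per condition; each drawn from the enriched-pathway
  member union with probability p_in = 0.7, otherwise uniformly from the
  universe. Condition-indexed sub-seeds make conditions differ under one
  master seed.
- **Rewired pairs:** the second network of a pair is a copy in which, for
  each of 10 planted nodes, half (ρ = 0.5) of the incident edges are
  deleted and replaced by edges to uniformly chosen new endpoints (no
  self-loops or duplicates); nodes too small to rewire at least one edge
  are skipped with a warning.

The generator does **not** emulate mass-spectrometry noise, protein
abundance, annotation incompleteness of real databases (every synthetic
protein is in the interactome, whereas most of UniProt is in no curated
pathway), or correlated false positives between conditions. Passing the
recovery tests therefore shows that the pipeline's statistics recover
planted structure under clean sampling assumptions — not that real
phosphoproteomic lists are free of the biases those assumptions exclude.

## Evaluation protocol and problem sizes

The acceptance checks exercise: exact-test agreement with
rational-arithmetic tail enumeration (1000 random tables, N ≤ 60, within
1e-10 relative error); path-extraction agreement with exhaustive
simple-path enumeration (200 digraphs, ≤ 10 nodes); topology-metric
agreement with hand-rolled BFS/path-counting (200 digraphs, ≤ 12 nodes);
planted-enrichment recovery (the 3 planted pathways in the top 5 by p,
20 seeds); planted-rewiring recovery (planted nodes' mean rank in the
top 5%, 1000-node networks, 20 seeds); and the scale-free / small-world
contrast, where per-seed condition metrics are the mean over the three
generated condition networks compared against the one random-baseline
network — the same design as a multi-condition study. These sizes are
the package's reference protocol and keep a full run to a few minutes on
one CPU.

## Known limitations

- The rewiring score is a transparent Jaccard distance; plugin
  implementations in interactive network tools may use different
  statistics, so rankings — not numeric values — are the comparable
  output.
- Selection uses raw p-values by default; with many pathways and small
  lists the coverage step can admit weakly supported pathways (visible in
  `selected_reason`).
- Identity alignment cannot relate paralogs or account for topology-only
  correspondence; a node absent from one database simply counts as
  absent.
- The worked-example fixtures are the published per-pathway excerpts, not
  complete experimental target lists; quantities that depend on the full
  lists (e.g. whole-list intersections) cannot be reproduced from the
  packaged data alone.
- GAF parsing uses direct annotations only; no ontology-graph closure.
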