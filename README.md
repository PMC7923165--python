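# p2n — comparative signaling-network analysis from phosphoproteomic target lists

`p2n` reconstructs and compares kinase signaling networks from
phosphoproteomic perturbation experiments. The motivating use case is a
kinase such as SYK (spleen tyrosine kinase, UniProt P43405) that acts as a
tumor suppressor in breast epithelial cells but as a tumor promoter in
B-cell lymphoma: given per-condition lists of proteins whose tyrosine
phosphorylation responds to perturbing the kinase, the package asks *which
signaling pathways those targets concentrate in, how the resulting
prior-knowledge networks differ between conditions, and along which routes
the signal most plausibly travels from the kinase to each target.*

It is a library first (with a thin `p2n` command-line interface) aimed at
computational biologists working with target lists (TSV), pathway databases
exported as GMT membership plus SIF interactions, and GO annotations (GAF).

## What it computes

1. **Pathway over-representation.** For each pathway, the one-sided Fisher
   exact test on the 2×2 table (universe *N*, targets-in-universe *K*,
   pathway size *n*, overlap *k*): *p* = P(X ≥ k), X ~ Hypergeom(N, K, n),
   with enrichment score ES = −log₁₀ *p*. Pathway selection keeps every
   significant pathway (raw *p* < α, default 0.05) and then adds, greedily
   by ascending *p*, pathways needed to *cover* targets that no significant
   pathway contains. Differential enrichment sorts pathways by mean ES
   across conditions and reports per-condition deviations; a bidirectional
   hierarchical clustering (Euclidean, complete linkage) groups pathways
   and conditions.
2. **Network construction.** The selected pathways are embedded into one
   directed prior-knowledge network per condition: nodes are the pathway
   members, edges every database interaction between them (cross-pathway
   edges included), with self-loops removed, duplicate edges merged
   (provenance unioned, conflicting signs demoted to `unknown`) and
   isolated nodes dropped. A random baseline runs the identical pipeline on
   uniformly sampled pseudo-targets.
3. **Topology diagnostics.** Log-log degree-histogram power-law fit
   (exponent and R², the classical scale-free criterion), mean clustering
   coefficient, characteristic path length and its distribution, and
   focal-kinase metrics (degrees, neighborhood connectivity, harmonic
   closeness, betweenness, mean path length from/through the node).
4. **Fusion and rewiring.** Condition networks are aligned by identity
   (nodes by accession, edges by ordered endpoint pair); every element is
   labeled common / exclusive / shared-by-subset from its presence set, and
   each node gets a rewiring score between two sides of the comparison —
   the Jaccard distance 1 − |E_a∩E_b|/|E_a∪E_b| of its incident edge sets.
   First-neighbor (proximal) subnetworks slice the fusion around proteins
   of interest.
5. **Signal propagation.** Over one shared prior-knowledge network, edges
   are weighted w(u→v) = log₂ outdeg(u), so a path's weight is −log₂ of
   the probability that an unbiased random walk follows it; Yen's
   algorithm returns the k best loopless paths from the kinase to each
   target plus every *near-shortest* path within ε of the optimum
   (defaults k = 5, ε = 1 bit). Path unions are labeled per condition, and
   target sets can be restricted to GO term groups (e.g. cell adhesion and
   motility).

A `synthetic_data` module generates ground-truth-bearing inputs — a
scale-free directed interactome, overlapping snowball pathways, target
lists with planted enrichment, and condition pairs with planted rewiring —
so every stage is testable without downloads.

## Worked example

The packaged fixtures encode the published per-pathway target tables for
SYK in MCF7/MDA-MB-231 breast cancer and DG75 Burkitt lymphoma cells:

```python
from p2n import datasets as fx
from p2n.enrichment import pathway_target_table

targets = fx.load_example_targets()
db = fx.load_example_db()
table = pathway_target_table(
    fx.BCR_PATHWAY, [targets[c] for c in fx.CONDITIONS], db
)
print(table.head(8).to_string(index=False))
```

```
symbol accession MCF7 MDA231  DG75
   BTK    Q06187             551 *
 CD79A    P11912               210
  GRB2    P62993    X             
INPPL1    O15357    X         1135
 MAPK1    P28482    X          187
 MAPK3    P27361               204
NFATC2    Q13469               752
NFKBIE    O00221         155   155
```

BTK appears only in the lymphoma dataset, phosphorylated at Y551 with the
`*` marking a residue the kinase can phosphorylate directly; an `X` means
the protein was identified by interaction with phosphorylated partners
(presence evidence, no site).

End-to-end on synthetic data with planted ground truth:

```python
from p2n import (fisher_enrichment, select_pathways, build_network,
                 gen_interactome, gen_pathway_db, gen_target_lists,
                 global_topology, SyntheticSpec)

spec = SyntheticSpec(seed=1)
net = gen_interactome(spec)                  # 2000-node scale-free interactome
db, truth = gen_pathway_db(net, spec)        # 40 pathways, 3 planted enriched
ds = gen_target_lists(db, truth, spec, n_conditions=1)[0]   # 150 targets
for r in fisher_enrichment(ds, db)[:3]:
    print(r.pathway_id, f"k={r.k}/n={r.n}", f"p={r.p:.3g}",
          r.pathway_id in truth.enriched)
```

```
sim:PW009 k=41/n=45 p=3.24e-44 True
sim:PW024 k=24/n=27 p=3.99e-25 True
sim:PW035 k=24/n=27 p=3.99e-25 True
```

The three planted pathways head the ranking. Selecting pathways and
building the network (`select_pathways` → `build_network`) yields, for
this seed, a 699-node / 1840-edge network with mean clustering 0.054,
characteristic path length 4.81 and degree power-law R² 0.854 — the
hub-rich, short-path structure expected of a signaling network and absent
from the size-matched random baseline.

The same workflow is scriptable end to end:

```sh
p2n simulate --seed 1 --out-dir sim/     # targets TSV + GMT + SIF + truth
p2n run --config cfg.yaml                # normalize → enrich → build →
                                         # topology → fuse → propagate
```

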