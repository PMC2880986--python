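# wgdnet

Tools for asking how a plant metabolic network copes with whole-genome
duplication (WGD): do the enzymes that matter most topologically — *hubs*
(high in/out-degree) and *bottlenecks* (high betweenness) — preferentially
keep both copies of their encoding genes (homeologs) after the duplication,
and do retained enzymes cluster on consecutive pathway steps?

The package is aimed at comparative genomicists and systems biologists who
have (a) an enzyme→gene table, (b) a reaction list with directionality,
(c) an expression matrix, and (d) homeolog/ortholog/substitution-rate
tables, and want the whole chain — network reconstruction, centralities,
modularity, expression and rate correlations, and the retention statistics —
as tested, scriptable pieces. A synthetic-data generator emulates all four
inputs, so every stage runs and is tested without any database download.

## The model and statistics

**Network.** Enzymes are nodes. A directed edge A→B exists when a product
metabolite of a reaction catalyzed by A is a substrate of a reaction
catalyzed by B; 14 ubiquitous currency metabolites (ATP, NADH, CO₂, …) are
removed first. When a single reversible reaction shared by two enzymes lets
the same metabolite act as substrate and product of the same enzyme, the
pair is stored once as a *bidirectional* edge.

**Centralities.** In-degree and out-degree count distinct neighbor enzymes.
Betweenness comes in two variants: the breadth-first-tree accumulation
(every tree vertex starts at 1; scores propagate to predecessors split by
shortest-path counts P(k)/P(j); endpoint mass included) and the standard
pair-dependency form B(v) = Σ_{s≠v≠t} σ_st(v)/σ_st, with a brute-force
enumeration oracle for verification.

**Modularity.** Simulated annealing maximizes Newman modularity
Q = Σ_s [l_s/L − (d_s/2L)²] on the undirected projection (iteration factor
1.0, cooling factor 0.95), with degree-preserving rewirings for a null Q.

**Retention statistics.** An enzyme is a *WGD-enzyme* when at least one
pair of its encoding genes is a retained homeolog pair. The package
compares centralities between WGD- and non-WGD enzymes (Mann–Whitney U,
exact for small groups), counts interactions whose both endpoints are
WGD-enzymes (IBWE), and tests that count against the permutation null of
uniformly placed labels — whose exact mean is E·m(m−1)/(n(n−1)) — reporting
z = (observed − mean)/sd. A second simulation draws the IBWE *excess* m,
samples m edges, and records how many enzymes f they touch, attributing
retention to enzyme–enzyme interaction. 2×2 contingency tests (Pearson,
Yates, Fisher) cover phylogenetic age and cross-species conservation of
IBWE. Expression summaries are the per-gene maximum intensity and the
variation (tissue-specificity) index V = Σ_j (1 − S′_ij/S′_max)/(n−1) with
a floor of 50; Kimura two-parameter distances handle noncoding flank
divergence; Spearman correlations with FDR control tie centralities to
expression and rates.

## Worked example

```python
from wgdnet import SyntheticConfig, label_permutation_test, ibwe_count
from wgdnet.synthetic_data import generate_bundle

bundle = generate_bundle(SyntheticConfig(seed=42))
net, labels = bundle.network, bundle.labels
print(f"enzymes: {net.n_enzymes}, directional: {net.directional_count}, "
      f"bidirectional: {net.bidirectional_count}")
print(f"WGD-enzymes: {len(labels.labeled_enzymes)}, IBWE: {ibwe_count(net, labels)}")
null = label_permutation_test(net, labels, n_reps=10000, seed=1)
print(f"null: N({null.null_mean:.1f}, {null.null_sd:.1f}), "
      f"z = {null.z_score:.2f}, empirical p = {null.p_empirical:.2e}")
```

prints

```
enzymes: 478, directional: 1015, bidirectional: 379
WGD-enzymes: 173, IBWE: 370
null: N(181.9, 19.1), z = 9.86, empirical p = 1.00e-04
```

The synthetic network has 478 enzymes and 1394 interactions with 173
labeled WGD-enzymes. Placing 173 labels uniformly at random induces about
182 label–label interactions (the closed form gives 181.9); the generator
plants labels with hub and pair bias, so the observed 370 IBWE sit far in
the upper tail (z ≈ 9.9) — the planted "consecutive steps" signal is
recovered. The same pipeline runs on real tables via the CLI:

```sh
wgdnet simulate --seed 42 --outdir bundle/        # or bring your own files
wgdnet build-net  --reactions bundle/reactions.lst --genes bundle/enzyme_genes.tsv --out edges.tsv
wgdnet centrality --reactions bundle/reactions.lst --genes bundle/enzyme_genes.tsv --out centrality.tsv
wgdnet wgd-test   --reactions bundle/reactions.lst --genes bundle/enzyme_genes.tsv \
                  --pairs bundle/wgd_pairs.tsv --out wgd.json --seed 1
```

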