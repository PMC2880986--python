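# Methods

This note documents the models, numerical choices and known limitations of
wgdnet, in the order the pipeline runs.

## Network reconstruction

Reactions arrive in the `reaction_mapformula.lst` dialect
(`RID: PATHWAY: M1 + M2 <dir> M3`, with `=>`, `<=`, `<=>`). Reverse lines
are normalized to forward by swapping sides before storage, so downstream
code only ever sees `forward` and `reversible`. Duplicate
(reaction, pathway) lines are dropped at parse time; the same reaction
appearing under several pathways is kept once per pathway so pathway
provenance survives to the module-composition summary. Identifier
comparison is case-sensitive after whitespace trimming.

**Currency filter.** Fourteen ubiquitous metabolites are removed from both
sides of every reaction before edges are derived: H+, NADH, NADP, NADPH,
NH3, ATP, ADP, AMP, NAD, CoA, O2, CO2, glutamate and pyrophosphate.
Because reaction files name compounds by identifier while the list above is
common names, the filter ships as a name→KEGG-compound table
(`CURRENCY_NAME_TO_KEGG`) and the default filter is the 14 KEGG ids; both
the set and the table are overridable. "Glu" is mapped to L-glutamate
(C00025): its currency role is amine-group carrier. "Pyrophosphate" is
diphosphate (C00013). A record whose substrate or product side becomes
empty under filtering is retained but flagged and yields no interactions.

**Edge derivation.** For every metabolite, each (enzyme, reaction) pair
producing it is linked to each pair consuming it; reversible reactions act
in both orientations; self-loops are dropped. Bidirectionality is
deliberately narrow: a pair of enzymes is stored with one *bidirectional*
edge only when both catalyze the same reversible reaction, i.e. the same
metabolite serves as substrate and product of the same enzyme through a
single reaction. Opposite directed links that arise from two *different*
reversible reactions remain two directional edges. Degrees count distinct
neighbor enzymes, not metabolite channels, and a bidirectional edge
contributes to the in- and out-degree of both endpoints.

## Betweenness

Two variants ship because they answer different needs:

* `betweenness_bfs_tree` — the breadth-first-tree accumulation: per source
  tree, every vertex starts with score 1; processing bottom-up, a vertex's
  score is added to its predecessors split proportionally to shortest-path
  counts P(k)/P(j); B(j) sums the accumulated score at j over all source
  trees. Endpoint mass is included by construction. This is the variant to
  use when reproducing analyses built on the leaf-initialized algorithm.
* `betweenness_standard` — ordinary pair-dependency betweenness
  (endpoints excluded), used for new analyses and cross-checked exactly
  against a brute-force path-enumeration oracle on small graphs.

A worked consequence of leaf initialization worth knowing: on the directed
path A→B→C the totals are A=3, B=4, C=3 — the *interior* vertex scores
highest overall because it appears in two source trees, while within any
single tree the root holds the largest accumulated mass. The two variants
usually rank nodes similarly on connected graphs; the test suite records
ranking agreement as a diagnostic, not a guarantee. All edges have unit
length; ties among shortest paths are always handled by path counting,
never by predecessor choice.

## Degree distributions and modularity

Power-law exponents are estimated by OLS on log-transformed (k, p(k))
pairs with k ≥ 1 and p(k) > 0 (≥3 points required); the exponent is
reported positive for decaying distributions, and the fit has zero residual
on data generated exactly from the model.

Modularity is maximized by simulated annealing on the undirected simple
projection (directions and edge kinds collapsed, reciprocal pairs merged):
per temperature, `iteration_factor·n²` single-node moves and
`iteration_factor·n` collective moves (merge of two random modules, or a
random bipartition split) are proposed and accepted by the Metropolis rule;
defaults are iteration factor 1.0 and cooling factor 0.95. Schedule
details not fixed by the cited method are exposed as parameters and default
to: initial temperature 1/(2L), stop after 3 consecutive temperatures with
no accepted move, at most 250 temperature steps; the best partition seen is
returned. Runs are bit-reproducible given a seed. Disconnected inputs are
partitioned per component with a warning, and Q reported for the combined
partition. For significance context, `n_randomizations` degree-preserving
rewirings (double edge swaps) are scored with a fast greedy modularity
search; this null is a cheaper surrogate than re-annealing each rewiring
and is reported as mean/sd only. The number of modules is an outcome, not
a parameter. On exhaustively enumerable benchmarks (≤8 nodes) the annealer
attains the global optimum, and it recovers the planted partition of a
ring of four triangles as the modal result across seeds. Full-size
networks (hundreds of nodes) take minutes at iteration factor 1.0; reduce
the factor for exploratory runs.

Pathway composition replaces enrichment annotation: each enzyme counts
toward every pathway of every reaction it catalyzes, unassigned enzymes
under `"unassigned"`, majority pathway flagged per module.

## Expression

The variation index is V = Σ_j (1 − S′_ij/S′_(i,max)) / (n − 1) with
S′ = max(S, floor) and floor 50 intensity units; V is 0 for constant
floored profiles and →1 for single-condition expression. Several variants
of such specificity indices circulate (n vs n−1 denominators in
particular); the adopted form is the standard tissue-specificity index,
which satisfies the required properties (range [0, 1], higher = more
stage-specific). No downstream result here depends on the n vs n−1 choice. Replicates are averaged on load via a
design table. Enzyme summaries are arithmetic means over the enzyme's
measured genes (the divisor is the gene count). Co-expression is plain
Pearson correlation (n ≥ 3, NaN with a warning on zero variance).

Rank correlations use Spearman with average-rank ties and two-sided p;
pairs with n < 5 are excluded with a warning. FDR control defaults to
Benjamini–Hochberg because it is deterministic; Storey's q-value (plug-in
π₀ at λ = 0.5) is available via `method="storey"` for comparability with
q-value-based workflows.

The concerted-divergence screen reports interacting enzyme pairs where each
endpoint has a measured homeolog pair with within-pair correlation below
`theta_within` (default 0.0) and the paralogs can be matched across the
edge with both cross correlations above `theta_cross` (default 0.5); both
thresholds are exposed.

## Evolutionary rates

Ka is consumed from input tables, never computed: codon-model ML estimation
is a solved problem elsewhere and outside this package's scope. For
noncoding flanks the Kimura two-parameter distance
d = −½ln(1−2P−Q) − ¼ln(1−2Q) is computed over aligned columns after
dropping gaps and ambiguity codes in either sequence; saturation
(non-positive log argument) raises a dedicated error. Alignment itself is
out of scope — a trivial equal-length pairing helper exists for tests.
With several orthologs per gene, the componentwise minimum over candidates
is taken per rate, missing components ignored. Enzyme-level rates are
arithmetic means over rated genes with per-rate n. Phylogenetic age is a
set-membership flag: ≥1 encoding gene in any ortholog group spanning the
native species and another.

## Retention statistics

Mann–Whitney comparisons use the tie-corrected normal approximation, with
an exact path (full enumeration of label splits, midrank U, two-sided p as
the fraction of splits at least as extreme) when both groups have ≤8
members; the exact path matches independent exact enumeration on tie-free
data and returns p = 1 for identical groups.

The label-permutation test draws m nodes uniformly without replacement per
replicate and counts edges with both endpoints drawn (each stored edge once,
directional or bidirectional). By default the node universe — and the
observed count — is the largest connected component, i.e. the analysis
network; the full enzyme set is one flag away. The analytic oracle for the
null mean is E·m(m−1)/(n(n−1)), exact on any graph without self-loops. Two
p-values are reported: the normal-fit tail (for comparability with
z-score-based reports) and the empirical
(1 + #{sample ≥ observed})/(1 + n_reps), which is authoritative in tests
because the normal fit is an approximation. The replicate default is 10000
(configurable; such simulations are commonly run with anywhere from 1000 to
10000 replicates). An all-nodes-labeled call has sd = 0 and is flagged
degenerate rather than given a z. The z computation takes mean and sd as
explicit arguments so that z-scores quoted from rounded summaries — e.g.
(255−183)/22 = 3.27 against a null summarized as N(182, 22) — can be
reproduced verbatim.

The edge-sampling attribution draws m ~ Normal(excess_mean, excess_sd) per
replicate, rounds to the nearest integer, clips to [0, E] (clipping the
negative normal tail at 0 is this package's choice — the procedure is
otherwise silent on it), samples m distinct edges uniformly and records the
number of distinct endpoint enzymes f; every replicate satisfies
0 ≤ f ≤ 2m, and the mean matches exhaustive subset enumeration on small
graphs.

Contingency tests expose Pearson (default, no continuity correction),
Yates and Fisher variants. The variants can disagree noticeably on a given
table — for the phylogenetic-age table [[162, 11], [281, 24]] they give
p ≈ 0.54 (Pearson), 0.67 (Yates) and 0.59 (Fisher) — so tests assert only
significance or non-significance, never a variant-specific value. The cross-species test counts an interaction as
foreign-connected when both endpoints have ≥1 ortholog enzyme labeled in
the foreign species, builds [[a, |IBWE|−a], [T−a, E−|IBWE|−T+a]] and tests
it; an empty foreign-connected set raises rather than returning a
degenerate table.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the analysis conditions: 478 enzymes, 1394
interactions of which 379 bidirectional, 173 labeled enzymes (fraction
173/478), 59 expression conditions, intensity floor 50, degree exponent
1.67. Out-degrees are drawn from a truncated discrete power law (cutoff 20,
chosen so the mean sits near the empirical ~2.9 links per enzyme at the
default exponent) and nudged by single units on uniformly chosen nodes to
hit the edge target exactly; targets are assigned by preferential
attachment on in-degree with strength 1.0; cycle edges are re-targeted
until the projection is connected, so the analysis component is the whole
network. Reactions and a 1–3-genes-per-enzyme map are synthesized so the
text pipeline (serialize → parse → filter → build) reconstructs the network
exactly, with currency metabolites sprinkled into ~30% of reactions to
exercise the filter.

Labels are planted with a logistic hub bias (slope 1.0 per sd of total
degree) and a per-edge pair bias (default 0.3) that forces both endpoints
of sampled edges to be labeled until the budget is met; ground truth is
recorded. Only enzymes with ≥2 annotated genes are eligible — a WGD-enzyme
needs a retained homeolog *pair* — so a label fraction of 1.0 requires a
configuration whose enzymes all carry ≥2 genes. Expression is log-normal
with the log-mean shifted by 0.4 per sd of enzyme degree (hub genes
expressed higher); rates decrease linearly with degree (slope −0.01 per
link) with Gaussian noise, floored at 0. Hub-bias, pair-bias and slope
values are not published quantities; they were fixed once at levels that
give the qualitative structure the analysis assumes (clear but not
overwhelming enrichment) and are fully configurable. The foreign species
is a mirrored copy with per-enzyme label conservation 0.9 and background
labeling 0.05.

Every stage derives its RNG stream from the single seed via a fixed
spawn-key scheme, so stages can be regenerated independently and the whole
bundle is bit-reproducible. What the generator does *not* emulate:
stoichiometric feasibility, realistic pathway semantics (pathway ids are
random tags), correlated expression across conditions, tandem-duplication
structure, or gene sharing between enzymes. Passing tests therefore show
that the statistics recover planted structure of the assumed form — not
that real AraCyc/KEGG-era tables would yield any particular count; the
published dataset-dependent tallies (496/478 enzymes, 1785 interactions,
11 modules, 173/255 labels, specific correlation values) are properties of
2008-era databases and are deliberately not acceptance constraints here.

## Problem sizes used in tests and the acceptance script

The acceptance script runs the permutation test at the full analysis scale
(478 nodes, 1394 edges, 173 labels, 10000 replicates; < 1 s). Property
tests run at the sizes their oracles allow: brute-force betweenness on
≤10-node digraphs, exhaustive modularity on ≤8 nodes, exact Mann–Whitney
on splits of 8, type-I calibration with 999-replicate tests on a 60-node
network over 1000 null seeds, and planted-recovery sweeps of 100 seeds at
150–478 nodes. The full suite runs in about half a minute on one CPU.
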