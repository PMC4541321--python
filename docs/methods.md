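# Methods

## The model

`drwgm` scores the topological importance of genes in metabolic pathways by
a **directed random walk with restart** on a merged gene–metabolite graph,
and uses those scores to build **pathway activity** features for two-class
sample classification.

### Graph construction

Each metabolic pathway is a set of reactions. A reaction contributes a
directed bipartite motif: every substrate compound points at every gene
implementing the catalyzing enzyme, and every such gene points at every
product compound. Reversible reactions contribute both directions. Enzymes
mapping to several genes yield one gene node per gene, each inheriting the
enzyme's full connectivity. Per-pathway graphs are merged into one global
graph in which every identifier appears once; shared compounds and genes
therefore couple pathways.

Two post-processing steps precede the walk:

1. **Edge reversal.** All edges are flipped so that walk mass flows toward
   *upstream* nodes. Upstream genes influence everything downstream of them
   and carry less accumulated expression noise, so they deserve more
   topological weight.
2. **Ground node.** An auxiliary node is linked bidirectionally to every
   node. This makes the graph strongly connected, guarantees every row of
   the transition matrix is stochastic, and ensures the walk converges.

The transition matrix is the row-normalized adjacency matrix:
`M[i, j] = 1/outdeg(i)` for each edge `i -> j`. A gene-only variant graph
(metabolites contracted out: `g1 -> g2` iff a product of a reaction of `g1`
is a substrate of a reaction of `g2`) supports the gene-expression-only
baseline walk.

### Initial weights

With two phenotypes A and B (t statistics oriented B − A, phenotypes sorted
lexicographically):

- gene `g`: `WG[g] = -log p_g` from a two-tailed two-sample t-test on
  z-normalized expression, then min–max rescaled to `[0, 1]` over the
  measured genes (`WG'`). The log base is irrelevant after rescaling.
- metabolite `m`: weight 1 if its two-sided Wilcoxon rank-sum p-value is
  below `met_alpha` (default 0.01), else 0. The hard cutoff (rather than a
  graded −log p weight, available as `metabolite_weighting="pvalue"`)
  concentrates influence on clearly differential compounds, which matters
  because metabolomic measurements are environmentally volatile.
- the ground node: 0.

The concatenated vector is L1-normalized to give `W0`. Variants: the full
method (`drw-gm`) uses both blocks; `drw-gm-nm` walks the same
gene–metabolite graph but zeroes the metabolite weights; `drw` walks the
gene-only graph. Genes or metabolites present in the graph but not measured
start at 0 (they still accumulate mass through neighbours); measured
features absent from the graph are ignored.

We combine the *rescaled* gene vector `WG'`, not the raw `WG`, with the
metabolite block: the rescaling step exists precisely to put the two blocks
on a common `[0, 1]` scale before concatenation.

### The walk

```
W_{t+1} = (1 - r) * M^T W_t + r * W0
```

with restart probability `r = 0.7` (the value used by the gene-only
predecessor of this method; exposed as a parameter), iterated until the L1
change between consecutive iterates falls below `1e-10` (`max_iter` 10000
as a safety guard). Because `W0` is a probability vector and `M` is
row-stochastic, every iterate sums to 1. The transposed form is the one
under which `W_t[i]` is the probability of being at node `i` at step `t`.
The stationary vector also solves the linear system
`(I − (1−r) M^T) x = r W0`; the package ships both solvers and the test
suite uses the direct solve as an independent oracle for the power
iteration.

### Pathway activity

For pathway `P_j`, the member genes with training t-test `p < 0.05` (n_j of
them) form the activity model. For a sample with z-scores `z`:

```
a(P_j) = sum_i Winf(g_i) * sgn(t(g_i)) * z(g_i)  /  sqrt(sum_i Winf(g_i)^2)
```

The root-sum-of-squares denominator was chosen so that (i) a single-gene
pathway reduces exactly to `±z`, (ii) the activity is invariant to scaling
all walk weights by a positive constant, and (iii) it matches the `1/sqrt(k)`
normalization family of the condition-responsive-genes (CORG) approach with
weights inserted. On a test cohort the model is frozen — walk weights *and*
training t-signs — and applied to z-scores computed over the *test* samples;
model genes missing from the test platform are dropped and the denominator
recomputed over the survivors, so cross-platform evaluation degrades
gracefully rather than failing.

A cohort with fewer than `min_diff_genes` differential genes (p < 0.05)
across the whole graph is treated as not discriminative and classifier
construction aborts. The default threshold of 50 presumes genome-wide
profiling; the synthetic benchmarks, which measure 80 genes, use scaled
thresholds (10 for the strong benchmark, 3 for the moderate one), fixed as
part of the benchmark definitions.

Baselines: per-sample **mean** or **median** of all member-gene z-scores
(no p filter), and a **PAC-style CORG** greedy search that seeds with the
highest-|t| member gene and keeps adding genes in |t| order while the |t| of
the sign-aligned `1/sqrt(k)`-averaged profile strictly increases.

## Evaluation protocols

Features are pathway activities; the classifier is logistic regression
(maximum likelihood with a vestigial ridge of 1e-6 — i.e. scikit-learn's
`C = 1e6` — so separable activity matrices still have a finite optimum).
AUC is the rank-based Mann–Whitney statistic with midrank ties.

**Greedy feature selection.** Rank features by the p-value of a t-test of
their activity on the *feature evaluation* set; the top feature always
enters (an empty model has no AUC to improve on); each subsequent feature is
kept iff the AUC of the refit classifier strictly increases on the disjoint
*feature selection* set.

**Within-dataset.** Per repeat: a stratified 5-fold partition; each fold in
turn is the held-out test set and everything — z-normalization parameters
excepted (z is per-cohort by definition), differential tests, the walk,
activity models, feature selection — is fitted on the remaining four folds.
Three random stratified 2/3–1/3 splits of the training samples drive the
greedy search; each optimized classifier is scored on the held-out fold.
15 AUCs per repeat, 1500 over the default 100 repeats. The metabolite
cohort is a fixed side input (profiled on its own samples) and is never
split. Splits are stratified to avoid single-class folds on small cohorts.
A training fold that yields no usable pathway model scores chance (0.5) for
its three classifiers with a warning — relevant only for null data.

**Cross-dataset.** The walk and the models come from the full training
cohort. Per repeat: a stratified 5-subset partition of the training cohort;
each subset in turn is the feature-selection set, the other four the
feature-evaluation set; the optimized classifier is scored on the full
independent test cohort (test-side z-normalization). 5 AUCs per repeat, 500
over 100 repeats.

**Cscore.** Rank shared pathways by training |t| descending;
`Cscore(N) = mean over the top N of t_train * t_test`. Large positive values
mean the discriminative pathways keep both their strength and their
direction in the independent cohort.

Determinism: a master seed spawns per-repeat integer streams
(`numpy.random.SeedSequence`), so every report is bit-for-bit reproducible.

## Synthetic data

The generator emulates the structure the method exploits; its defaults are
the study conditions of the test suite and acceptance benchmarks.

- **Topology.** Each pathway is a chain of reactions
  `c_k -> gene -> c_{k+1}` with one peripheral gene per reaction; hub
  enzymes (default `hub_fraction = 0.15`, at least one per pathway)
  additionally catalyze every reaction of the chain, giving them high
  degree. Every third reaction is reversible. Topology is deterministic
  given the counts, so specs differing only in seed share one graph and
  yield independent cohorts for cross-dataset runs.
- **Expression.** Gaussian per-gene noise; hub genes are low-variance
  (sd 0.5) versus peripheral genes (sd 1.0), reflecting that hub-gene
  expression varies less. In risk pathways, hub genes and half of the
  peripheral genes are shifted in phenotype B by a *standardized* effect
  (units of the gene's own sd), so "equally significant" planted hub and
  peripheral genes differ only in topology. Default 30 + 30 samples.
- **Metabolites.** Log-normal abundances (log-sd 0.5); in risk pathways a
  fraction (default 0.3) of compounds gets a 1.0 log-unit shift — about two
  log-sds, comfortably rank-sum-detectable — in phenotype B. The metabolite
  cohort has its own samples.
- **Benchmarks.** The *strong* benchmark (10 pathways, 3 risk, effect
  1.5 sd) is used for recovery checks: hub promotion in `Winf`,
  classification above 0.9 AUC and above the Mean/Median baselines, risk
  pathways in the top selection-frequency quartile, and higher Cscore than
  the Mean baseline between independent cohorts. The *moderate* benchmark
  (hub 1.0 sd, peripheral 0.5 sd, half the risk metabolites shifted) keeps
  AUC off the ceiling for comparing the three walk variants; their ordering
  (full method ≥ no-metabolite-weights ≥ gene-only graph) is asserted as a
  non-strict trend across 20 seeds within two paired standard errors, since
  the variant differences are small relative to simulation noise at this
  scale.

What the generator does **not** emulate: microarray platform and batch
effects, correlated gene noise within pathways, metabolite–gene
concentration coupling, realistic pathway sizes (tens to hundreds of genes)
or genome-wide gene counts. Passing tests therefore demonstrate the
machinery and its no-leakage property, the walk's hub/upstream promotion,
and the qualitative orderings — not effect sizes transferable to real
cohorts.

## Numerical choices and edge cases

- t-tests: pooled-variance Student t by default (Welch by option), oriented
  B − A. Degenerate all-equal rows report t = 0, p = 1.
- Rank-sum tests: exact null when both groups ≤ 25 and the row is tie-free;
  otherwise normal approximation with continuity correction.
- z-normalization: sample sd (n − 1); zero-variance features become
  all-zero rows with a logged warning rather than an exception.
- All gene p-values equal (min–max rescale undefined): all measured genes
  get weight 1 before normalization, with a warning.
- Ranking ties (node weights, feature p-values): broken lexicographically
  by identifier, so every ordering is deterministic.
- Sparse matrices throughout the walk; results match the dense definition
  to the solver tolerance.
- Accuracy is reported at probability threshold 0.5 alongside AUC.

## Known limitations

- Two-phenotype designs only; multiclass problems must be decomposed
  externally.
- Metabolic pathways only: the construction needs reactions with
  substrates and products, so signalling pathways are out of scope.
- The activity normalization denominator and the strict-increase greedy
  rules are the package's own concrete choices within the method family;
  alternatives (e.g. capping the CORG size) would change baselines
  slightly.
- Currency metabolites (ATP, H2O...) are not filtered by default; heavy
  currency coupling between pathways can distort the walk, and
  `exclude_compounds` exists for that case.
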