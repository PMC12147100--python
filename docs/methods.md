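# Methods

## Overview

`sceve` clusters a genes × cells count matrix recursively. One recursion on
a pool of cells runs four stages: (1) select k highly variable genes (HVGs)
on the pool's own counts; (2) run every base clusterer on the HVG-restricted,
normalized pool; (3) combine the partitions through the similarity graph
into robust clusters plus a leftover; (4) keep only robust clusters that are
marker-characterized, or abandon the split. Accepted clusters (and the
leftover) are themselves recursed until a pool is too small (< `min_cells`),
the ensemble cannot agree strongly enough, or no proposed cluster is
biologically distinct.

## Consensus model and its assumptions

The pairwise similarity `S(x,y) = min(|x∩y|/|x|, |x∩y|/|y|)` is computed by
direct set intersection. (The same quantity can be obtained as the smaller
of the two association-rule confidences conf(x→y), conf(y→x) from a
frequent-itemset miner; direct counting is exact and simpler, so that route
is treated as an implementation device, not part of the definition.) Both
acceptance tests are strict inequalities: an edge is strong iff
`S > s_lim`, a component is kept iff `R > max(R_lim, R_parent)`.

The robustness `R_z` sums only the **strong** edges of a component (weak
edges are removed before components exist, so the subgraph whose weighted
density is measured is the filtered one). `R_z` lies in [0, 1] for every
component that can emit a robust cluster. Two degenerate graph cases are
resolved explicitly:

- A component that transitively contains two clusters of the same method
  has an empty core (no cell can be "grouped together in all the base
  clusters"); it emits nothing and its cells fall to the leftover. For such
  components the weighted density can formally exceed 1; they never emit,
  so the [0, 1] scale of reported robustness is unaffected.
- If the cores of two accepted components overlap (possible only through
  threshold edge cases), the contested cells go to the component with
  higher robustness; ties break on larger core, then lexicographically
  smallest (method, label) member. This keeps the output a deterministic
  partition of the pool.

The number of methods M entering `R_z` and `R_lim` is the number of
partitions actually produced: a base clusterer that fails is logged and
omitted, and M shrinks accordingly, keeping robustness on a [0, 1] scale
relative to achievable agreement. Fewer than two surviving partitions makes
the pool an unsplittable leaf. The majority size is `m = ⌊M/2⌋ + 1`.

## Base clusterers

The consensus layer is method-agnostic; any callable satisfying the
`BaseClusterer` contract (name, declared input transform, `fit(norm, seed)`
returning one label per cell) can be registered, and externally computed
partitions can be injected from two-column CSVs. The built-in roster covers
four methodological families:

| name | family | input | details |
|---|---|---|---|
| `leiden` | kNN-graph community detection | log1p(CP10K) | PCA(50) → kNN graph → Leiden, resolution 0.1 |
| `snn` | SNN-weighted community detection | log1p(CP10K) | PCA(50) → shared-nearest-neighbour graph, Jaccard weights pruned at 1/15 → Leiden, resolution 0.3 |
| `density` | density-based | log2(CPM+1) | PCA(50) → HDBSCAN, min cluster size max(5, n/100); noise cells join the nearest cluster centroid so the output is a partition |
| `hier` | hierarchical with internal validation | log1p(CP10K) | PCA(50) → Ward linkage, k ∈ [2, 10] chosen by maximal silhouette |

kNN uses k = min(15, n/5) neighbours. The two Leiden clusterers run at
deliberately conservative resolutions: within one recursion a base
clusterer only needs to separate populations that are distinct *at this
resolution* — finer structure is the job of the next recursion, and
conservative base partitions keep the ensemble from fragmenting a
homogeneous pool. Each method receives a deterministic seed,
`base_seed + crc32(method_name)`, with the pool's label folded into
`base_seed` so repeated sub-analyses are independent yet reproducible.

## Preprocessing

HVGs are reselected inside every recursion on the pool's own counts (the
expression structure that separates subtypes is usually invisible at the
whole-dataset level). Genes are ranked by the variance of log1p(CP10K)
expression standardized against a mean–variance trend fitted by lowess
(frac 0.3); the lowess is heavily robustified (10 reweighting iterations) so
that a minority of genuinely variable genes cannot drag the technical trend
toward themselves. Pools offering fewer than 20 distinct gene means fall
back to raw log-variance ranking; ties break on gene id so the ranking is
independent of input order. "TPM" on UMI counts without gene lengths
reduces to counts-per-million, so the `log2cpm` transform is
log2(1 + CPM). Zero-total cells normalize to all-zero columns with a
warning. Pseudocount 1 inside every log.

## Characterization filter

Markers of a cluster are computed against the **rest of its pool**:
log2 fold change of pseudocount-shifted mean de-logged normalized
expression, with a two-sided Wilcoxon rank-sum test on the normalized
values, Bonferroni-corrected over all genes of the pool (the significance
filter can be switched off for fold-change-only behaviour). A cluster is
well-characterized at ≥ 10 markers with log2FC > 4 and adjusted p < 0.05.

Two passes are made: clusters failing pass 1 merge into the leftover, the
survivors and the enlarged leftover are re-tested, and failures of pass 2
are merged as well (exactly two attempts). If no robust cluster survives,
the pool is not split. Two documented choices where the procedure was
genuinely open:

- The leftover's own marker count never vetoes a split — the no-split
  condition is read as "no *robust* cluster remained characterized". The
  leftover exists because methods disagree, not because it is a coherent
  population, so requiring it to be marker-distinct would be incoherent.
- A consensus outcome consisting of a single robust cluster equal to the
  whole pool is treated as no-split (it subdivides nothing, and recursing
  on it would not reduce the problem). In practice such a cluster already
  fails characterization, having no "rest of pool" to be distinct from.

Together the rising threshold `max(R_lim, R_parent)` and the
characterization filter are the two over-clustering guards: the first stops
recursion where agreement stops increasing, the second rejects splits of
transcriptionally homogeneous pools even when the clusterers agree on them.

## Synthetic data generator

The generator emulates a droplet-style UMI experiment under a
gamma–Poisson (negative binomial) law: relative gene abundances are drawn
log-normally (σ = 1.5), per-cell library sizes are log-normal (median 7500,
σ = 0.25 on the log scale), and counts have variance
mean + dispersion·mean² with dispersion 0.25. Four design axes: number of
clusters; balanced sizes (⌊N/k⌋ with the remainder on the first clusters)
vs imbalanced sizes following the floored normalized geometric ladder
`n_i = ⌊N·2^(−i)/(1 − 2^(−k))⌋` (which reproduces the reference vector
{5161, 2580, 1290, 645, 322} at N = 10000, k = 5; totals may fall a few
cells short of N and are deliberately not redistributed); and *related*
(cluster i+1 perturbs cluster i's profile — a chain, so transcriptome
correlation decays with chain distance) vs *unrelated* (every cluster
perturbs the base profile independently) transcriptomes. A perturbation
multiplies ⌈de_fraction·n_genes⌉ random gene means by 2^(±f),
f ~ N(fc_log2_mean, fc_log2_sd), sign random. With k = 1 the base profile
is used untouched.

Defaults (de_fraction 0.1, fc_log2_mean 6, fc_log2_sd 0.5) model strongly
distinct cell types: the 16-fold marker definition, after pseudocount
damping on the CP10K scale, requires planted effects comfortably above 2^4,
and 2^6 is the scale of canonical cell-type markers. What the generator
does **not** emulate: batch effects, doublets, ambient RNA, gene–gene
correlation beyond the shared profile, trajectories, and empirical gene-wise
dispersion profiles estimated from a real tissue. Tests passing on these
data therefore demonstrate the correctness and calibration of the
algorithm's machinery under its stated model — not performance on any
particular real dataset, where base-clusterer quality dominates.

## Evaluation metrics

NMI (normalized by max entropy by default; min/geometric/arithmetic
variants available) and ARI compare leaf clusterings with ground truth;
both are undefined/uninformative degenerately — NMI returns NaN when both
labellings are single clusters. The silhouette index and neighborhood
purity (mean fraction of a cell's k = 50 nearest neighbours sharing its
label) are computed with Euclidean distances on log-normalized expression
restricted to the labelled cells; cells in singleton clusters score 0 in
the silhouette, and a single-cluster labelling has no silhouette (NaN).
Leftover-excluded evaluation simply restricts the labelling to cells whose
leaf is not a leftover node.

## Numerical and scale choices

Deterministic throughout for a fixed seed (all randomness flows from numpy
`SeedSequence`s; per-method and per-pool seeds as above). Problem sizes in
the test suite — 2000 cells × 2000 genes for recovery runs, 1000 × 1000
for the single-population runs, ≤ 200 cells for the brute-force oracle
sweeps — were chosen as the smallest scales at which the behaviours of
interest (five-population recovery, over-clustering refusal) are stably
expressed under the generator's defaults. Count matrices are held dense
(int64); at these scales memory is not a constraint, and marker testing
and PCA operate on dense arrays anyway.

## Known limitations

- The built-in clusterers are analogues of the families used in published
  ensembles, not re-implementations of any particular tool; when fidelity
  to a specific external roster matters, inject its partitions via the CSV
  interface.
- Bonferroni correction over all pool genes is conservative; marker counts
  near the 10-gene boundary can flip with the significance filter off.
- The HVG criterion substitutes a lowess-standardized variance for
  ecosystem-specific selectors; rankings agree on strong signals but not
  necessarily in the long tail.
- Robustness quantifies *method agreement*, not biological truth: M highly
  correlated clusterers can agree confidently on the same mistake.
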