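# Methods

## Statistics on the de-logged scale

Input matrices hold `log_base(normalized count + pseudocount)` values
(default: log2, pseudocount 1, both overridable per dataset — natural-log
pipelines are common). All cluster-wise statistics are computed after
inverting that transform, because the arithmetic mean of normalized counts
is the quantity of biological interest and averaging log values
underestimates it. For each cluster and gene:

- `DR` — fraction of cells with a non-zero normalized count (entries with a
  de-logged value above 1e-12 count as detected);
- `MDGE` — mean normalized count over detected cells, defined as 0 when the
  gene is undetected so tables stay dense and the identity below never
  degenerates;
- `MGE` — mean normalized count over all cells of the cluster.

`MGE = DR × MDGE` holds exactly by construction and is enforced in the test
suite at 1e-12 relative tolerance. Matrix validation rejects non-finite
entries and any log value whose de-logged count would be negative beyond
1e-9, which catches wrong log-base/pseudocount metadata early.

## Differential expression

Significance: two-sided Wilcoxon rank-sum test, computed on the
log-normalized values (ranks are invariant under the monotone transform).
The exact null distribution is used when the pooled sample size is at most
50 and the pooled values are tie-free; otherwise the normal approximation
with tie and continuity corrections (scipy's `mannwhitneyu`). The rank-sum
test is distribution-free, robust to the unbalanced group sizes of vs-rest
comparisons, and embarrassingly parallel per gene; its slight bias toward
rarely detected genes is removed by the detection-rate filter: a gene is
tested only if `DR ≥ dr_threshold` (default 10%) in at least one side of
the comparison. For vs-rest comparisons the filter uses the pooled rest DR
(cell-count-weighted mean of the other clusters' DRs) — an interpretation,
since per-other-cluster filtering would also be defensible.

Multiple testing: Benjamini–Hochberg step-up, applied within each
comparison's tested set (per cluster for vs-rest, per pair for pairwise),
not globally — each stored table is a self-contained set of tests.

Effect sizes are reported for *all* genes, tested or not:

- `dDR = DR_A − DR_B`;
- `logGER = log2((MGE_A + pc)/(MGE_B + pc))` with `pc` defaulting to the
  reciprocal of the total number of cells in the dataset — the smallest
  representable step in count-based data. The alternatives both fail:
  `pc = 1` compresses magnitudes (provably: |log2((a+1)/(b+1))| ≤
  |log2(a/b)| for a, b > 0), most strongly near zero, while `pc = 1e-99`
  makes any comparison against a zero mean land beyond magnitude 300, far
  outside the range of real ratios. The 15-mean grid simulation
  (`pseudocount_grid` / `pseudocount_logger_table`) tabulates all three
  behaviours; the grid is evenly spaced from 0 to 50 with a single zero
  entry, and N = 1000 cells is assumed for the 1/N variant.

Externally computed DE tables (e.g. from a model-based test) can replace
the built-in results; they are schema-validated (effect size, p, FDR,
tested flag) but never recomputed.

## Granularity metrics and the resolution sweep

From the pairwise tables:

- the **nearest neighbour** of a cluster is the other cluster with the
  fewest significant genes (FDR < threshold, either direction); ties break
  by cluster-name order. The neighbour relation is deliberately not
  symmetrized.
- **neighbour-DE genes** of a cluster are the positively DE genes (FDR <
  threshold and effect toward the cluster) in its neighbour pair. Counting
  *both* directions for neighbour identification but only the *positive*
  direction for the reported sets reflects the two different roles:
  "hardest to distinguish from" is undirected, "has its own marker-like
  genes" is directed. A gene with logGER exactly 0 is never positive.
- **marker genes** are positively DE against every other cluster; by
  construction `markers(c) ⊆ neighbour_DE(c)`.

A solution passes the neighbour check iff every cluster has at least one
neighbour-DE gene; a single-cluster solution passes vacuously (there are no
pairs to fail). `sweep_resolutions` processes solutions by increasing
cluster count (stable on ties) and, with `stop_on_loss`, stops after the
first failing solution — which is retained and flagged rather than
discarded, so the failure can be inspected. The package reports pass/fail
and the counts; the final resolution choice is left to the user.

Silhouette widths use plain Euclidean distance on the supplied embedding
with no axis reweighting (variance-weighting of PCs is an upstream choice
the package must not assume). `s(i) = (b−a)/max(a,b)` with the usual
conventions: width 0 for singleton-cluster cells and for coincident points
(`a = b = 0`). The implementation is direct from the definition and is
cross-checked in the tests against both a brute-force oracle and
scikit-learn.

## Annotation and cell-set comparison

Auto-annotation ranks genes within each cluster by descending MGE (ties:
DR, then name) and assigns the cell type whose catalog markers have the
smallest mean rank; catalog genes absent from the data are ignored rather
than penalized, and ties go to the first type name. MGE is the default rank
statistic because it blends magnitude and detection; MDGE and DR are
available alternatives. This is a labelling convenience and makes no claim
of equivalence with dedicated classifiers.

Manual comparisons label cells A / B / rest and reuse the full DE
machinery, so comparing two existing clusters reproduces their pairwise
table exactly; when A and B cover all cells the vs-rest comparison is
skipped with a warning. Volcano tables report (logGER, −log10 FDR) for
tested genes, clamping FDR 0 to half the smallest nonzero FDR before the
log; MA tables report difference and average of any of MGE/MDGE/DR.

## Synthetic data

`simulate_dataset` draws counts from a negative binomial — the simplest
model reproducing the tight coupling between expression magnitude and
detection probability in droplet data — then library-size normalizes
(median library size as the reference) and log2-transforms with
pseudocount 1. Defaults, chosen once:

- `n_clusters 5`, `cells_per_cluster 40`, `n_genes 500`,
  `de_genes_per_cluster 10`, `effect_multiplier 4`: the standard recovery
  condition used throughout the tests; effect multiplier 1 gives null data.
- `baseline_mean 2.0` counts/cell with per-gene lognormal spread
  (sigma 0.5): the simulated genes stand for the detectably expressed
  subset of a transcriptome that survives the DR filter, not the full
  ~20k-gene complement, and such genes typically average a few counts per
  cell.
- `dispersion 0.5` in the RNA-seq convention (variance = mu + 0.5 mu²,
  NB size 2), i.e. biological CV ≈ 70% within a cluster.

Each cluster's DE genes are exclusive to it (no overlap between clusters).
What the generator does *not* emulate: batch effects, doublets, ambient
RNA, trajectories/continuous variation, gene–gene correlation, and
cell-level library-size covariates. Passing recovery tests therefore shows
the machinery behaves correctly under its own model assumptions, not that
any particular real dataset will be resolved correctly.

`build_resolution_series` surrounds a ground-truth labelling with coarser
solutions (merging true clusters along the average-linkage dendrogram of
their centroid distances in log-expression space) and finer ones (random
bisection of one true cluster per extra count), yielding the
under/exact/over-clustered series the sweep is designed to discriminate.

## Numerical and design choices

- Cluster labels are always text and never coerced ("1" ≠ "01").
- Pairwise results are keyed by the name-sorted cluster pair; effects are
  oriented toward the first-named cluster, and serialized keys join the
  names with a dash.
- De-logging clips rounding residues in [−1e-9, 0) to zero.
- Archives are ZIPs with fixed (1980) member timestamps so identical runs
  are byte-identical; the manifest stores per-file SHA-256 digests and
  loading verifies all of them.
- Clusters with fewer than 3 cells are flagged as unreliable to test
  (`validate_solution`); the threshold is a convention, not a hard rule.
- Problem sizes in the test suite (40–200 cells per condition, 100–500
  genes, 20 simulation seeds for the stochastic claims) were chosen as the
  smallest scales at which the rank-sum test has realistic power, so the
  whole suite documents the method's behaviour in minutes on one core.

## Known limitations

- The Wilcoxon test needs enough cells per cluster (a handful of cells per
  side cannot reach FDR significance after BH correction); the stopping
  rule inherits that conservatism — tiny true clusters can fail the
  neighbour check for lack of power rather than lack of identity.
- The pooled-rest DR filter can admit genes driven by a single large
  "rest" cluster.
- The neighbour-DE count metric depends on the FDR threshold and on
  dataset size; counts are comparable across resolutions of one dataset,
  not across datasets.
- Auto-annotation is rank-based and unweighted; closely related types with
  shared markers will tie or flip.
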