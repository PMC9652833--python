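# Methods

This note documents the models, default parameters and numerical choices
behind `discpair`, and what the synthetic validation does and does not
demonstrate about real data.

## Scope and data model

The pipeline starts from gene × barcode UMI count matrices (10x triplet
convention: Matrix Market coordinate-integer file plus features and
barcodes TSVs) tagged with a modality, `cells` (scRNA-seq of dissociated
cells) or `nuclei` (snRNA-seq). Upstream steps — read mapping, UMI
deduplication, genome annotation — are out of scope. Two curated tabular
inputs drive annotation: a marker matrix (identity → marker genes,
optional positive weights) and a merge map (fine label → combined cell
type). Gene symbols must be unique; the reader de-duplicates collisions
by suffixing `.1`, `.2` in stable order.

## Quality control

Per barcode we compute detected genes (count > 0) and the percentage of
reads in three prefix-defined gene classes: mitochondrial (`mt:`),
ribosomal protein (`RpS`, `RpL`) and heat-shock (`Hsp`). Filters:

| rule | cells | nuclei |
|---|---|---|
| minimum detected genes | 300 (kept) | 300 (kept) |
| maximum detected genes | 3000 (kept) | pre-filter 99th percentile (ties kept) |
| mitochondrial reads | > 10% dropped (10.0% kept) | same |
| gene support | ≥ 5 barcodes | ≥ 3 barcodes |

All boundary semantics are strict ("more than", "less than"): a barcode
at exactly 300 or 3000 genes or exactly 10.0% mitochondrial reads is
kept. This matters — it changes the kept set at the boundaries — so it
is fixed here rather than left to implementation accident. The nuclei
upper rule uses the 99th percentile with linear interpolation
(`numpy.percentile` default) computed on the pre-filter distribution;
the threshold is frozen into the QC table so filtering is idempotent.
Drop reasons are assigned in the order too-few-genes →
too-many/top-1% → high-mito, first match recorded; the high gene-count
rules double as the doublet proxy and no model-based doublet detector is
included. Gene support is counted after barcode filtering, matching the
dependency between the two filters.

## Normalization and variable-gene ranking

Counts are scaled per barcode to the median depth M and
log-transformed: v(g,b) = ln(1 + c(g,b)·M/d(b)); size factors d(b)/M are
retained. Zeros are preserved exactly, which keeps the matrix sparse.
This deliberately replaces regularized negative-binomial (SCTransform
style) normalization: the downstream consumers here need only a
depth-corrected log scale and a variable-gene ranking, and a closed-form
method keeps every stage fully specified and dependency-free. The
substitution is a design choice of this package, documented here
prominently because fold changes and dispersion ranks are not expected
to match a Pearson-residual pipeline gene for gene.

Variable genes are ranked by the variance of standardized values: genes
are placed in 20 equal-occupancy bins by mean expression, the expected
standard deviation of a gene is the mean observed standard deviation of
its bin, and per-barcode z-values are clipped at √n_barcodes before the
variance is taken (the usual vst-style guard against one outlier barcode
owning the score). Fewer than 20 genes fall back to a single bin. Ties
break lexicographically by symbol, making the ranking fully
deterministic and invariant to barcode order.

## Embedding and clustering

PCA runs on the HVG-restricted, gene-centered matrix via SVD with a
deterministic sign convention (each component's largest-magnitude gene
loading is positive). Requesting more components than the matrix rank
truncates with a warning.

The cluster stage builds a k-nearest-neighbor graph (k = 20, Euclidean
distance in 30 PCs, neighbor lists include the point itself), re-weights
edges by the Jaccard overlap of neighbor lists (shared nearest
neighbors) and prunes weights below 1/15. Communities maximize
resolution-parametrized modularity by greedy local moving with a seeded
node order, iterating local moving and graph aggregation until no
further improvement — i.e., standard Louvain run to convergence, which
we chose over a fixed single aggregation pass because convergence is
what makes the planted-type partition the reliable optimum at default
sizes while remaining deterministic under a fixed seed. Barcodes left
without edges after pruning become singleton clusters; final labels are
contiguous integers ordered by decreasing cluster size.

Resolution is an explicit parameter (default 1.0) and `discpair cluster
--sweep` reports cluster counts over a grid for inspection; there is no
automated resolution choice. Two properties of modularity worth knowing
when interpreting results: with only two or three balanced, well-
separated groups, resolution 1.0 can prefer sub-communities of each
group (drop the resolution to merge them); with many groups — the
11-type default — resolution 1.0 recovers the planted partition exactly.

## Marker detection

For each cluster with ≥ 3 barcodes, genes detected in ≥ 10% of the
cluster's barcodes are tested one-vs-rest with a two-sided Wilcoxon
rank-sum test. For n+m ≤ 10 the p-value is computed exactly by
enumerating all C(n+m, n) group assignments (midranks for ties);
otherwise a normal approximation with tie correction and a 0.5
continuity correction is used. The approximation sits within a few
percent (absolute) of the exact law at the smallest sizes it is applied
to and converges quickly above them. Benjamini–Hochberg adjustment runs
per cluster across its tested genes (not jointly across clusters).
Fold change is computed on de-logged means with pseudocount 1:
log2((mean(expm1 v_cluster)+1)/(mean(expm1 v_rest)+1)). A marker
requires log2FC > 0.25 and adjusted p < 0.05, both strict. Top-N lists
sort by (adjusted p ascending, log2FC descending, symbol).

The test choice (Wilcoxon) and adjustment (BH) are the de-facto defaults
of this workflow family; both are isolated behind small functions
(`rank_sum_p`, `bh_adjust`) and swappable.

## Annotation

score(identity, cluster) = Σ weights of the identity's markers present
in the cluster's significant set; with unit weights, a plain count.
Markers absent from the dataset's gene universe are logged and ignored.
An optional per-identity normalization (score / marker-set size) is
available behind a flag but is not the default, because the tie rule is
defined on equal marker *counts*. Assignment: the top-scoring identity
wins; exactly two identities tied at the top (within 1e-9 for real
weights, exact for integer scores) give the dual label "A|B" in
alphabetical order; three or more ties give "Other", as does an all-zero
score column (no evidence — a case the count rule alone does not
address, resolved here as "Other"). Merging applies a total mapping from
fine to combined labels and fails loudly on any unmapped label; the
pipeline driver (where dual labels arise data-dependently) extends the
map with identity mappings for observed labels and records that in the
run manifest.

## Integration and comparison statistics

Integration is deliberately simple and fully specified rather than
anchor-based: restrict both datasets to the union of their top-3000
variable genes intersected with the shared gene universe, z-score each
gene within its dataset (absorbing per-modality location/scale shift),
concatenate barcodes, and run the standard embedding + clustering. Joint
clusters are annotated from a joint one-vs-rest marker table against the
same marker matrix. Per-dataset z-scoring assumes broadly comparable
cell-type composition between the datasets; a cell type entirely absent
from one dataset would break its gene-level statistics, which is the
known limitation this stage shares with any scaling-only integration.
The stage sits behind a narrow contract (two normalized matrices in, a
joint labelled assignment out) and is pluggable.

Comparison statistics:

* **Contribution.** r = n_filtered_nuclei / n_filtered_cells; per joint
  label, corrected cells share = count_cells·r / (count_cells·r +
  count_nuclei), in percent; shares sum to 100 per label and are
  invariant to multiplying both datasets' counts by a common constant.
  When both filtered matrices are present the factor is computed from
  them; it can also be supplied.
* **Variable-gene Venn.** Set partition (unique A, shared, unique B) of
  two gene lists; external lists are accepted, since variable-gene
  rankings differ between normalization methods.
* **DE overlap.** Per combined cell type, the union U of both datasets'
  significant genes is the denominator; percent unique-to-each and
  shared sum to exactly 100. An empty union is reported as missing.
* **Transitions.** Barcode-matched contingency of individual labels vs
  joint labels, emitted square and in long form for alluvial plotting;
  a barcode present individually but missing from the joint assignment
  is a hard error (tracking would be silently broken otherwise).

Derived run summaries (per-disc yield, percent of the expected ~44,000
cells per disc, mean reads per barcode) reproduce the conventions such
summary tables print: per-disc count rounded to the nearest cell,
percent-of-expected truncated to one decimal (computed on the unrounded
per-disc yield), and mean reads by integer division.

## Synthetic data generator

`synthetic.generate_pair` emulates the paired design: one gene universe
(default 66 marker genes = 11 identities × 6, 1000 background genes,
8 mitochondrial, 30 ribosomal protein, 8 heat-shock genes, named with
the QC prefix conventions) and one identity set shared by both
modalities. Per barcode, counts are multinomial over a type-specific
probability vector with depth ~ negative binomial (mean 3000, dispersion
10, floored at 2000 for quality barcodes); each type multiplies its
marker genes' weights by `marker_fold` (default 10); a Dirichlet
perturbation (concentration 600) adds per-barcode variability.
Modality effects:

* cells — ribosomal read fraction 0.20, heat-shock fraction 0.05
  (a free parameter: the source workflow reports a heat-shock burden
  qualitatively, not as a fraction), mitochondrial baseline 2%, and 14%
  of non-low-quality barcodes drawn as mitochondrial failures with
  target fraction uniform in 0.13–0.30 (safely above the 10% filter,
  so planted and realized failure sets coincide at default depths);
* nuclei — ribosomal fraction reduced by 28%, heat-shock ≈ 0,
  mitochondrial baseline 0.3% with failure rate 0.02%;
* both — doublets (rate 0.05) as averaged two-type profiles at doubled
  depth, low-quality barcodes (rate 0.03) with depth < 300 so they are
  detected-gene failures by construction.

The nuclei expression profile is flatter (lognormal σ 0.4 vs 0.8 for
cells), emulating the higher genes-per-barcode of nuclear data without
modelling intronic reads; at the default depth this puts the median
detected genes near 540 (cells) vs 630 (nuclei). The absolute nuclei
median is capped by the deliberately small gene universe (~1100 genes),
so the generator reproduces the direction and the cells-side magnitude
of the contrast, not the nuclei-side absolute. The generator is fully
reproducible from its seed and emits a truth table (per-barcode identity
or `doublet:A+B` / `lowq`, mitochondrial-failure flag, per-gene class)
used by the recovery tests.

What passing on synthetic data shows: every stage implements its
contract, boundaries are exact, and the pipeline recovers planted
structure under realistic noise at the stated failure rates. What it
does not show: robustness to ambient RNA, batch effects beyond the
modelled modality shifts, intron-driven quantification differences,
continuous differentiation trajectories, or marker matrices that are
incomplete or wrong — on real data, annotation quality is bounded by the
curated marker matrix.

## Problem sizes and determinism

Default validation sizes are 11 types × 200 barcodes per modality
(~2,400 barcodes each, ~1,100 genes), chosen so the full paired analysis
— both modalities plus integration — completes in well under a minute
while leaving every statistic comfortably clear of its sampling noise.
All randomness flows from a single root seed split deterministically per
stage (CRC-based, always < 2^31); two runs with identical config and
seed produce byte-identical TSV outputs (floats are formatted at 10
significant digits).
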