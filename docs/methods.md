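# Methods

This note documents the statistical model behind `txconcord`, the
choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish about real data.

## Pipeline model

### Expression filter

Genes are kept when their CPM (count / raw column sum × 10⁶) is ≥ 10 in
at least *n* samples, *n* being the smallest group size — the standard
edgeR-style rule guaranteeing that a gene expressed in only the smallest
group can survive. The comparison is inclusive (≥) and uses raw library
sizes, not normalized ones. The filter is idempotent. The grouping
column defaults to the model-system label and is configurable.

### PCA

`prcomp`-equivalent: the gene × sample log(TPM+1) matrix is transposed
(samples are observations), each transcript is centered, nothing is
scaled, and the centered matrix is decomposed by SVD. The number of
components is min(samples − 1, transcripts). Loadings are the unit-norm
right singular vectors; scores reconstruct the centered input exactly.
Because the empirical loading test below is direction-sensitive, each
PC's sign is fixed deterministically: the largest-magnitude loading in a
component is made positive.

### Score ANOVA and PC selection

Per PC, a one-way ANOVA (closed-form sum-of-squares construction,
F = (SSB/(k−1))/(SSW/(N−k)), upper-tail F(k−1, N−k) p-value) compares
scores between the focus group and the rest; k ≥ 2 group labels are
supported. Perfect separation (SSW = 0, SSB > 0) is reported as
degenerate with p = 0 rather than an error. The pipeline carries the
max-F PC forward by default; a fixed index (`pc_selection = "fixed:k"`)
is available for analyses where the interesting component is chosen by
inspection instead.

### Cross-PC empirical loading significance

For transcript *t* with loading *L* on PC *j*, the null is every loading
in PCs ≠ *j*; by default the tested transcript's own loadings in those
PCs are excluded too (`exclude_self=True`). The test is directional and
strict: for *L* > 0, p = #{null > L} / #{null > 0}; for *L* < 0,
p = #{null < L} / #{null < 0}. No pseudocount is added, so p = 0 is
attainable (flagged `small-null` when the same-sign pool is empty);
L = 0 gives p = 1 (flagged `zero-loading`). Selection uses p ≤ 0.05
inclusive.

Two caveats are inherent to this construction. First, which loadings
belong in the null is ambiguous when reading "all other transcripts'
loadings in all the other PCs"; both readings are implemented and
`exclude_self` records the choice. Second, the test depends on each
PC's sign convention: the null's positive and negative sides are not
mirror images, so flipping a single PC changes p-values. The
deterministic sign-fixing above makes results reproducible; negating
the entire loading matrix is the operation that leaves every p-value
invariant, and the test suite asserts exactly that.

### Information-weighted correlation and pseudo-distance

Over the selected transcripts, a sample pair (i, j) receives:

* `pearson_r` — Pearson correlation of the full log1p vectors, zeros
  included (a co-present-only mode exists behind a flag);
* `jaccard` — shared-present genes over genes present in either;
* `completeness` — fraction of genes with concordant presence/absence;
* `weight` — jaccard × completeness by default. The two ingredients are
  both reported, and the combiner is configurable
  (`product | jaccard-only | completeness-only`) because the functional
  form combining them is a modeling choice — the product is the minimal
  composition that vanishes when either information source does;
* `weighted_r = pearson_r × weight` and
  `pseudo_distance = 1 − weighted_r`.

On zero-free data weight ≡ 1 and the whole construction collapses to
the plain Pearson correlation matrix (asserted to 1e-12). The
pseudo-distance is symmetric with a zero diagonal but is *not* a metric
— the triangle inequality is not asserted anywhere. Degenerate pairs
(zero-variance or all-absent samples) are flagged, given weighted_r = 0
and distance 1, and clustering proceeds with a warning rather than
failing.

### Clustering and leaf ordering

Agglomerative clustering with complete (default), average or single
linkage, implemented with Lance–Williams updates and a deterministic
tie-break: among equal minimal distances, the smallest (node, node) id
pair merges first. Complete linkage is the default because nothing in
the analysis constrains the choice; it is configuration, not inference.

Leaf ordering is a dendsort-style rule, fully specified so it is
auditable: at each internal node the child whose subtree contains the
smaller minimum merge height comes first; a leaf's key is +∞; ties
break by lexicographically smallest leaf label. The reordering never
touches topology or heights, and its output is invariant to any
permutation of the input leaf order. `cut_clusters(k)` applies the
first n−k merges (heights are monotone for these linkages) and numbers
clusters by their smallest leaf index, so cuts are deterministic too.

### Over-representation

Upper-tail hypergeometric test per term (population = universe,
successes = in-universe term genes, draws = query), BH adjustment
across all tested terms (delegated to statsmodels' step-up
implementation), and the reporting filter FDR ≤ 0.05 with ≥ 2 genes.
"Annotated to two or more genes" is read as ≥ 2 *query-overlap* genes
by default; the term-size reading is available via `min_count_on`.
The universe defaults to the genes surviving the expression filter —
the tested features define the background.

## Synthetic benchmark

The generator emulates a four-system tumor experiment (bulk tumor,
sorted tumor cells, 2D lines, 3D tumoroids; 6 samples each by default,
configurable up to the published design sizes) with known ground truth.

* **Counts**: negative binomial with variance μ + μ²φ, φ = 0.05 by
  default (well-controlled isogenic cultures; BCV ≈ 0.22). Gene
  baseline means are lognormal (ln-mean 4.6, ln-sd 1.5 — a wide,
  realistic dynamic range), library-size factors lognormal (ln-sd
  0.25), gene lengths uniform on 200–10,000 bp, fixed across samples.
  TPM is computed from the post-dropout counts and lengths.
* **Group structure**: 10% of genes (drawn from above the 30th
  expression percentile — markers are reliably detected genes) carry
  group-specific signatures: every group gets its own random ±1 sign
  pattern over the planted genes, the focus (2D) group at the full
  log2 `signal_shift` amplitude and non-focus groups at half. Group
  mean profiles are therefore mutually decorrelated on the planted
  genes, each model system has a distinct signature, and the focus
  group's larger amplitude dominates the leading variance direction —
  which is what makes a single max-F PC, and a k = 4 cut from genes
  selected on that one PC, well-posed. With `signal_shift = 0` the
  groups are exchangeable and the pipeline's null behavior can be
  measured.
* **Dropout**: applied after count sampling as an independent Bernoulli
  zero-mask. The per-gene propensity is the Beta(c·r, c·(1−r)) quantile
  (c = `dropout_shape` = 0.1, r = the group's rate) evaluated at the
  gene's expression-rank quantile, so propensities are U-shaped: lowly
  expressed genes are near-always absent, well-expressed genes
  near-always present, and the marginal zero-injection rate per group
  equals the configured rate exactly. This mirrors the mean-dependence
  of zeros in real RNA-seq and produces the consistent presence/absence
  patterns the information weighting assumes. A uniform per-entry rate
  would instead inject enormous log-scale variance into every gene
  (a dropped mid-expression gene swings log1p(TPM) by ~5–6), burying
  any plausible planted signal under the noise eigenvalue bulk;
  `expected_zero_fraction` returns the exact per-group expectation for
  calibration tests.

What the benchmark does **not** model: batch effects, isoform
structure, correlated gene modules beyond the planted signatures,
compositional coupling among unplanted genes, or read-level noise.
Passing tests therefore show that the pipeline recovers structure of
the kind it assumes at realistic noise levels — not that it is robust
to every artifact of real experiments.

### Benchmark scales used

Default packaged design: 2000 genes, 4 × 6 samples, 10% planted genes,
log2 shift 2.0, 20% dropout. Unit tests use 200–400 gene versions of
the same design; oracle-equivalence checks use 100 random loading
matrices (≤ 200 × 8) and 500 enrichment configurations on universes
≤ 12, where exhaustive enumeration is exact. These sizes were chosen so
the whole suite runs comfortably on a laptop while leaving the planted
effects at the amplitudes stated above.

## Numerical conventions

* Threshold comparisons follow their stated forms literally: CPM ≥ 10,
  DEG |LFC| > 0.5 and FDR < 0.05 (strict), loading p ≤ 0.05 and
  enrichment FDR ≤ 0.05 (inclusive).
* Missing FDR values in DE tables are treated as non-significant.
* TPM/CPM columns sum to 10⁶ within 1e-6 relative; all-zero sample
  columns are an error naming the sample.
* Pipeline outputs carry a one-line provenance header (version, config
  hash excluding the output directory, seed); two runs with the same
  configuration and seed are byte-identical.

## Known limitations

* The empirical loading null mixes structured PCs (other group
  signatures) into the reference distribution, so its p-values are
  conservative when several strong components exist; the null-selected
  fraction at α = 0.05 sits near 0.05 but is not guaranteed uniform.
* The pseudo-distance is not a metric; linkages that assume metricity
  (e.g. Ward) are deliberately not offered.
* The hand-rolled agglomeration is O(n³) with an O(n² log n) tie-break
  scan per step — fine for sample-level matrices (tens to hundreds of
  samples), not intended for gene-level clustering.
* Differential-expression fitting is out of scope: DEG thresholds are
  applied to externally produced tables only.
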