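# Methods

This note documents the models implemented in `wmniche`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data does and does not emulate.

## Scientific setting

Glioblastoma cells infiltrating along myelinated tracts encounter a
microenvironment — the white matter — that can push them toward a
pre-oligodendrocyte fate, marked by SOX10 induction, reduced proliferation
and reduced motility. The computational evidence for this rests on three
legs, all implemented here: (1) cell-type signatures derived from reference
brain atlases; (2) differential expression between tumour cells
micro-dissected from the corpus callosum (CC, white matter), striatum (ST,
grey matter) and tumour bulk, with clusters of regulated genes tested for
signature enrichment; (3) quantitative microscopy read-outs (g-ratios,
percent-positive counts, contact and disruption rules) establishing the
injury-and-differentiation phenotype.

## Signature derivation

Input is a gene × (cell type, replicate) expression matrix on a linear,
non-negative scale (FPKM-like). Processing order:

1. duplicate gene ids collapsed by arithmetic mean;
2. genes whose maximum condition mean is below `low_coverage_min`
   (default 1.0 expression unit) removed;
3. replicates averaged per condition;
4. values moved to log2(x + 1) (`log2_transform=True` by default);
5. rows median-centred.

The log step is a deliberate design choice: variable-gene selection by
coefficient of variation is only meaningful on the linear scale (s/μ needs
a positive mean, and the published CV cutoffs for such atlases are
linear-scale values), whereas clustering and the discrimination margin are
better behaved on centred log values, where a gene's baseline abundance
cancels and markers of one type share a profile regardless of expression
level. `select_variable_genes` therefore takes the raw matrix and computes
CV (sample sd, ddof 1) on condition-averaged linear values;
`derive_signatures` takes the centred log matrix.

K-means (10 restarts, lowest within-cluster sum of squares, fixed seed)
clusters the selected genes on their centred condition profiles. A cluster
is promoted to the signature of cell type *T* iff its mean profile is
maximal at *T* and exceeds the second-highest condition by at least
`margin` (default 0.5 log2 units, i.e. the cluster is ~40 % higher in its
own type than anywhere else). At most one cluster per cell type is kept
(largest margin wins). "Good cell-type discrimination" is not a published
algorithm anywhere in this literature — it is operationalised here as this
margin rule and exposed as a parameter. `k` defaults to twice the number of
cell types; for atlases with clean one-block-per-type structure, `k` equal
to the number of cell types maximises marker recovery (the empirical-k
philosophy the original atlas analyses also followed), and that is what
the acceptance computation uses.

## Differential expression

The count model is negative binomial with variance μ + αμ². The pipeline
is intentionally transparent rather than a re-implementation of any
specific tool:

- **Size factors** are median-of-ratios: factor_s = median over genes with
  positive geometric mean of count_gs / geomean_g. This matches the
  standard estimator exactly (verified against an independent
  implementation in the tests). Note the exact invariance property:
  multiplying one library by c multiplies its factor by c *relative to the
  other samples* (the per-gene geometric means absorb a common c^(1/n)).
- **Dispersion** α per gene by method of moments, pooled across the two
  compared groups, floored at 1e-4. No shrinkage toward a trend, no
  outlier refitting, no independent filtering.
- **Wald statistic**: log2 ratio of size-factor-normalised group means with
  pseudo-count 0.5 over a delta-method standard error,
  SE² = Σ_groups (μ c̄/n + αμ²/n)/(μ + ½)² / ln²2, where c̄ is the group
  mean of 1/s.
- **Reference distribution**: two-sided *t* with n_A + n_B − 2 degrees of
  freedom. With an estimated standard error and no dispersion shrinkage, a
  plain normal reference is measurably anticonservative at typical
  replication (null false-positive fraction ≈ 0.085 at 10 replicates per
  group, ≈ 0.125 at 3); the t reference restores calibration (≈ 0.05) at
  both depths without any tuning of the simulation.
- **Multiple testing**: BH step-up across tested genes; genes with zero
  counts in both groups carry NA statistics and are excluded from the BH
  denominator.

Gene selection for clustering uses strict thresholds — p_adj < α and
|log2 ratio| > 0.58 (i.e. 1.5-fold) in at least one regional comparison —
with α defaulting to 0.05; the per-signature regulation summary uses the
more permissive 0.1. Both appear in the source material and both are
configurable. Selected genes are K-means-clustered (k = 7 by default) on
their (CC, ST) log2-ratio vectors.

Sample-level PCA approximates a variance-stabilised view as
log2(normalised count + 1) on the 500 most variable genes, with each
component's sign fixed by its largest-magnitude loading so runs are
comparable.

## Enrichment

For each (gene group, signature) pair, both intersected with the universe
(default: all genes surviving the count filter), the p-value is the
hypergeometric upper tail P(X ≥ overlap). Correction (BH default,
Bonferroni available) is applied across all cells of the matrix. Genes in
multiple signatures are tested in each; no exclusivity is enforced. The
table also reports the percentage of each group found in each signature,
which is the natural x-axis when plotting −log10 p against coverage.

## Morphometry

Feret diameter is the maximum pairwise distance over contour points
(computed on the convex hull for speed; identical to the all-pairs
maximum). The g-ratio divides the axon Feret by the axon-plus-sheath
Feret; which caliper to use is not standardised, so the maximum Feret is
used consistently in numerator and denominator (both contour-based and
pre-measured-diameter inputs are accepted, since EM analysts usually record
diameters directly). Decompaction is scored strictly: an axon is
decompacted only when *more than* 15 % of its circumference is affected;
degeneration is the logical OR of five qualitative features. Groups with
fewer than 50 axons trigger a warning, not an error, mirroring how minimum
sample sizes are used descriptively in EM work. The g-ratio-vs-diameter
trend is ordinary least squares per condition; constant-diameter input is
flagged rather than fitted, and constant g-ratio input reports slope 0
with R² 0.

## Quantification rules

All geometry is 2-D, in µm, image convention (y down). Every threshold
quoted as "<" is strict, uniformly:

- **Contact**: nucleus modelled as a disc; contact iff
  min over axon polylines of (point-to-polyline distance − nucleus radius)
  < 1.5 µm. A nucleus edge exactly 1.5 µm away is *not* in contact.
- **Disruption**: ROI fluoromyelin mean grey is normalised by max grey;
  a white-matter ROI is disrupted iff it contains axons AND its normalised
  intensity < 0.25 × the contralateral intact reference. Exactly 25 % is
  not disrupted; no axons, never disrupted.
- **Tiers**: percentile mode uses the 25th/75th percentiles of ≥ 100
  reference nuclei (low ≤ Q25, high ≥ Q75, medium between — the "medium"
  band is the open interval, a choice this package makes explicit);
  reference mode uses background (< background ⇒ negative) and the minimum
  of > 20 flagged high cells (≥ that ⇒ high).
- **Percent-positive**: ROIs below the minimum denominator count
  (default 750 cells) are excluded and logged, not errors; a pooled
  percentage across surviving ROIs is appended.
- **Invasion**: "area occupied by tumour cells" is not a well-defined
  published quantity; it is operationalised as the convex hull of the cell
  positions, with a caller-supplied mask area accepted as an alternative.
  The index divides that area by the bulk-polygon perimeter; migrated
  distance is the Euclidean distance to the bulk polygon (0 inside).

Cohort scoring calls a sample "high" when its z-score strictly exceeds
`threshold_z` (default 1.0, under which a normal cohort yields ≈ 16 % high
expressors — the size of "subset" the published cohorts describe; the
actual cut-off used there is unstated, so this is a parameter, not a
claim). qPCR relative expression is 2^−(Ct_gene − Ct_reference), with an
optional fold-change-over-control second normalisation.

## Synthetic data

The generators define the conditions under which the pipeline is validated:

- **Atlas**: per-gene log2 baseline uniform on [2, 6]; markers gain
  `marker_effect` = 2.0 log2 units in their own type; log-normal noise
  `noise_sd` = 0.5 log2 units (so the planted effect is 4× the noise);
  3 cell types × 50 markers + 500 background genes, 3 replicates.
- **Region counts**: NB counts with variance μ + αμ² (α default 0.1 for
  null simulations, 0.05 in the orchestrated run, 0.01 for clean effect
  recovery); baselines log-uniform on [20, 2000]; Bulk/CC/ST with 3
  replicates each by default (matching typical xenograft replication) and
  10 per group for calibration studies, where moment dispersion estimates
  are stable. Planted genes change their region's mean by 2^(log2 effect).
- **Axons**: elliptical cross-sections (eccentricity ≤ 0.2) with uniform
  sheath thickness; decompaction/degeneration flags honoured exactly at
  round(n × fraction); "demyelinated" sets use thinner sheaths, raising
  g-ratios.
- **Cell fields**: uniform positions, exact positive counts per marker,
  tier-banded intensities, contact truth computed from the same strict
  rule the classifier uses (on purpose: the generator records geometric
  truth, the classifier is validated against independent brute-force and
  shapely oracles in the tests).

One global seed expands to per-generator substreams through fixed offsets,
so adding a generator never changes another's draws, and every generator is
byte-deterministic at fixed seed.

What the synthetic data does **not** emulate: mapping/quantification noise
upstream of the count matrix, correlated gene modules, ortholog mapping
between species, batch effects, segmentation error in cell positions or
intensities, and 3-D tissue geometry. Passing tests therefore demonstrate
the correctness and calibration of the computations, not the biological
robustness of any particular dataset.

## Problem sizes and numerics

Validation runs use 2000-gene count matrices, 150-marker atlases, 60-axon
EM sets and fields of a few hundred cells; the planted-enrichment check
repeats the full pipeline over 10 seeds. These sizes give stable Monte
Carlo estimates (binomial error on a 2000-gene false-positive fraction is
≈ 0.005) while keeping any single validation run in seconds. Ties in
K-means are resolved by the fixed-seed restart policy; CV uses sample
standard deviation; hypergeometric tails come from scipy's survival
function; BH from statsmodels. Degenerate inputs (zero-variance cohorts,
all-zero genes, self-intersecting polygons, duplicate timestamps) raise
explicit errors naming the rule violated.

## Known limitations

- The NB test deliberately omits dispersion shrinkage, Cook's-distance
  outlier handling and independent filtering; concordance with DESeq2 is
  promised only for the size-factor estimator and the count filter.
- rlog is approximated by log2(normalised + 1) for PCA.
- Signature derivation assumes one dominant profile per cell type; cell
  types defined by combinatorial absence of expression will not pass the
  margin rule.
- The deposited-accession gene-count reproduction (applying the count
  filter to the published raw counts) requires the external download;
  `wmniche.geo.count_filter_report` performs it on a locally provided
  table.
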