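# Methods

This note documents the statistical models, defaults, and design choices
behind spatomics, and what the synthetic fixtures do and do not establish
about real data.

## Data model

A dataset is a collection of feature × sample matrices (assays) over one
shared sample axis, with per-sample metadata, per-feature metadata, and one
spatial geometry per sample. A geometry is a point or an axis-aligned
rectangle; its centroid — (x, y) for a point, (x + w/2, y + h/2) for a
rectangle — is the sample's location for every distance computation.
Coordinates are Cartesian in arbitrary dataset units (`planar`) or
degrees longitude/latitude (`lonlat`); lonlat distances are great-circle
(haversine) kilometers on a sphere of radius 6371 km. Nothing downstream
depends on coordinate magnitude, only on relative distances, which is what
makes the toolkit usable from micrometer tissue grids to continental
surveys. When multiple assays coexist (multi-omics on the same ROIs), they
share the sample axis; each assay's feature index is a subset of the
feature table, so a proteomics and a metabolomics assay can carry different
features. ROIs may overlap; overlap is never deduplicated.

Missing values are IEEE NaN in memory. On text ingestion the strings
`""`, `"NA"`, `"NaN"`, `"null"` — the common proteomics export dialects —
parse to missing, and the count is logged. When an image is attached, the
dataset coordinate origin is the image's bottom-left corner and
registration is (units-per-pixel, x-offset, y-offset); plotting converts to
raster row order internally, so one documented convention replaces per-file
guessing.

Analyses append per-feature statistics to the feature table under
`<analysis-name>__<stat>` columns. Re-running an analysis under the same
name replaces exactly its own columns; assay values and sample metadata are
never touched by a statistical routine.

The on-disk form is a single HDF5 file (groups `/assays`, `/samples`,
`/features`, `/geometries`, `/images`); export to AnnData `.h5ad` (samples
as obs, centroids in `obsm["spatial"]`) is provided for ecosystem interop.
Reading other ecosystems' serialized objects or vendor coordinate formats
is out of scope.

## Missingness and imputation

DDA mass spectrometry misses low-abundance analytes stochastically, so a
missing cell is usually *not* evidence of absence and often
abundance-dependent (MNAR). `calc_missingness` reports the missing fraction
overall (count of missing cells over total cells, which equals the
cell-count-weighted mean of the per-feature fractions) and per
feature/sample.

Eight imputation methods are registered — seven standard and one
spatially-aware — chosen to span MCAR-oriented and MNAR-oriented practice:

| method | imputed value | orientation |
|---|---|---|
| `zero` | 0 | naive baseline |
| `global_min` | matrix-wide minimum | MNAR (detection floor) |
| `half_feature_min` | feature minimum / 2 | MNAR |
| `feature_mean` | feature mean of observed | MCAR |
| `feature_median` | feature median of observed | MCAR |
| `knn_expression` | mean of k expression-nearest samples | MCAR |
| `downshifted_gaussian` | draw from N(μ_f − s·σ_f, (c·σ_f)²) | MNAR |
| `knn_spatial` | mean of k spatially nearest observing samples | spatial |

Every method preserves observed cells bitwise, records method, parameters
and seed in the dataset provenance, and leaves a feature missing (with a
warning) when it has no observed values and the method is feature-local.
The downshifted Gaussian defaults s = 1.8, c = 0.3 follow widespread
label-free proteomics practice for simulating the detection limit; with a
fixed seed the draw is bit-reproducible. Statistics are computed per
feature, which assumes features have been normalized across samples first
(median centering is provided: subtract each sample's observed median;
missing stays missing).

`knn_expression` measures sample distance as the root-mean-square
difference over features observed in both samples; samples sharing fewer
than 3 observed features are ineligible neighbors, which keeps the distance
estimate stable under high missingness.

`knn_spatial` fills cell (f, s) from feature f's values in the k samples
nearest to s by centroid distance, restricted to samples observing f.
Defaults: k = 4 (the cardinal-neighbor count of a grid layout), uniform
weighting, self excluded, distance ties broken by sample-table order for
determinism. Inverse-distance weighting is available; coincident
(distance-0) neighbors then dominate — their plain mean is taken — which is
the defensible limit of 1/d weights without dividing by zero. Fewer than k
observing neighbors falls back to all available with one warning per
feature. With k = n − 1 and uniform weights the method reduces exactly to
the feature mean over observing samples, a useful oracle identity. Both
weightings are offered because the field has no consensus; uniform is the
default as the lower-variance choice on regular grids.

## Feature selection

Tests never impute implicitly: missing values are omitted pairwise, so
imputation remains an explicit, logged step that the analyst chooses.
Abundances are assumed log₂ scale; a `linear_scale` flag log₂-transforms
first, adding half the smallest positive observed value when nonpositive
cells (e.g. zero counts) are present.

**Categorical contrasts.** Per feature, a two-sided Welch t-test (unequal
variances, Welch–Satterthwaite df) between two sample groups, with
`group_b="rest"` giving one-vs-rest; multi-level columns expand to
independent one-vs-rest contrasts. Welch is the default because small-n MS
group variances are rarely equal; a pooled-variance option exists. The
effect size is the difference of group means on the log₂ scale. Features
with fewer than 2 observed values in either group, or zero variance in
both, are flagged undefined and excluded from multiple-testing correction.
Benjamini–Hochberg step-up FDR (q(i) = min over j ≥ i of m·p(j)/j, capped at
1) is applied across defined features.

**Distance gradients.** The distance of sample s to a reference category is
the minimum centroid distance to any reference sample (0 inside the
reference). Per feature, Pearson (p from the t-transform against
Student-t(n−2)) or Spearman correlation between observed abundance and
that distance. Reference samples are excluded by default: their distance is
0 by definition, so including them anchors the regression at an artificial
point; a flag overrides. Features with fewer than 3 usable samples or zero
variance are undefined and excluded from the FDR.

ROIs are treated as independent replicates even when several derive from
the same tissue image or site; no blocking or mixed model is applied. This
is a real limitation for designs with strong per-image batch structure.

## Enrichment

The universe for over-representation is the set of *measured* features
(after filtering), not the whole annotation space — MS detectability bias
otherwise inflates every test. ORA uses the hypergeometric upper tail
P(X ≥ k); sets are first intersected with the universe and those with
fewer than `min_size` (default 5) or more than `max_size` (default 500)
surviving members are not tested.

Gradient (rank-based) enrichment ranks features by a signed statistic
(gradient r, DE t) descending, ties broken by input order, and computes a
weighted Kolmogorov–Smirnov running sum: hits advance by |score|^w
(normalized, w = 1 by default), misses retreat by 1/(N − |S|); the
enrichment score is the extremum, its sign the direction, the hits up to
the extremum the leading edge. The null permutes set membership over the
ranked features n_perm times (default 1000, seed required);
p = (1 + #{|ES_perm| ≥ |ES|}) / (1 + n_perm), the add-one rule that keeps
permutation p-values strictly positive. Sets covering the whole universe
have a degenerate running sum and are excluded. For spatial display, a
set's per-sample score is the mean abundance of its leading-edge members,
exposed as a derived assay the heatmap can paint — a deliberate,
documented reduction, since no standard per-cell enrichment statistic
exists.

## Visualization

Heatmaps draw one filled rectangle or marker per ROI, colored through a
monotone normalization with out-of-range values clamped; samples without a
value get a neutral missing color. The palette defaults to sequential
(viridis) for one-signed values and a zero-centered diverging map when
values span both signs, because signed statistics read best with a neutral
midpoint. Figure dimensions follow the aspect ratio of the coordinate
extent (clipped to [0.4, 2.5]) and never the magnitude. Geographic data
renders in plate-carrée (plain lon/lat axes, equal aspect); boundary
polygons come from a user-supplied GeoJSON — no map data is ever
downloaded. Volcano plots place zero p-values at the largest finite
−log₁₀(p) + 1 with a warning rather than dropping them.

## Synthetic fixtures

The tissue fixture emulates a gridded proteomics experiment: rows × cols
unit rectangles (default 10×10), a compact contiguous block of islet-like
ROIs (default 20, chosen nearest the grid center), and per-feature log₂
abundances μ_f + Δ·[marker, islet] − β·d(s)·[gradient] + N(0, σ²) with
μ_f ~ N(20, 2²). Defaults, chosen once as a realistic regime for
label-free DDA data on a log₂ scale: 500 features, 50 markers with
Δ = 2, 50 gradient features with β = 0.5 per grid unit, σ = 0.5. Markers
model cell-type-specific proteins (insulin-like); gradient features model
secreted/diffusing proteins whose abundance decays with distance from the
source region. Note the gradient features are, by construction, also
differentially expressed between the regions.

The geospatial fixture emulates a soil metagenome survey: 54 sites (two
depths each, 108 samples) at uniform lon/lat within a continental-scale
bounding box, a desert/non-desert split by longitude band (stratified so
both biomes are populated), and per-KO counts from a negative binomial
with low means (2–10) and variance μ + 0.5μ² — the low-abundance,
low-variance character of KO presence counts as opposed to MS intensities.
Six KOs are differential by default: 4 with desert means ×4, 2 with ÷4.

Missingness mechanisms: MCAR drops each cell with the target probability;
MNAR drops cell (f, s) with probability sigmoid(α − 1.5·z(f, s)) where z is
the within-feature z-score — low values vanish preferentially, as at a
detection limit. The slope 1.5 is fixed; only the intercept α is calibrated
(by bisection, 80 iterations) so the expected overall rate matches the
target, because a one-dimensional calibration is robust. The pre-masking
matrix is retained as a `__complete` assay so imputation error is
measurable.

What the fixtures do *not* model: correlated features, per-sample batch
effects, heteroscedastic noise, realistic microscopy content (the bundled
background is a flat gradient image), spatial autocorrelation beyond the
planted block/gradient structure, and compositionality of count data.
Passing tests on these fixtures demonstrate correctness and calibration of
the statistics under their stated assumptions, not performance on any real
tissue or soil dataset.

## Pipelines, determinism, numerical notes

Pipelines are YAML: a global seed, an output directory, and an ordered
stage list. Every stage name and parameter key is validated before any
stage runs; a failure mid-run aborts with the stage name and keeps earlier
outputs. Each produced file enters a manifest with a parameters hash and a
content hash, so deterministic stages are verifiable by re-running.
Stochastic steps (fixtures, downshifted-Gaussian draws, permutation nulls)
take the global seed unless a stage overrides it, and are bit-reproducible
given the same seed.

Numerical choices worth knowing: BH is computed by the vectorized step-up
with NaN p-values carried through untouched and the effective m equal to
the number of defined tests; Pearson/Spearman and Welch statistics come
from SciPy; hypergeometric tails from `scipy.stats.hypergeom.sf` (tested
against exact rational enumeration); distance ties in kNN break by
sample-table order; the weighted-KS hit increment falls back to unweighted
counts if all member scores are exactly zero. Problem sizes in the test
suite and the acceptance script (10×10 grids, 500 features, 500 sets ×
500 permutations, 5–20 seeds per claim) were chosen as the smallest sizes
at which the statistical claims are stable.
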