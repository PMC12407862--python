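# spatomics

Spatial analysis for region-of-interest (ROI) resolved omics data — built
for mass-spectrometry proteomics and metabolomics, where experiments have
few, spatially sparse samples, heavy missingness, and no a-priori genes of
interest. The toolkit is agnostic to what the features are and to the
coordinate scale: the same code analyses micrometer tissue grids and
kilometer-scale environmental surveys.

## What it does

A `SpatialOmicsDataset` binds feature × sample abundance matrices to sample
metadata, feature metadata, one spatial geometry (point or rectangle) per
ROI, and optional registered background images, with planar or lon/lat
coordinates. Around that container:

- **Missingness & imputation** — `calc_missingness` reports missing-cell
  fractions; `impute` offers 7 standard methods (zero, global minimum,
  half feature minimum, feature mean/median, expression-space kNN, and a
  downshifted-Gaussian MNAR draw: imputed values for feature *f* are drawn
  from N(μ_f − s·σ_f, (c·σ_f)²), default s = 1.8, c = 0.3) plus a
  **spatially-aware kNN**: a missing cell (f, s) is filled from feature
  *f*'s values in the *k* ROIs spatially nearest to *s* (Euclidean or
  great-circle distance), uniform or inverse-distance weighted. Neighbors
  are close in *space*, not close in expression.
- **Feature selection** — `spatial_diff_ex` runs per-feature Welch
  two-sample t-tests between ROI categories (log₂ fold change, t, Welch–
  Satterthwaite df, two-sided p, Benjamini–Hochberg FDR);
  `distance_based_analysis` correlates each feature's abundance with the
  distance d(s) = min over reference ROIs of dist(s, ref) (Pearson with the
  t-transform t = r·√((n−2)/(1−r²)), or Spearman).
- **Enrichment** — `enrich_ora`: hypergeometric upper-tail
  over-representation, P(X ≥ k) with N = |universe|, K = |set ∩ universe|,
  n = |selected|, k = |set ∩ selected|; `enrich_gradient`: weighted
  Kolmogorov–Smirnov running-sum enrichment (GSEA-style, weight 1) of a
  signed per-feature statistic with a seeded permutation null,
  p = (1 + #{|ES_perm| ≥ |ES|}) / (1 + n_perm).
- **Visualization** — `spatial_heatmap` paints values at their ROI
  geometries over optional background images or GeoJSON boundaries;
  `volcano_plot` draws effect size vs −log₁₀(p) with up/down counts.
- **Synthetic fixtures** — `generate_tissue_fixture` (islet-like grid with
  planted marker and distance-gradient features) and
  `generate_geospatial_fixture` (lon/lat sites × depths with negative-
  binomial gene-family counts and planted desert/non-desert effects), both
  recording ground truth so sensitivity and FDR are measurable;
  `apply_missingness` masks MCAR or MNAR (logistic in the within-feature
  z-score) to a calibrated rate.
- **Pipelines & CLI** — YAML-configured stage pipelines with validated
  parameters and a content-hashed manifest (`run_pipeline`), and a thin
  `spatomics` command with `ingest`, `missingness`, `impute`, `diffex`,
  `gradient`, `ora`, `gsea`, `heatmap`, `volcano`, `fixture`, `run`
  subcommands.

## Worked example

Desert vs non-desert gene families across 54 soil sampling sites, two
depths each (`examples/05_geospatial_workflow.py`):

```text
108 samples at 54 sites, 300 KOs, coordinate mode: lonlat

top desert vs non-desert KOs:
            log_fc  t_stat  fdr
feature_id
K00003      2.1299  9.8174  0.0
K00000      2.1650  8.4602  0.0
K00004     -2.1036 -8.2520  0.0
K00005     -1.4371 -7.0598  0.0
K00001      1.9964  6.4453  0.0
K00002      1.9157  6.4506  0.0

volcano: 4 up, 2 down (the fixture plants exactly 4 up and 2 down)
wrote ko_map.png: K00003 abundance per site on a lon/lat map
```

The six planted KOs (K00000–K00005) top the ranking; the volcano counts at
FDR < 0.05 and |log₂FC| > 1 recover the planted 4-up/2-down split exactly,
and the heatmap shows the top KO's elevation as a geographic gradient. The
other scripts in `examples/` walk through ingestion (`01`), the imputation
benchmark (`02`, where spatial kNN beats the feature mean on masked cells
of a spatially structured fixture), islet vs non-islet differential
expression with ORA (`03`), and distance-gradient analysis with rank-based
enrichment (`04`).

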