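# Methods

This note documents the models implemented in `ensemblesdm`, the defaults
and the reasoning behind the choices that the workflow itself leaves open.

## Modeling pipeline

### Occurrences and predictors

Occurrence records are WGS84 lon/lat presences. Spatial thinning keeps at
most one point per raster cell and then applies a greedy great-circle pass
in input order: a point survives only if it lies at least `min_dist_km`
(haversine) from every point already kept. Greedy-in-input-order is the
simplest deterministic rule; thinning an already-thinned set is a no-op.

Collinearity among predictors is screened with the pairwise Pearson matrix
over all valid raster cells of the model-fitting extent (computing it at
occurrence cells instead is supported but not the default — with few
presences the cell-based estimate is far more stable). The filter is
greedy: layers are visited in an explicit priority order (default: input
order) and kept iff |r| ≤ 0.75 against every layer already kept. Which
member of a correlated group survives is mathematically underdetermined, so
the priority list is exposed as the reproducibility knob, and the retained
set is *certified* — the code asserts max pairwise |r| ≤ threshold rather
than assuming it.

### Presence/pseudo-absence data

Pseudo-absences (default 10,000) are drawn uniformly, without replacement,
among valid cells not containing a presence. One draw is shared by all
repetitions. At fit time pseudo-absences are down-weighted so the two
classes carry equal total weight (the "prevalence 0.5" convention);
scikit-learn's MLP and LDA do not accept sample weights, so the ANN and FDA
members fit unweighted — with the narrow-niche defaults used here that has
no visible effect on their ranking. Splits are stratified 80/20 per
repetition (3 repetitions), giving 9 × 3 = 27 models.

### The nine algorithms

All scorers map a predictor vector to a presence probability in [0, 1]:

| name   | implementation                                                  |
|--------|-----------------------------------------------------------------|
| GLM    | unpenalized logistic regression on standardized predictors      |
| GBM    | gradient-boosted trees (100 trees, depth 3, lr 0.1)             |
| GAM    | logistic regression on cubic B-spline bases (5 knots)           |
| CTA    | single decision tree (depth ≤ 8, ≥ 5 points/leaf)               |
| ANN    | one-hidden-layer perceptron (8 units, α = 1e-3)                 |
| SRE    | native surface range envelope, presence quantiles q = 0.025     |
| FDA    | shrinkage linear discriminant analysis                          |
| RF     | random forest (200 trees, ≥ 2 points/leaf)                      |
| MAXENT | L1-regularized logistic model on linear + quadratic features    |

MAXENT is an approximation of the maximum-entropy model as a sparse
logistic fit on quadratic features; it honours the same scorer contract and
is documented as an approximation. SRE predicts strictly {0, 1}: 1 iff the
point lies inside the per-predictor presence-quantile envelope on *every*
predictor. Hyperparameters are fixed, conservative, and recorded here —
there is deliberately no tuning stage. A degenerate training fold (one
class) marks that model failed; a suite run collects failures instead of
aborting.

### Evaluation and ensembles

TSS is maximized over candidate cutoffs formed by the midpoints between
consecutive sorted unique scores plus {0, 1}; the smallest maximizing
cutoff is reported, so ties break towards sensitivity. AUC is the
rank-based (Mann–Whitney) statistic with midrank ties.

Ensembles admit members with held-out TSS ≥ 0.8 (inclusive). Committee
averaging votes each member at its own cutoff; the weighted mean uses
TSS-proportional weights (weights ≥ 0, summing to 1). Grids are reported on
the 0–1000 integer scale with half-up rounding, so map class boundaries are
platform-stable.

Ensemble-level AUC/TSS are computed by pooling out-of-fold predictions:
for each repetition, the gated members *of that repetition* are combined on
that repetition's validation rows, and the pooled predictions are scored
once. This keeps the ensemble evaluation strictly out-of-fold; evaluating
all members on all folds would leak training rows across repetitions.

Variable importance follows the permutation convention: permute one
predictor column, re-predict, and report mean over permutations (default 3,
sub-seeded) of max(0, 1 − Pearson r(original, permuted predictions)). The
table layout is variables × algorithms plus a Mean column.

### Range change

Current and future ensemble grids are binarized at the cutoff that
maximizes the ensemble's pooled out-of-fold TSS on *current* data; the same
cutoff applies to future projections. Percentages are relative to the
current range (Loss + Stable); `range_change = percent_gain −
percent_loss`. Counts conserve valid pixels and are antisymmetric under
time reversal (loss ↔ gain). Percentages are kept unrounded internally and
rounded to 3 decimals only at serialization. The change map codes
loss = −2, absent = −1, stable = 1, gain = 2.

### Niche dynamics

PCA-env is calibrated on the *pooled* centered+scaled backgrounds of the
two periods, so both are projected with one set of loadings. Each entity in
a comparison is, by default in the pipeline, a sample (≤ 1,000 cells) of
the cells the weighted ensemble predicts suitable in that period; the
background is all valid cells (subsampled to ≤ 10,000, seeded). Kernel
densities use a product-Gaussian kernel with the bivariate
Silverman/Scott bandwidth per axis, h = σ·n^(−1/6); occupancy is
z ∝ occ/env on background support, normalized to sum 1 on the 100×100 grid
spanning the pooled background extremes.

The equivalency test reassigns the pooled occurrence sets to groups of the
original sizes (default alternative "lower": reject when observed D is low
relative to the null). The similarity test translates niche 2's point cloud
so its centroid lands uniformly at random inside its background envelope,
wrapping coordinates at the grid edges (default alternative "greater").
Both alternatives are overridable, p = (count + 1)/(reps + 1), default
reps = 99. Under the null with reps = 99, the p ≤ 0.05 rejection rule is
exact by exchangeability, which the test suite confirms by simulation
(type-I error over 500 null datasets, run at a scaled-down grid of R = 24
with 30 + 30 points per group).

## Synthetic data: what it does and does not emulate

The generator produces standardized, spatially autocorrelated Gaussian
layers (Gaussian-smoothed white noise, autocorrelation length
`spatial_range` cells, default 4) with an *exactly* imposed cross-layer
correlation matrix (empirical whitening followed by recoloring with the
target's matrix square root). Default study conditions: 6 layers on a
120×120 grid at 0.05° resolution, one layer pair correlated at r = 0.85 to
exercise the collinearity filter, 2% shared nodata.

The virtual species is a product of Gaussian responses on two driving
layers (optima 0.8 and −0.4, widths 0.25 and 0.35 in layer standard
deviations, the first dominant), rescaled to peak 1 — a narrow-niche
specialist occupying ~3% of the landscape, which matches the intended use
case of modeling a range-restricted montane herb. Presences (default 250)
are drawn without replacement with probability proportional to true
suitability, one per cell. Scenario shifts are per-layer affine maps:
"contraction" cools the dominant driving layer by 1.5 sd so suitable
conditions retreat into the field's upper tail; "expansion" compresses the
driving layers toward the optima (x′ = μ + 0.5(x − μ)), enlarging the
suitable area. Both directions are therefore known a priori and downstream
sign checks are against ground truth.

Not emulated: realistic GCM structure or inter-variable physics, dispersal
limits, sampling bias beyond uniform, and observation error in coordinates.
Passing tests show the pipeline's statistics behave correctly on clean,
well-specified data; they say nothing about robustness to biased sampling
or non-Gaussian predictor fields.

## Numerical and I/O choices

* GeoTIFF I/O is implemented on tifffile, writing the standard
  georeferencing tags (ModelPixelScale, ModelTiepoint, a minimal
  GeoKeyDirectory with the EPSG code, GDAL_NODATA = −9999); layers are
  float32 single-band files plus a JSON manifest. Grids must agree on the
  transform to within 1e-6.
* Cell membership uses half-open intervals; points exactly on an interior
  edge assign to the lower-index cell.
* One global seed fans out to named per-stage sub-seeds via a crc32-hashed
  `SeedSequence`, so stage results are independent of call order and
  identical config+seed reruns are byte-identical.
* Density grids treat background support as env_density > 1e-12 × max;
  z is defined as 0 off support.
* Zero-variance layers yield undefined correlations; they are reported as
  missing and dropped with a warning during selection.

## Known limitations

* MAXENT and GAM are scikit-learn approximations of their classical
  namesakes; their scores are well-calibrated members of the ensemble but
  not drop-in replacements for the original implementations.
* The similarity test shifts only the second niche by default (flag to
  reverse); shifting both is not implemented.
* Committee/weighted are the only ensemble rules; no Kappa/Boyce metrics,
  no VIF-based filtering, no spatial block cross-validation, no
  dispersal-constrained range-change variants.
* Correlation filtering is threshold-greedy; it makes no claim of
  optimality (e.g. maximum retained subset).
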