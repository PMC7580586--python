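# Methods

This note records the statistical model behind `elementscape`, the
choices made where the underlying methodology is open, and what the
synthetic test landscape does and does not establish about real data.

## Data model and grid conventions

Samples are individuals with a WGS84 lon/lat location and a vector of
14 trace-element concentrations (ppb) measured in fur. All spatial
work happens on regular lon/lat rasters with square cells (default
0.16°, ~315 km² at mid-latitudes, shrinking poleward). Cell (0, 0) is
the north-west cell, rows grow southward, and a cell's representative
point is its center (`origin + (index + 0.5)·cellsize`). Distances
that matter physically (IDW weights, the nightly-travel buffer) use
the haversine formula in km on the IUGG mean-radius sphere; kernel
bandwidths for the spatially weighted PCA use plain degree distances,
matching how bandwidths are usually quoted for geographically
weighted models. Rasters are read and written as ESRI ASCII grids
(plain text, NODATA → NaN); sample tables are CSV; range polygons are
GeoJSON rasterized by a cell-center-in-polygon test.

## Outlier screening and transfer regressions

Profiles can be screened by squared robust Mahalanobis distance from
a minimum-covariance-determinant (MCD) location/scatter fit, flagged
above the χ²(df = 14) quantile (default 0.975). The MCD subset search
is order-sensitive, so the fit runs on canonically sorted rows to
make flags invariant to input ordering. Screening never auto-drops
samples in library use; the CLI drops flagged samples only when
`preprocess.screen_outliers` is enabled.

The soil→fur transfer is ordinary least squares per element with fur
as the response — the direction matter moves through the food web.
Slope, intercept, R², the two-sided slope *p* from the *t*
distribution and the residual SD (n−2 denominator) are retained. On
real fur these relationships are weak (all R² < 0.16, three of 14
elements significant at 0.05), which is why assignment uses a
multivariate summary rather than single elements.

## Spatially weighted PCA

At every sample location the covariance of *globally standardized*
concentrations (each element centered and scaled by its mean and
ddof-1 SD) is computed with kernel weights normalized to sum to one,
and eigendecomposed. Standardization on the correlation scale is
forced by the data: element abundances span three orders of
magnitude, and a raw-covariance PCA would be an Fe/Mg axis.

* **Kernels:** bisquare (default), Gaussian, uniform. An integer
  bandwidth is adaptive — the per-location distance to the k-th
  nearest sample — a float is a fixed degree radius.
* **Bandwidth selection:** leave-one-out cross-validation. For each
  candidate, each sample is held out, local components at its
  location are fitted from the rest, and the squared residual of the
  held-out standardized profile after projection onto the leading
  component(s) is accumulated; the candidate minimizing the total
  wins. Candidates default to eight neighbor counts spanning
  10–100% of n.
* **Determinism:** eigenvalues sorted descending; every loading
  vector is flipped so its largest-magnitude entry is positive, which
  pins results across eigendecomposition backends.
* **Summary loadings:** the per-location loadings of a component are
  sign-aligned to the first location's vector, averaged element-wise
  (median available), and renormalized. This reduction from
  location-varying loadings to one table is a pragmatic
  reconstruction; with moderate-to-large bandwidths local loadings
  vary little and the summary is stable.
* **Retention:** the Kaiser rule (eigenvalue > 1) applied to the mean
  eigenvalue spectrum rescaled to sum to the number of elements
  (correlation scale). Only PC1 is carried into assignment by
  default.
* **Scoring:** by default scores are the dot product of *raw* ppb
  concentrations with the summary loadings. With an
  (almost-)everywhere-positive PC1 loading this keeps scores positive
  and on an interpretable ppb-weighted scale; it also makes the
  score of the mean profile equal the sum of the per-element weights
  (loading × mean). Standardized scoring is available
  (`mode="standardized"`) and shifts scores to straddle zero without
  changing their ordering.
* **Spatial structure test:** Monte-Carlo permutation of scores over
  locations with global Moran's I (inverse-distance weights) as the
  statistic, `p = (1 + #{I_perm ≥ I_obs}) / (n_perm + 1)`. The
  statistic choice is ours; any spatial-structure statistic could be
  substituted.

## Basemap

The **direct** portion interpolates sample scores by global-
neighborhood IDW with power 2 (the conventional GIS default), exactly
honoring sample values at their own cells, and is clipped to the
convex hull of the sample locations (optionally buffered in degrees)
— scores are only trusted where samples constrain them. The
**indirect** portion converts soil grids through the per-element
transfer fits to hypothetical fur (truncated at 0) and scores it with
the same summary loadings. Merging is a hard partition: in-range
cells take the direct value inside the hull, the indirect value
outside, with no blending — the seam is left visible rather than
contaminating the better-constrained direct surface.

**Assignment σ.** σ is the residual SD (n−2) from the OLS of actual
sample scores on basemap-predicted scores at their cells. Predicted
values are computed by *leave-one-out* IDW — each sample predicted
from all the others — because plain IDW is exact at its own nodes and
would drive σ toward zero, making every assignment impossibly
confident. The LOO calibration uses only training samples, so no
held-out information leaks into σ. A fixed σ can be supplied instead;
the study-scale convention is σ² = 9.696 (σ ≈ 3.11). That published
phrasing is ambiguous between σ and σ²; we treat 9.696 as the
variance (the parenthetical symbol is σ²) with a switch
(`sigma_is_variance`) for the other reading.

## Assignment and its scoring

The per-cell likelihood is the normal density of the individual's
score y* around the cell prediction μ_i, divided by its theoretical
maximum 1/(σ√2π) so values land in [0, 1]. The raw density cannot
exceed ≈ 0.128 at σ ≈ 3.11, so the published practice of reading the
result as a 0–1 probability implies exactly this normalization; raw
density mode is retained behind `normalize=False`.

Correctness uses ≥ (not >) at the threshold, and the 10-km buffer
scans *cell centers* within the haversine radius — a deterministic
rule, rather than any polygon-overlap test. Precision (range
fraction) weights cells by cos(latitude) since equal-degree cells
shrink poleward. With a 0.16° cell and a 10-km radius the buffer
usually adds only the immediate neighbors of the sampling cell.

## Cross-validation

Leave-k-out (default k = 3, 100 replicates): each replicate draws k
held-out individuals without replacement — independently across
replicates, so triples may recur — rebuilds summary loadings, scores,
both basemap portions, the transfer fits and σ from the n−k training
individuals only, then assigns the held-out individuals. Pooled
accuracy counts buffer rescues; precision averages range fractions
over correctly assigned individuals only, since an incorrect
assignment's "precision" describes the wrong place. A threshold sweep
re-classifies every held-out surface at 0.5/0.66/0.75. Reports are
plain dataclasses serialized to JSON; identical seeds give
byte-identical reports.

σ is re-estimated inside every replicate from training residuals by
default (no leakage). A fixed-σ mode reproduces the single-global-σ
convention. The two modes answer different questions: with honest
per-replicate calibration, threshold-0.5 accuracy converges to the
~76% a well-calibrated normal model yields by construction
(P(|z| ≤ √(2 ln 2)) under z ~ N(0,1)) regardless of how informative
the landscape is — the signal shows up in *precision*. Under a fixed
σ the probability scale is absolute, and accuracy also separates
informative from uninformative landscapes.

## Synthetic landscape

Per element, soil is `baseline + linear gradient + Σ signed Gaussian
bumps`, truncated at 0 — tunable spatial autocorrelation with
closed-form ground truth. Fur at a uniform-random origin is
`a + b·soil(origin cell) + N(0, τ)`, truncated at 0. Three presets:

* `strong_signal_config` — element gradients fanned across 14
  directions (3 ppb/degree), mild bumps, τ = 3 ppb: origin is
  recoverable; used for recovery and regression tests.
* `no_signal_config` — soil varies mildly but transfer slope is 0 and
  τ = 20 ppb: fur carries no geographic information. Soil still
  varies so the transfer regression stays well-posed; the fitted
  slopes are then ≈ 0.
* `weak_transfer_config` — τ set from the soil field's spatial
  variance so realized per-element fur~soil R² ≈ 0.1, emulating the
  coupling strength of real fur (R² < 0.16).

Default scale: a 24° × 12° region (the aspect of an eastern North
American study range, on an abstract rectangle) at 0.16° cells, 126
individuals (a realistic museum-collection validation set); tests and
the acceptance script use 30–60 individuals and 3–30 replicates to
keep everything interactive on one core. What the synthetic results
do **not** show: truncation at 0 is not log-normal (real Fe has
SD > mean; heavy right tails can be emulated by bump amplitude but are
not default), elements are generated independently (real elements
co-vary geochemically), origins are uniform rather than
habitat-weighted, and soil is observed without survey error. Passing
tests demonstrate the machinery is correct and that the pipeline
recovers planted signal — not that any particular species' fur
carries signal of that strength.

## Numerical notes

* Concentrations are validated non-negative at ingest; NaN anywhere
  in a profile is a hard error naming the sample.
* CSV round-trips use `%.17g` on write and round-trip float parsing
  on read, preserving doubles exactly.
* Coincident samples in IDW average their values at the shared cell;
  a sample exactly on a cell center takes precedence over weighting.
* Degenerate cases raise rather than guess: all-zero summary
  loadings, singular scatter in MCD, constant soil predictor, perfect
  σ fit (σ = 0), collinear convex hulls (buffer suggested), k ≥ n.
* Permutation tests with constant scores return p = 1 with a warning
  (Moran's I undefined).
* Seeds: per-element soil fields use independent `SeedSequence([seed,
  element_index])` streams, so adding an element never perturbs the
  others; profile draws use a separate stream.
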