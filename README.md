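# elementscape

Likelihood-of-origin geographic assignment from trace-element tissue
chemistry, built for migratory-wildlife movement studies — the
motivating case is sourcing migratory bats (e.g. the eastern red bat,
*Lasiurus borealis*) killed at wind-energy facilities back to the
summer molting grounds where their fur was grown.

The idea: trace-element concentrations in fur reflect, through the
food web, the element composition of local soil, which varies across
continental scales. A multivariate summary of an individual's
14-element fur profile (Al, Ni, Cu, Rb, Y, Mo, Sn, Ba, Cs, Ce, Hg,
Mg, Mn, Fe, in ppb) therefore carries a geographic signature that can
be compared against a continuous *basemap* of predicted values.

## The model

1. **Spatially weighted PCA.** Element profiles are standardized and
   summarized with a geographically weighted PCA: at every sample
   location the correlation-scale covariance is computed with kernel
   weights `w_ij = K(d_ij / b)` (bisquare kernel, bandwidth `b`
   selected by leave-one-out cross-validated reconstruction error) and
   eigendecomposed. Sign-aligned local PC1 loadings are averaged into
   one summary loading vector; each individual's score is
   `y* = x · v₁` on the raw concentration vector `x`.
2. **Basemap.** Inside the convex hull of the sampled locations the
   PC1 surface `μ_i` is interpolated from sample scores by inverse
   distance weighting (`w_j = d_j⁻²`, haversine distances). Beyond it,
   per-element OLS transfer fits `fur_e = a_e + b_e · soil_e` turn soil
   grids into hypothetical fur, scored with the same loadings. The two
   portions are merged with no seam smoothing.
3. **Assignment.** For an individual with score `y*`, each cell `i`
   gets the normal density
   `f(y*|μ_i, σ) = (σ√2π)⁻¹ exp(−(y*−μ_i)²/(2σ²))`, normalized by its
   maximum so values span [0, 1]. σ is the residual SD of actual vs
   basemap-predicted scores (study-scale default σ² = 9.696). An
   assignment is *correct* when the value at the true cell is ≥ 0.5,
   or when any cell center within 10 km (a night's flight from a
   roost) reaches it; *precision* is the fraction of the range at or
   above the threshold — smaller is better.
4. **Evaluation.** Leave-three-out cross-validation (default 100
   replicates) rebuilds the whole pipeline per replicate and reports
   pooled accuracy and correct-only precision, plus a threshold sweep
   (0.5 / 0.66 / 0.75).

A `synthetic_landscape` module generates soil grids (baseline +
gradient + Gaussian bumps) and known-origin fur profiles with the
weak soil→fur coupling (per-element R² < 0.16) and high dispersion
real fur shows, so the full pipeline runs and is tested at desk scale
without external soil-survey or museum data.

## Worked example

```python
import numpy as np
from elementscape import *
from elementscape.evaluation import EvalConfig, leave_k_out_cv
from elementscape.gwpca import variance_table
from elementscape.preprocess import fit_element_regressions, soil_at_locations
from elementscape.assignment import classify_assignment
from elementscape.synthetic_landscape import strong_signal_config

cfg = strong_signal_config(seed=1, n_individuals=60)
soil = generate_soil_grids(cfg)
profiles, truth = sample_fur_profiles(soil, cfg)

model = fit_gwpca(profiles, bandwidth=36)       # adaptive, 36 neighbors
print(variance_table(model).head(3).round(3))

mask = RangeMask.full(soil.template)
regs = fit_element_regressions(profiles, soil_at_locations(soil, profiles))
bm, scores = build_basemap(profiles, model, mask, soil=soil,
                           regressions=regs, hull_buffer_degrees=0.5)
print(f"sigma = {bm.sigma:.3f}")

surf = likelihood_surface(scores.component(0)[0], bm)
res = classify_assignment(surf, profiles.lons[0], profiles.lats[0],
                          sample_id=profiles.ids[0])
print(f"{res.sample_id}: probability {res.probability:.2f}, "
      f"range fraction {res.range_fraction:.2f}, correct={res.correct}")

report = leave_k_out_cv(profiles, soil, mask, EvalConfig(k=3, reps=30, seed=1))
print(f"CV accuracy {report.accuracy:.3f}, "
      f"mean range fraction {report.mean_range_fraction:.3f}")
```

prints

```
component  eigenvalue  correlation_scale_eigenvalue  proportion  retained
      PC1       3.011                         7.914       0.565      True
      PC2       1.741                         4.577       0.327      True
      PC3       0.177                         0.466       0.033     False
sigma = 8.079
synth-0000: probability 1.00, range fraction 0.19, correct=True
CV accuracy 0.789, mean range fraction 0.252
```

PC1 captures 56% of element variation on this landscape; the first
individual's own cell is a perfect match (probability 1.00) and its
candidate-origin area is 19% of the region. Across the leave-three-out
replicates, 79% of held-out individuals are assigned correctly while
the plausible origin area is cut to ~25% of the range.

The same pipeline runs from the shell:

```bash
elementscape all -c config.yaml --seed 1 --out run1
```

with subcommands `simulate`, `fit`, `basemap`, `assign`, `evaluate`
for individual stages (see `elementscape --help`). Inputs are plain
CSV sample tables, ESRI ASCII element rasters and GeoJSON range
polygons.

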