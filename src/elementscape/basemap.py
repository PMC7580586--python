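"""Continuous PC1 prediction surfaces ("basemaps").

The basemap predicts the PC1 fur score at every grid cell inside a
species range. Where samples exist the surface comes directly from
inverse-distance-weighted (IDW) interpolation of sample scores
("direct" portion, limited to the convex hull of the sample
locations). Elsewhere it comes indirectly: soil concentrations are
passed through the per-element transfer regressions to hypothetical
fur concentrations, which are scored with the same summary loadings
("indirect" portion). The two portions are merged with no seam
smoothing — each cell is owned by exactly one portion — preserving the
more trustworthy direct surface verbatim.

The assignment standard deviation sigma is the residual SD (n-2
denominator) of the regression of actual sample scores on the scores
the basemap predicts at their cells. The study-scale default when no
calibration pairs are supplied is sigma^2 = 9.696.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats
from shapely.geometry import MultiPoint
import shapely

from elementscape.geo import haversine_km
from elementscape.gwpca import GWPCAModel, ScoreSet, score_samples, summarize_loadings
from elementscape.io_formats import ElementProfileSet, RangeMask, RasterGrid, SoilGridSet
from elementscape.preprocess import ElementRegressionSet

DEFAULT_SIGMA_SQUARED = 9.696
DEFAULT_IDW_POWER = 2.0

REGION_OUTSIDE = 0
REGION_DIRECT = 1
REGION_INDIRECT = 2


@dataclass
class Basemap:
    """Predicted-score raster with per-cell provenance and assignment sigma.

    ``regions`` holds 0 (outside range), 1 (direct) or 2 (indirect)
    per cell; every in-range cell has a finite predicted value.
    """

    mu: RasterGrid
    regions: np.ndarray
    sigma: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.regions = np.asarray(self.regions, dtype=int)
        if self.regions.shape != self.mu.shape:
            raise ValueError("region labels must match the raster shape")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        in_range = self.regions != REGION_OUTSIDE
        if not np.isfinite(self.mu.values[in_range]).all():
            raise ValueError("non-finite predicted value inside the range")

    @property
    def in_range(self) -> np.ndarray:
        return self.regions != REGION_OUTSIDE


def idw_interpolate(scores: ScoreSet, template: RasterGrid,
                    power: float = DEFAULT_IDW_POWER,
                    component: int = 0) -> RasterGrid:
    """Inverse-distance-weighted surface of sample scores.

    Cell value = sum(w_j y_j) / sum(w_j) with w_j = d_j^-power and d_j
    the haversine distance (km) from the cell center to sample j. A
    cell whose center coincides with a sample takes that sample's
    value exactly (mean over coincident samples).
    """
    if len(scores.ids) == 0:
        raise ValueError("IDW needs at least one scored sample")
    if power <= 0:
        raise ValueError("IDW power must be positive")
    y = scores.component(component)
    lon, lat = template.centers()
    out = np.empty(template.shape)
    # distances: (n_cells, n_samples)
    d = haversine_km(lon.ravel()[:, None], lat.ravel()[:, None],
                     scores.lons[None, :], scores.lats[None, :])
    exact = d <= 1e-9
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    flat = np.empty(d.shape[0])
    has_exact = exact.any(axis=1)
    if has_exact.any():
        # nodes: mean of coincident samples
        masked = np.where(exact, y[None, :], np.nan)
        flat[has_exact] = np.nanmean(masked[has_exact], axis=1)
    rest = ~has_exact
    flat[rest] = (w[rest] @ y) / w[rest].sum(axis=1)
    out[:] = flat.reshape(template.shape)
    return template.copy_with(out)


def direct_extent(profiles_or_scores, template: RasterGrid,
                  buffer_degrees: float = 0.0) -> np.ndarray:
    """Boolean mask of cells whose center lies in the convex hull of the
    sample locations (optionally buffered, degrees)."""
    lons = np.asarray(profiles_or_scores.lons, float)
    lats = np.asarray(profiles_or_scores.lats, float)
    if len(lons) < 3:
        raise ValueError("direct extent needs at least 3 samples")
    hull = MultiPoint(list(zip(lons, lats))).convex_hull
    if buffer_degrees:
        hull = hull.buffer(buffer_degrees)
    if hull.area == 0:
        raise ValueError(
            "sample locations are collinear; pass a positive buffer_degrees"
        )
    lon, lat = template.centers()
    return shapely.contains_xy(hull, lon.ravel(), lat.ravel()).reshape(template.shape)


def indirect_surface(soil: SoilGridSet, regressions: ElementRegressionSet,
                     summary_loading: np.ndarray,
                     elements: list[str] | None = None) -> RasterGrid:
    """Score hypothetical fur predicted from soil at every cell.

    Per cell: hypothetical fur_e = max(intercept_e + slope_e * soil_e, 0),
    then the dot product with the summary loading (raw scoring mode,
    matching ``score_samples``).
    """
    elements = elements if elements is not None else soil.elements
    missing = [e for e in elements if e not in regressions.regressions]
    if missing:
        raise ValueError(f"no transfer regression for element(s) {missing}")
    summary_loading = np.asarray(summary_loading, float).ravel()
    if summary_loading.size != len(elements):
        raise ValueError("loading length does not match element list")
    template = soil.template
    out = np.zeros(template.shape)
    for coef, element in zip(summary_loading, elements):
        fur = regressions.predict_fur(element, soil[element].values)
        out += coef * fur
    return template.copy_with(out)


def merge_basemap(direct: RasterGrid, direct_mask: np.ndarray,
                  indirect: RasterGrid | None, range_mask: RangeMask,
                  sigma: float, metadata: Mapping | None = None) -> Basemap:
    """Combine direct and indirect surfaces into one basemap.

    In-range cells take the direct value where the direct mask is
    true, otherwise the indirect value; there is no blending at the
    seam. Out-of-range cells are no-data. ``indirect=None`` restricts
    the basemap to the direct portion of the range.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if not direct.same_grid(range_mask.grid):
        raise ValueError("direct surface and range mask are on different grids")
    if indirect is not None and not direct.same_grid(indirect):
        raise ValueError("direct and indirect surfaces are on different grids")
    direct_mask = np.asarray(direct_mask, bool)
    rng_mask = range_mask.mask
    regions = np.full(direct.shape, REGION_OUTSIDE, dtype=int)
    regions[rng_mask & direct_mask] = REGION_DIRECT
    if indirect is not None:
        regions[rng_mask & ~direct_mask] = REGION_INDIRECT
    mu = np.full(direct.shape, np.nan)
    mu[regions == REGION_DIRECT] = direct.values[regions == REGION_DIRECT]
    if indirect is not None:
        mu[regions == REGION_INDIRECT] = indirect.values[regions == REGION_INDIRECT]
    return Basemap(direct.copy_with(mu), regions, float(sigma),
                   dict(metadata or {}))


def loo_idw_predictions(scores: ScoreSet, template: RasterGrid,
                        power: float = DEFAULT_IDW_POWER,
                        component: int = 0) -> np.ndarray:
    """Leave-one-out IDW prediction at each sample's cell center.

    Used to calibrate the assignment sigma: IDW is exact at its own
    nodes, so predicting each sample from all the *other* samples is
    the honest measure of how well the surface predicts a score at a
    location it has not seen.
    """
    y = scores.component(component)
    n = y.size
    if n < 2:
        raise ValueError("leave-one-out prediction needs at least 2 samples")
    centers = np.array([
        # evaluate at the center of the cell containing the sample
        template.center_of(*template.cell_of(lo, la))
        for lo, la in zip(scores.lons, scores.lats)
    ])
    d = haversine_km(centers[:, 0][:, None], centers[:, 1][:, None],
                     scores.lons[None, :], scores.lats[None, :])
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    out = np.empty(n)
    for j in range(n):
        wj = w[j].copy()
        wj[j] = 0.0
        exact = (d[j] <= 1e-9) & (np.arange(n) != j)
        if exact.any():
            out[j] = y[exact].mean()
        elif np.isfinite(wj).all() and wj.sum() > 0:
            out[j] = (wj @ y) / wj.sum()
        else:
            # another sample coincides with this cell center
            coincident = np.isinf(wj)
            out[j] = y[coincident].mean()
    return out


def estimate_sigma(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Assignment sigma: residual SD of OLS actual ~ predicted, n-2
    denominator. A perfect fit is a degenerate assignment model."""
    predicted = np.asarray(predicted, float)
    actual = np.asarray(actual, float)
    if predicted.shape != actual.shape or predicted.ndim != 1:
        raise ValueError("predicted and actual must be matching 1-D arrays")
    n = predicted.size
    if n < 3:
        raise ValueError("sigma estimation needs at least 3 pairs")
    if np.ptp(predicted) == 0:
        resid = actual - actual.mean()
    else:
        res = stats.linregress(predicted, actual)
        resid = actual - (res.intercept + res.slope * predicted)
    sigma = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    if sigma == 0:
        raise ValueError("all residuals are zero: degenerate assignment model")
    return sigma


def surface_correlation(map_a: Basemap | RasterGrid, map_b: Basemap | RasterGrid,
                        n_points: int = 150, seed: int = 0) -> float:
    """Pearson correlation of the two maps at random in-range cell centers.

    Cells must be valid (finite, in-range) on both maps; sampling is
    uniform over those cells with replacement-free draws.
    """
    if n_points < 3:
        raise ValueError("need at least 3 points")
    a_vals, a_ok = _map_values(map_a)
    b_vals, b_ok = _map_values(map_b)
    if a_vals.shape != b_vals.shape:
        raise ValueError("maps are on different grids")
    ok = a_ok & b_ok
    idx = np.flatnonzero(ok)
    if idx.size < 3:
        raise ValueError("fewer than 3 overlapping valid cells")
    rng = np.random.default_rng(seed)
    pick = rng.choice(idx, size=min(n_points, idx.size), replace=False)
    x = a_vals.ravel()[pick]
    y = b_vals.ravel()[pick]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant surface in the sampled cells")
    return float(np.corrcoef(x, y)[0, 1])


def _map_values(m: Basemap | RasterGrid) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(m, Basemap):
        return m.mu.values, m.in_range & np.isfinite(m.mu.values)
    return m.values, np.isfinite(m.values)


def build_basemap(
    profiles: ElementProfileSet,
    model: GWPCAModel,
    range_mask: RangeMask,
    template: RasterGrid | None = None,
    soil: SoilGridSet | None = None,
    regressions: ElementRegressionSet | None = None,
    idw_power: float = DEFAULT_IDW_POWER,
    hull_buffer_degrees: float = 0.0,
    scoring_mode: str = "raw",
    sigma: float | None = None,
) -> tuple[Basemap, ScoreSet]:
    """Convenience pipeline: summary loadings -> scores -> direct IDW
    surface + optional indirect surface -> merged basemap with sigma.

    ``sigma=None`` estimates sigma from predicted-vs-actual scores at
    the sample cells; pass a fixed value (e.g. sqrt(9.696)) to mirror a
    pre-calibrated assignment model.
    """
    template = template if template is not None else range_mask.grid
    summary = summarize_loadings(model)
    scores = score_samples(summary, profiles, model=model, mode=scoring_mode)
    direct = idw_interpolate(scores, template, power=idw_power)
    dmask = direct_extent(scores, template, hull_buffer_degrees)
    indirect = None
    if soil is not None and regressions is not None:
        if scoring_mode != "raw":
            raise ValueError("the indirect surface is defined for raw scoring only")
        indirect = indirect_surface(soil, regressions, summary[0],
                                    elements=model.elements)
    if sigma is None:
        predicted = loo_idw_predictions(scores, template, power=idw_power)
        sigma = estimate_sigma(predicted, scores.component(0))
    meta = {"idw_power": idw_power, "kernel": model.kernel,
            "bandwidth": model.bandwidth, "scoring_mode": scoring_mode}
    bm = merge_basemap(direct, dmask, indirect, range_mask, sigma, meta)
    return bm, scores
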