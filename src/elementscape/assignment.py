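"""Likelihood-of-origin surfaces and assignment scoring.

Given an individual's PC score y* and a basemap of predicted cell
values mu_i with assignment SD sigma, the likelihood that the
individual originated in cell i is the normal density

    f(y* | mu_i, sigma) = (1 / (sigma sqrt(2 pi))) exp(-(y* - mu_i)^2 / (2 sigma^2))

By default the density is normalized by its theoretical maximum
1/(sigma sqrt(2 pi)), giving per-cell values
f_i = exp(-(y* - mu_i)^2 / (2 sigma^2)) in [0, 1] — 1 where the map
predicts exactly y*. Raw-density mode is available via
``normalize=False``.

An assignment is *correct* when the value at the true (sampling) cell
meets the threshold (default 0.5), or — the buffer rescue — when any
cell whose center lies within a nightly-travel buffer (default 10 km,
haversine) of the true location meets it. *Precision* is the fraction
of in-range area at or above the threshold (smaller = more precise),
with cell areas weighted by cos(latitude) since degree cells shrink
poleward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from elementscape.basemap import Basemap
from elementscape.geo import haversine_km
from elementscape.io_formats import RangeMask, RasterGrid

DEFAULT_THRESHOLD = 0.5
DEFAULT_BUFFER_KM = 10.0


@dataclass
class AssignmentSurface:
    """Per-cell likelihood of origin for one individual."""

    grid: RasterGrid          # normalized (or raw) likelihood; NaN out of range
    in_range: np.ndarray
    y_star: float
    sigma: float
    normalized: bool = True

    def probability_at(self, lon: float, lat: float) -> float:
        """Likelihood value of the cell containing the location."""
        row, col = self.grid.cell_of(lon, lat)
        if not self.in_range[row, col]:
            raise ValueError(f"location ({lon}, {lat}) is outside the range")
        return float(self.grid.values[row, col])


@dataclass
class AssignmentResult:
    """Bookkeeping for one individual's assignment."""

    sample_id: str
    probability: float        # likelihood at the true/sampling cell
    correct: bool
    rescued: bool             # correct only via the buffer rule
    range_fraction: float     # in-range area fraction >= threshold
    threshold: float
    y_star: float = np.nan


def likelihood_surface(y_star: float, basemap: Basemap,
                       normalize: bool = True) -> AssignmentSurface:
    """Evaluate the origin likelihood of a score y* over every in-range cell."""
    if not np.isfinite(y_star):
        raise ValueError("y* must be finite")
    sigma = basemap.sigma
    mu = basemap.mu.values
    f = np.exp(-((y_star - mu) ** 2) / (2.0 * sigma**2))
    if not normalize:
        f = f / (sigma * np.sqrt(2.0 * np.pi))
    f = np.where(basemap.in_range, f, np.nan)
    return AssignmentSurface(basemap.mu.copy_with(f), basemap.in_range.copy(),
                             float(y_star), float(sigma), normalize)


def probability_at(surface: AssignmentSurface, lon: float, lat: float) -> float:
    return surface.probability_at(lon, lat)


def cell_areas_km2(grid: RasterGrid) -> np.ndarray:
    """Approximate cell areas: (cellsize * 111.195 km)^2 * cos(latitude)."""
    km_per_deg = np.pi / 180.0 * 6371.0088
    _, lat = grid.centers()
    return (grid.cell_size * km_per_deg) ** 2 * np.cos(np.radians(lat))


def range_fraction(surface: AssignmentSurface, threshold: float,
                   range_mask: RangeMask | None = None) -> float:
    """Fraction of in-range area with likelihood >= threshold
    (latitude-aware cell areas)."""
    mask = surface.in_range if range_mask is None else (
        surface.in_range & range_mask.mask)
    if not mask.any():
        raise ValueError("empty range")
    areas = cell_areas_km2(surface.grid)
    above = mask & (surface.grid.values >= threshold)
    return float(areas[above].sum() / areas[mask].sum())


def classify_assignment(
    surface: AssignmentSurface,
    true_lon: float,
    true_lat: float,
    threshold: float = DEFAULT_THRESHOLD,
    buffer_km: float = DEFAULT_BUFFER_KM,
    sample_id: str = "",
) -> AssignmentResult:
    """Score one individual against its known origin.

    Correct when the cell containing the true location is >= threshold,
    or when any in-range cell center within ``buffer_km`` (haversine)
    of the true location is >= threshold (rescued). ``buffer_km=0``
    reduces to the pure threshold rule.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if buffer_km < 0:
        raise ValueError("buffer_km must be >= 0")
    prob = surface.probability_at(true_lon, true_lat)
    correct = prob >= threshold
    rescued = False
    if not correct and buffer_km > 0:
        lon, lat = surface.grid.centers()
        near = surface.in_range & (
            haversine_km(lon, lat, true_lon, true_lat) <= buffer_km
        )
        if near.any() and np.nanmax(surface.grid.values[near]) >= threshold:
            correct = True
            rescued = True
    frac = range_fraction(surface, threshold)
    return AssignmentResult(sample_id, prob, bool(correct), rescued, frac,
                            threshold, surface.y_star)
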