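"""Geographically weighted PCA of element profiles.

At every sample location the covariance of the (globally standardized)
element concentrations is computed with kernel weights that decay with
distance, and eigendecomposed, so loadings and eigenvalues can vary
across space. A single summary loading vector per component is then
obtained by averaging sign-aligned local loadings; sample scores are
the dot product of concentrations with the summary loadings.

Conventions
-----------
* Standardization: each element is centered and scaled by its global
  mean/SD (SD with n-1 denominator) before the weighted covariance, so
  the analysis runs on the correlation scale. Elements span several
  orders of magnitude in ppb; raw-covariance PCA would be dominated by
  the most abundant ones.
* Kernel weights are normalized to sum to one at each location, so in
  the uniform-kernel / large-bandwidth limit the local covariance
  equals the global (1/n) covariance of the standardized data.
* Eigenvalues are sorted descending; every loading vector is flipped
  so its largest-magnitude entry is positive, making results stable
  across eigendecomposition backends.
* The Kaiser retention rule (eigenvalue > 1) is applied to the
  correlation-scale spectrum, i.e. eigenvalues rescaled to sum to the
  number of elements.
* Scores default to RAW (uncentered, unstandardized) concentrations
  dotted with the summary loadings, which keeps all scores positive
  for positive-loading components; ``mode="standardized"`` scores the
  standardized data instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from elementscape.geo import pairwise_degree_distance
from elementscape.io_formats import ElementProfileSet

KERNELS = ("bisquare", "gaussian", "uniform")


def kernel_weights(distances: np.ndarray, bandwidth: float, kernel: str) -> np.ndarray:
    """Unnormalized kernel weights for distances at a given bandwidth."""
    d = np.asarray(distances, dtype=float)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if kernel == "bisquare":
        u = d / bandwidth
        w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
    elif kernel == "gaussian":
        w = np.exp(-0.5 * (d / bandwidth) ** 2)
    elif kernel == "uniform":
        w = np.where(d <= bandwidth, 1.0, 0.0)
    else:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNELS}")
    return w


@dataclass
class GWPCAModel:
    """A fitted geographically weighted PCA."""

    elements: list[str]
    kernel: str
    bandwidth: float | int
    adaptive: bool
    lons: np.ndarray
    lats: np.ndarray
    means: np.ndarray                 # per-element standardization mean
    sds: np.ndarray                   # per-element standardization SD (ddof=1)
    local_loadings: np.ndarray        # (n_locations, n_components, n_elements)
    local_eigenvalues: np.ndarray     # (n_locations, n_components)

    @property
    def n_components(self) -> int:
        return self.local_eigenvalues.shape[1]

    @property
    def mean_eigenvalues(self) -> np.ndarray:
        """Eigenvalue spectrum averaged over locations."""
        return self.local_eigenvalues.mean(axis=0)

    @property
    def eigen_proportions(self) -> np.ndarray:
        lam = self.mean_eigenvalues
        return lam / lam.sum()

    @property
    def correlation_scale_eigenvalues(self) -> np.ndarray:
        """Mean spectrum rescaled so it sums to the number of elements."""
        lam = self.mean_eigenvalues
        return lam * (len(self.elements) / lam.sum())

    @property
    def n_retained(self) -> int:
        """Kaiser rule: components with correlation-scale eigenvalue > 1."""
        return int(np.sum(self.correlation_scale_eigenvalues > 1.0))

    def standardize(self, conc: np.ndarray) -> np.ndarray:
        return (np.asarray(conc, float) - self.means) / self.sds


@dataclass
class ScoreSet:
    """Per-sample component scores y* with their locations."""

    ids: list[str]
    lons: np.ndarray
    lats: np.ndarray
    scores: np.ndarray  # (n_samples, n_components_retained)

    def component(self, k: int = 0) -> np.ndarray:
        return self.scores[:, k]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.ids, "lon": self.lons, "lat": self.lats})
        for k in range(self.scores.shape[1]):
            df[f"PC{k + 1}"] = self.scores[:, k]
        return df


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _sign_fix(vectors: np.ndarray) -> np.ndarray:
    """Flip each loading vector (last axis) so its largest-|.| entry is >= 0."""
    idx = np.argmax(np.abs(vectors), axis=-1, keepdims=True)
    signs = np.sign(np.take_along_axis(vectors, idx, axis=-1))
    signs[signs == 0] = 1.0
    return vectors * signs


def _local_eig(z: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of the weighted covariance of rows of z with weights w.

    Returns (eigenvalues descending, loadings as rows).
    """
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("kernel weights vanish: bandwidth too small")
    w = w / total
    m = w @ z
    zc = z - m
    cov = (zc * w[:, None]).T @ zc
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    loadings = _sign_fix(vec[:, order].T)
    return lam, loadings


def _adaptive_bandwidths(dist: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Per-location bandwidth = distance to the k-th nearest other sample."""
    n = dist.shape[0]
    if not 2 <= n_neighbors <= n:
        raise ValueError(f"adaptive bandwidth {n_neighbors} outside [2, {n}]")
    part = np.sort(dist, axis=1)
    bw = part[:, n_neighbors - 1]
    if (bw <= 0).any():
        # coincident points: fall back to smallest positive distance
        pos = np.where(part > 0, part, np.inf).min(axis=1)
        bw = np.maximum(bw, pos)
    return bw


def fit_gwpca(
    profiles: ElementProfileSet,
    bandwidth: float | int,
    kernel: str = "bisquare",
    adaptive: bool | None = None,
) -> GWPCAModel:
    """Fit a geographically weighted PCA at every sample location.

    ``bandwidth`` is an adaptive neighbor count when given as an int
    (or when ``adaptive=True``), otherwise a fixed kernel distance in
    degrees. Requires more samples than elements.
    """
    n, p = profiles.conc.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than elements ({p})")
    if adaptive is None:
        adaptive = isinstance(bandwidth, (int, np.integer)) and not isinstance(
            bandwidth, bool
        )
    means = profiles.conc.mean(axis=0)
    sds = profiles.conc.std(axis=0, ddof=1)
    if (sds == 0).any():
        const = [e for e, s in zip(profiles.elements, sds) if s == 0]
        raise ValueError(f"constant element(s) {const}: cannot standardize")
    z = (profiles.conc - means) / sds

    dist = pairwise_degree_distance(profiles.lons, profiles.lats)
    if adaptive:
        bws = _adaptive_bandwidths(dist, int(bandwidth))
    else:
        bws = np.full(n, float(bandwidth))

    local_lam = np.empty((n, p))
    local_load = np.empty((n, p, p))
    for i in range(n):
        w = kernel_weights(dist[i], bws[i], kernel)
        lam, loadings = _local_eig(z, w)
        local_lam[i] = lam
        local_load[i] = loadings

    return GWPCAModel(
        elements=list(profiles.elements),
        kernel=kernel,
        bandwidth=bandwidth,
        adaptive=adaptive,
        lons=profiles.lons.copy(),
        lats=profiles.lats.copy(),
        means=means,
        sds=sds,
        local_loadings=local_load,
        local_eigenvalues=local_lam,
    )


def summarize_loadings(model: GWPCAModel, n_components: int | None = None,
                       method: str = "mean") -> np.ndarray:
    """Collapse location-varying loadings to one vector per component.

    Local vectors for a component are sign-aligned to the first
    location's vector, combined element-wise (mean, or median), and
    renormalized to unit norm.
    """
    if n_components is None:
        n_components = max(model.n_retained, 1)
    out = np.empty((n_components, len(model.elements)))
    for k in range(n_components):
        vecs = model.local_loadings[:, k, :]
        ref = vecs[0]
        signs = np.where(vecs @ ref < 0, -1.0, 1.0)
        aligned = vecs * signs[:, None]
        if method == "mean":
            v = aligned.mean(axis=0)
        elif method == "median":
            v = np.median(aligned, axis=0)
        else:
            raise ValueError("method must be 'mean' or 'median'")
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(f"summary loading for component {k + 1} collapsed to zero")
        out[k] = _sign_fix(v / norm)
    return out


def score_samples(
    summary_loadings: np.ndarray,
    profiles: ElementProfileSet,
    model: GWPCAModel | None = None,
    mode: str = "raw",
) -> ScoreSet:
    """Project profiles onto summary loadings.

    ``mode="raw"`` (default) scores raw ppb concentrations;
    ``mode="standardized"`` scores (x - mean)/sd using the model's
    standardization (requires ``model``).
    """
    summary_loadings = np.atleast_2d(np.asarray(summary_loadings, float))
    if summary_loadings.shape[1] != len(profiles.elements):
        raise ValueError(
            "loading length does not match the profile element order "
            f"({summary_loadings.shape[1]} vs {len(profiles.elements)})"
        )
    if model is not None and model.elements != profiles.elements:
        raise ValueError("element order mismatch between model and profiles")
    if mode == "raw":
        data = profiles.conc
    elif mode == "standardized":
        if model is None:
            raise ValueError("standardized scoring needs the fitted model")
        data = model.standardize(profiles.conc)
    else:
        raise ValueError("mode must be 'raw' or 'standardized'")
    scores = data @ summary_loadings.T
    return ScoreSet(list(profiles.ids), profiles.lons.copy(), profiles.lats.copy(),
                    scores)


def element_weights(summary_loading: np.ndarray, element_means: np.ndarray) -> np.ndarray:
    """Per-element weight = loading x mean concentration (interpretive
    aid: how much each element contributes to a typical score)."""
    return np.asarray(summary_loading, float) * np.asarray(element_means, float)


def variance_table(model: GWPCAModel) -> pd.DataFrame:
    """Per-component variance proportions and Kaiser retention flags."""
    lam = model.mean_eigenvalues
    corr_lam = model.correlation_scale_eigenvalues
    return pd.DataFrame({
        "component": [f"PC{k + 1}" for k in range(model.n_components)],
        "eigenvalue": lam,
        "correlation_scale_eigenvalue": corr_lam,
        "proportion": model.eigen_proportions,
        "retained": corr_lam > 1.0,
    })


def loading_table(model: GWPCAModel, n_components: int = 3) -> pd.DataFrame:
    """Loadings and weights (loading x mean ppb) per component."""
    n_components = min(n_components, model.n_components)
    summary = summarize_loadings(model, n_components)
    data: dict[str, np.ndarray] = {"element": np.array(model.elements)}
    for k in range(n_components):
        data[f"PC{k + 1}_loading"] = summary[k]
        data[f"PC{k + 1}_weight"] = element_weights(summary[k], model.means)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# bandwidth selection
# ---------------------------------------------------------------------------

def _loo_cv_score(z: np.ndarray, dist: np.ndarray, bandwidth: float | int,
                  kernel: str, adaptive: bool, k: int) -> float:
    """Sum of squared held-out residuals after projecting each sample on
    the k leading local components fitted without it."""
    n = z.shape[0]
    total = 0.0
    for i in range(n):
        others = np.arange(n) != i
        d = dist[i, others]
        if adaptive:
            nb = int(bandwidth)
            if nb > d.size:
                return np.inf
            bw = np.sort(d)[nb - 1]
            if bw <= 0:
                bw = np.where(d > 0, d, np.inf).min()
        else:
            bw = float(bandwidth)
        w = kernel_weights(d, bw, kernel)
        if w.sum() <= 0:
            return np.inf
        try:
            _, loadings = _local_eig(z[others], w)
        except ValueError:
            return np.inf
        w_norm = w / w.sum()
        m = w_norm @ z[others]
        r = z[i] - m
        v = loadings[:k]
        resid = r - v.T @ (v @ r)
        total += float(resid @ resid)
    return total


def select_bandwidth(
    profiles: ElementProfileSet,
    kernel: str = "bisquare",
    candidates: Sequence[float | int] | None = None,
    adaptive: bool = True,
    n_components: int = 1,
) -> float | int:
    """Choose the bandwidth minimizing leave-one-out reconstruction error.

    For each candidate, every sample is held out in turn, the local
    components at its location are fitted from the remaining samples,
    and the squared residual of the held-out (standardized) profile
    after projection onto the leading ``n_components`` components is
    accumulated. Default candidates span 10%-100% of n (adaptive
    neighbor counts).
    """
    n = len(profiles)
    if n < 5:
        raise ValueError("bandwidth selection needs at least 5 samples")
    if candidates is None:
        lo = max(2, int(np.ceil(0.1 * n)))
        candidates = sorted({int(c) for c in np.linspace(lo, n - 1, 8)})
    if not len(candidates):
        raise ValueError("empty candidate list")
    means = profiles.conc.mean(axis=0)
    sds = profiles.conc.std(axis=0, ddof=1)
    z = (profiles.conc - means) / np.where(sds == 0, 1.0, sds)
    dist = pairwise_degree_distance(profiles.lons, profiles.lats)
    scores = [
        _loo_cv_score(z, dist, c, kernel, adaptive, n_components) for c in candidates
    ]
    if not np.isfinite(scores).any():
        raise ValueError("all candidate bandwidths degenerate (too few neighbors)")
    return candidates[int(np.argmin(scores))]


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def morans_i(values: np.ndarray, lons: np.ndarray, lats: np.ndarray) -> float:
    """Global Moran's I with inverse-distance weights (degree units)."""
    values = np.asarray(values, float)
    n = len(values)
    d = pairwise_degree_distance(lons, lats)
    with np.errstate(divide="ignore"):
        w = np.where(d > 0, 1.0 / d, 0.0)
    np.fill_diagonal(w, 0.0)
    z = values - values.mean()
    denom = float(z @ z)
    s0 = w.sum()
    if denom == 0 or s0 == 0:
        return np.nan
    return float(n / s0 * (z @ w @ z) / denom)


def permutation_test(
    scores: ScoreSet,
    n_perm: int = 199,
    seed: int = 0,
    component: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo test of spatial structure in the component scores.

    Statistic: Moran's I (inverse-distance weights) of the scores at
    the sample locations. Null: scores randomly permuted over the
    locations. Returns (observed I, p) with
    p = (1 + #{perm >= observed}) / (n_perm + 1). Constant scores give
    an undefined statistic; returns (nan, 1.0) with a warning.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    values = scores.component(component)
    observed = morans_i(values, scores.lons, scores.lats)
    if not np.isfinite(observed):
        warnings.warn("constant scores: Moran's I undefined, returning p = 1")
        return np.nan, 1.0
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        if morans_i(perm, scores.lons, scores.lats) >= observed:
            count += 1
    return observed, (1 + count) / (n_perm + 1)
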