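"""Profile screening and per-element soil-to-fur transfer regressions.

Outlier screening uses squared robust Mahalanobis distances from a
minimum-covariance-determinant (MCD) fit, flagged against a chi-square
quantile with df = number of elements. The transfer model is ordinary
least squares of fur concentration (response) on soil concentration
(predictor), fitted independently per element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet

from elementscape.io_formats import ElementProfileSet, SoilGridSet

DEFAULT_OUTLIER_QUANTILE = 0.975


@dataclass
class OutlierReport:
    """Squared robust Mahalanobis distances and the flags they imply."""

    ids: list[str]
    squared_distances: np.ndarray
    cutoff: float
    quantile: float
    flagged: list[str]

    def keep_mask(self) -> np.ndarray:
        flagged = set(self.flagged)
        return np.array([i not in flagged for i in self.ids])


@dataclass
class ElementRegression:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    residual_sd: float


@dataclass
class ElementRegressionSet:
    """Per-element OLS fits of fur (response) on soil (predictor)."""

    regressions: dict[str, ElementRegression]

    @property
    def elements(self) -> list[str]:
        return list(self.regressions)

    def __getitem__(self, element: str) -> ElementRegression:
        return self.regressions[element]

    def predict_fur(self, element: str, soil_values: np.ndarray) -> np.ndarray:
        """Hypothetical fur concentration from soil, truncated at 0."""
        reg = self.regressions[element]
        return np.maximum(reg.intercept + reg.slope * np.asarray(soil_values, float), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"element": e, "slope": r.slope, "intercept": r.intercept,
             "r_squared": r.r_squared, "p_value": r.p_value,
             "residual_sd": r.residual_sd}
            for e, r in self.regressions.items()
        ]
        return pd.DataFrame(rows)


def soil_at_locations(soil: SoilGridSet, profiles: ElementProfileSet) -> np.ndarray:
    """Per-sample soil concentration vector, (n_samples, n_elements).

    Each value is the soil grid cell containing the sample location;
    an out-of-extent or no-data location is an error naming the sample.
    """
    out = np.empty((len(profiles), len(profiles.elements)))
    for i, (sid, lon, lat) in enumerate(zip(profiles.ids, profiles.lons, profiles.lats)):
        for j, element in enumerate(profiles.elements):
            grid = soil[element]
            try:
                value = grid.value_at(lon, lat)
            except ValueError as exc:
                raise ValueError(f"sample {sid!r}: {exc}") from None
            if np.isnan(value):
                raise ValueError(
                    f"sample {sid!r} falls on a no-data cell of element {element!r}"
                )
            out[i, j] = value
    return out


def flag_outliers(
    profiles: ElementProfileSet,
    quantile: float = DEFAULT_OUTLIER_QUANTILE,
    robust: bool = True,
    random_state: int = 0,
) -> OutlierReport:
    """Flag samples whose squared (robust) Mahalanobis distance exceeds
    the chi-square quantile with df = n elements.

    MCD location/scatter by default; ``robust=False`` uses the
    classical mean/covariance (useful for hand-checkable toys).
    ``quantile=1`` flags nothing.
    """
    n, p = profiles.conc.shape
    if n <= p:
        raise ValueError(
            f"need more samples ({n}) than elements ({p}) for Mahalanobis screening"
        )
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    x = profiles.conc
    if robust:
        # fit on canonically ordered rows so flags are invariant to the
        # input ordering (the MCD subset search is order-sensitive)
        order = np.lexsort(x.T[::-1])
        est = MinCovDet(random_state=random_state).fit(x[order])
        location, scatter = est.location_, est.covariance_
    else:
        location = x.mean(axis=0)
        scatter = np.cov(x.T, ddof=1).reshape(x.shape[1], x.shape[1])
    if not np.isfinite(np.linalg.cond(scatter)) or np.linalg.cond(scatter) > 1e12:
        raise ValueError(
            "scatter matrix is singular; drop collinear elements or regularize"
        )
    centered = x - location
    d2 = np.einsum("ij,jk,ik->i", centered, np.linalg.inv(scatter), centered)
    cutoff = float(stats.chi2.ppf(quantile, df=p))  # inf at quantile=1
    flagged = [sid for sid, d in zip(profiles.ids, d2) if d > cutoff]
    return OutlierReport(list(profiles.ids), d2, cutoff, quantile, flagged)


def fit_element_regressions(
    fur: ElementProfileSet, soil_vectors: np.ndarray
) -> ElementRegressionSet:
    """OLS fur ~ soil per element: slope, intercept, R^2, two-sided
    slope p-value, residual SD with n-2 denominator."""
    soil_vectors = np.asarray(soil_vectors, float)
    n = len(fur)
    if soil_vectors.shape != (n, len(fur.elements)):
        raise ValueError("soil vector shape must match the profile set")
    if n < 3:
        raise ValueError("need at least 3 paired observations per element")
    out: dict[str, ElementRegression] = {}
    for j, element in enumerate(fur.elements):
        x = soil_vectors[:, j]
        y = fur.conc[:, j]
        if np.ptp(x) == 0.0:
            raise ValueError(f"zero soil variance for element {element!r}")
        res = stats.linregress(x, y)
        resid = y - (res.intercept + res.slope * x)
        residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2)))
        out[element] = ElementRegression(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
            p_value=float(res.pvalue),
            residual_sd=residual_sd,
        )
    return ElementRegressionSet(out)
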