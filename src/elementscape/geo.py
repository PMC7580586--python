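"""Geodesic helpers shared across the pipeline.

Working units are decimal degrees (WGS84 lon/lat); great-circle
distances in kilometres come from the haversine formula on a spherical
Earth (R = 6371.0088 km, the IUGG mean radius).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Inputs broadcast like numpy arrays; scalars return a scalar.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards tiny negative round-off before sqrt
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_degree_distance(lons, lats):
    """Euclidean distance matrix in degree units (used for kernel bandwidths)."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    dx = lons[:, None] - lons[None, :]
    dy = lats[:, None] - lats[None, :]
    return np.hypot(dx, dy)
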