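"""Geodesic helpers (haversine distances on a spherical Earth)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def haversine(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in meters between points in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))
    return float(d) if np.ndim(d) == 0 else d


def haversine_matrix(coords) -> np.ndarray:
    """Full pairwise distance matrix (meters) for an (n, 2) lat/lon array."""
    coords = np.asarray(coords, dtype=float)
    lat = coords[:, 0][:, None]
    lon = coords[:, 1][:, None]
    return haversine(lat, lon, lat.T, lon.T)
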