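"""Small geodesy helpers for GPS mobility features."""

from __future__ import annotations

import numpy as np

EARTH_R = 6371000.0


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres (vectorised over array inputs)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = np.sin((lat2 - lat1) / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    return 2 * EARTH_R * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def local_xy(lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection to metres around the trace centroid.

    Adequate for the sub-10-km extents of daily mobility traces; used only
    for fast within-radius tests, final distances use :func:`haversine_m`.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    lat0 = lat.mean() if len(lat) else 0.0
    x = (lon - (lon.mean() if len(lon) else 0.0)) * 111320.0 * np.cos(np.radians(lat0))
    y = (lat - lat0) * 110540.0
    return x, y
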