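"""Great-circle geometry on a spherical Earth (mean radius 6371 km)."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = ["EARTH_RADIUS_KM", "haversine_km"]


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Pairwise great-circle distances in km between two point sets.

    ``lat1/lon1`` of length n and ``lat2/lon2`` of length m (degrees)
    give an (n, m) distance matrix.
    """
    la1 = np.radians(np.atleast_1d(np.asarray(lat1, dtype=float)))[:, None]
    lo1 = np.radians(np.atleast_1d(np.asarray(lon1, dtype=float)))[:, None]
    la2 = np.radians(np.atleast_1d(np.asarray(lat2, dtype=float)))[None, :]
    lo2 = np.radians(np.atleast_1d(np.asarray(lon2, dtype=float)))[None, :]
    dlat = la2 - la1
    dlon = lo2 - lo1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
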