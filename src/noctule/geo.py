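"""Great-circle geometry and small numeric helpers shared across the pipeline."""

from __future__ import annotations

import math

import numpy as np

#: Mean Earth radius (IUGG), km.
EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_km(lons, lats):
    """Full symmetric matrix of great-circle distances (km) between points."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])


def cross_haversine_km(lons_a, lats_a, lons_b, lats_b):
    """(len(a), len(b)) matrix of great-circle distances in km."""
    lons_a = np.asarray(lons_a, dtype=float)
    lats_a = np.asarray(lats_a, dtype=float)
    lons_b = np.asarray(lons_b, dtype=float)
    lats_b = np.asarray(lats_b, dtype=float)
    return haversine_km(lons_a[:, None], lats_a[:, None], lons_b[None, :], lats_b[None, :])


def round_half_up(x):
    """Round to the nearest integer with ties going up (0.5 -> 1, 1.5 -> 2).

    numpy's default rounds ties to even; GIS reclassification tools round up.
    """
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def meters_to_degrees_lat(meters: float) -> float:
    """Meridional arc length in degrees for a distance in meters."""
    return meters / (EARTH_RADIUS_KM * 1000.0) * 180.0 / math.pi


def geodesic_circle(lon: float, lat: float, radius_m: float, n_vertices: int = 64):
    """Approximate geodesic circle as a lon/lat polygon ring.

    Uses the local tangent-plane scaling (1 degree longitude = cos(lat)
    degrees of meridional arc), adequate for the sub-kilometer buffers used
    around forest points.
    """
    dlat = meters_to_degrees_lat(radius_m)
    coslat = math.cos(math.radians(lat))
    if coslat <= 1e-9:
        raise ValueError("geodesic_circle is undefined at the poles")
    dlon = dlat / coslat
    t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    return np.column_stack([lon + dlon * np.cos(t), lat + dlat * np.sin(t)])
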