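"""Great-circle distances and bearings on a spherical Earth.

All spatial analysis in this package works directly on latitude/longitude
(WGS84 decimal degrees): the study domain is far too large for any single
planar projection, so lags between locations are measured as great-circle
distances on a spherical approximation. Distances are in kilometres,
bearings in degrees.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "EARTH_RADIUS_KM",
    "validate_coords",
    "great_circle_distance",
    "final_bearing",
    "fold_bearing",
    "pairwise_lags",
]

#: Equatorial radius in km, matching the default of the R ``geosphere``
#: spherical-distance routines. Configurable in every function below.
EARTH_RADIUS_KM = 6378.137


def validate_coords(lat, lon) -> None:
    """Raise ``ValueError`` on latitudes outside [-90, 90] or longitudes
    outside [-180, 180] (NaN also rejected)."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not (np.all(np.abs(lat) <= 90.0) and np.all(np.isfinite(lat))):
        raise ValueError("latitude outside [-90, 90] or non-finite")
    if not (np.all(np.abs(lon) <= 180.0) and np.all(np.isfinite(lon))):
        raise ValueError("longitude outside [-180, 180] or non-finite")


def great_circle_distance(lat1, lon1, lat2, lon2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between points on a sphere.

    Uses the haversine form, which is numerically stable for small
    separations. Accepts scalars or broadcastable arrays.
    """
    validate_coords(lat1, lon1)
    validate_coords(lat2, lon2)
    phi1, lam1, phi2, lam2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    # clip guards rounding at antipodes
    d = 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return d if d.shape else float(d)


def _initial_bearing_rad(phi1, lam1, phi2, lam2):
    dlam = lam2 - lam1
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    return np.arctan2(y, x)


def final_bearing(lat1, lon1, lat2, lon2):
    """Bearing of the great-circle arc at the *arrival* point, degrees in [0, 360).

    Computed as the back-azimuth of the reversed arc: the initial bearing
    from the destination to the origin, rotated 180 degrees. Coincident
    points have no defined bearing and raise ``ValueError`` (scalar input
    only; for arrays the result is NaN at coincident pairs).
    """
    validate_coords(lat1, lon1)
    validate_coords(lat2, lon2)
    phi1, lam1, phi2, lam2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    theta = np.degrees(_initial_bearing_rad(phi2, lam2, phi1, lam1))
    out = np.mod(theta + 180.0, 360.0)
    same = (phi1 == phi2) & (lam1 == lam2)
    if out.shape == ():
        if same:
            raise ValueError("bearing undefined for coincident points")
        return float(out)
    return np.where(same, np.nan, out)


def fold_bearing(bearing):
    """Fold a bearing to [0, 180): a lag and its reverse belong to the same
    direction class in directional variography."""
    return np.mod(np.asarray(bearing, dtype=float), 180.0)


def pairwise_lags(lat, lon, radius_km: float = EARTH_RADIUS_KM):
    """All unordered pairs of n points with distance and arrival bearing.

    Returns ``(i, j, dist_km, bearing_deg)`` arrays of length n(n-1)/2 with
    i < j. Duplicate coordinates are allowed: their distance is 0 and the
    bearing is NaN (flagged, not an error).
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size < 2:
        raise ValueError("need at least 2 points")
    validate_coords(lat, lon)
    i, j = np.triu_indices(lat.size, k=1)
    d = great_circle_distance(lat[i], lon[i], lat[j], lon[j], radius_km=radius_km)
    phi1, lam1 = np.radians(lat[i]), np.radians(lon[i])
    phi2, lam2 = np.radians(lat[j]), np.radians(lon[j])
    theta = np.mod(np.degrees(_initial_bearing_rad(phi2, lam2, phi1, lam1)) + 180.0, 360.0)
    coincident = (lat[i] == lat[j]) & (lon[i] == lon[j])
    theta = np.where(coincident, np.nan, theta)
    return i, j, np.atleast_1d(d), theta
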