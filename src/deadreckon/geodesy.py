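"""Spherical and ellipsoidal geodesy primitives.

Track integration, drift correction and 2-D distance all use a spherical
Earth of radius 6,371,000 m (haversine distances, destination-point steps,
initial great-circle bearings).  The oblate WGS-84 ellipsoid enters only
when 3-D positions are converted to Earth-centred Cartesian coordinates
for Pythagorean 3-D distance sums.

All angles at the public surface are degrees; latitudes are geodetic
(WGS-84) decimal degrees, longitudes wrap to (-180, 180].
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0
"""Mean Earth radius (m) used for all spherical formulae."""

WGS84_A = 6_378_137.0
"""WGS-84 semi-major axis (m)."""

WGS84_F = 1.0 / 298.257223563
"""WGS-84 flattening."""

WGS84_B = WGS84_A * (1.0 - WGS84_F)
WGS84_E2 = WGS84_F * (2.0 - WGS84_F)  # first eccentricity squared


def wrap_longitude(lon):
    """Wrap longitude(s) in degrees to (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    wrapped = -((-lon + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def wrap_heading(h):
    """Wrap heading(s) in degrees to [0, 360)."""
    h = np.asarray(h, dtype=float)
    wrapped = np.mod(h, 360.0)
    # round-off can leave values a hair below 360; snap them to 0
    wrapped = np.where(360.0 - wrapped < 1e-9, 0.0, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


def wrap_signed_angle(a):
    """Wrap angle(s) in degrees to (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def haversine_m(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_M):
    """Great-circle distance (m) between points given in decimal degrees.

    Vectorised over any broadcastable combination of inputs.
    """
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * radius * np.arcsin(np.sqrt(a))
    return d if np.ndim(d) else float(d)


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing (deg clockwise from true North)."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    b = wrap_heading(np.degrees(np.arctan2(y, x)))
    return b if np.ndim(b) else float(b)


def forward_step(lat, lon, heading_deg, distance_m, radius: float = EARTH_RADIUS_M):
    """Spherical destination point: advance ``distance_m`` along ``heading_deg``.

    Vectorised; returns (lat, lon) in degrees with lon wrapped to (-180, 180].
    """
    distance_m = np.asarray(distance_m, dtype=float)
    if np.any(distance_m < 0):
        raise ValueError("forward_step distance must be >= 0")
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    theta = np.radians(heading_deg)
    delta = distance_m / radius
    sin_phi2 = np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    phi2 = np.arcsin(np.clip(sin_phi2, -1.0, 1.0))
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * sin_phi2,
    )
    lat2 = np.degrees(phi2)
    lon2 = wrap_longitude(np.degrees(lam2))
    if np.ndim(lat2):
        return lat2, lon2
    return float(lat2), float(lon2)


def geodetic_to_ecef(lat, lon, h):
    """WGS-84 geodetic (deg, deg, m ellipsoidal height) -> ECEF (x, y, z) in metres."""
    phi = np.radians(lat)
    lam = np.radians(lon)
    sin_phi = np.sin(phi)
    n = WGS84_A / np.sqrt(1.0 - WGS84_E2 * sin_phi**2)
    x = (n + h) * np.cos(phi) * np.cos(lam)
    y = (n + h) * np.cos(phi) * np.sin(lam)
    z = (n * (1.0 - WGS84_E2) + h) * sin_phi
    return x, y, z


def ecef_to_geodetic(x, y, z):
    """ECEF (m) -> WGS-84 geodetic (lat deg, lon deg, height m).

    Bowring's closed-form first guess refined by fixed-point iteration;
    converges to sub-micrometre height error for near-surface points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    lon = np.degrees(np.arctan2(y, x))
    p = np.hypot(x, y)
    # Bowring initial parametric latitude
    theta = np.arctan2(z * WGS84_A, p * WGS84_B)
    ep2 = WGS84_E2 / (1.0 - WGS84_E2)
    phi = np.arctan2(
        z + ep2 * WGS84_B * np.sin(theta) ** 3,
        p - WGS84_E2 * WGS84_A * np.cos(theta) ** 3,
    )
    for _ in range(3):
        sin_phi = np.sin(phi)
        n = WGS84_A / np.sqrt(1.0 - WGS84_E2 * sin_phi**2)
        h = p / np.cos(phi) - n
        phi = np.arctan2(z, p * (1.0 - WGS84_E2 * n / (n + h)))
    sin_phi = np.sin(phi)
    n = WGS84_A / np.sqrt(1.0 - WGS84_E2 * sin_phi**2)
    h = np.where(
        np.abs(np.cos(phi)) > 1e-8, p / np.cos(phi) - n, z / sin_phi - n * (1.0 - WGS84_E2)
    )
    return np.degrees(phi), lon, h


def to_local_enu(lat, lon, lat0: float, lon0: float, radius: float = EARTH_RADIUS_M):
    """Project (lat, lon) onto an equirectangular east/north tangent plane at (lat0, lon0).

    Adequate at biologging segment scales (tens of km); exact inverse is
    :func:`from_local_enu`.
    """
    dlat = np.asarray(lat, dtype=float) - lat0
    dlon = wrap_signed_angle(np.asarray(lon, dtype=float) - lon0)
    north = np.radians(dlat) * radius
    east = np.radians(dlon) * radius * np.cos(np.radians(lat0))
    return east, north


def from_local_enu(east, north, lat0: float, lon0: float, radius: float = EARTH_RADIUS_M):
    """Inverse of :func:`to_local_enu`."""
    lat = lat0 + np.degrees(np.asarray(north, dtype=float) / radius)
    lon = lon0 + np.degrees(
        np.asarray(east, dtype=float) / (radius * np.cos(np.radians(lat0)))
    )
    return lat, wrap_longitude(lon)


def circular_mean_deg(angles_deg, weights=None):
    """Mean of angles in degrees on the circle, result in [0, 360)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if weights is None:
        s, c = np.mean(np.sin(a)), np.mean(np.cos(a))
    else:
        w = np.asarray(weights, dtype=float)
        s, c = np.sum(w * np.sin(a)), np.sum(w * np.cos(a))
    return float(wrap_heading(np.degrees(np.arctan2(s, c))))
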