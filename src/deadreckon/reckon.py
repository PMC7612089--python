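"""Dead-reckoning: integrate travel vectors into an uncorrected pseudo-track.

Each step advances the position along the current heading by speed * dt on
a spherical Earth (destination-point formula). If an external current field
is supplied, its (u, v) drift is added to the powered displacement as an
instantaneous vector sum before the geodesic step — the "current
integration" used for animals travelling in fluid media. The vertical
coordinate accumulates the per-step dz.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .geodesy import forward_step, wrap_heading
from .types import CurrentField, GeoTrack, TravelVectorSeries


def current_lookup(field: CurrentField, lat: float, lon: float, t: float) -> tuple[float, float]:
    """(u, v) m/s at a point and time: nearest-neighbour in space, linear in time.

    Queries outside the grid extent return (0, 0) and increment the field's
    miss counter.
    """
    if (
        lat < field.lat[0]
        or lat > field.lat[-1]
        or lon < field.lon[0]
        or lon > field.lon[-1]
        or t < field.time[0]
        or t > field.time[-1]
    ):
        field.out_of_grid_count += 1
        return 0.0, 0.0
    i_lat = int(np.argmin(np.abs(field.lat - lat)))
    i_lon = int(np.argmin(np.abs(field.lon - lon)))
    k = int(np.searchsorted(field.time, t, side="right") - 1)
    if k >= field.time.size - 1:
        return float(field.u[-1, i_lat, i_lon]), float(field.v[-1, i_lat, i_lon])
    t0, t1 = field.time[k], field.time[k + 1]
    w = (t - t0) / (t1 - t0)
    u = (1 - w) * field.u[k, i_lat, i_lon] + w * field.u[k + 1, i_lat, i_lon]
    v = (1 - w) * field.v[k, i_lat, i_lon] + w * field.v[k + 1, i_lat, i_lon]
    return float(u), float(v)


def integrate_track(
    start: tuple[float, float, float],
    tv: TravelVectorSeries,
    current: Optional[CurrentField] = None,
) -> GeoTrack:
    """Sequentially integrate travel vectors from a start position.

    Per step the powered displacement (east, north) = speed * dt *
    (sin h, cos h) is summed with the current drift (u, v) * dt (sampled at
    the pre-step position and time), and the position advances by the summed
    vector's bearing and magnitude. Output has ``len(tv) + 1`` positions.
    """
    lat0, lon0, z0 = start
    n = tv.t.size
    dt = tv.dt
    if not (
        np.all(np.isfinite(tv.heading)) and np.all(np.isfinite(tv.speed)) and np.all(np.isfinite(tv.dz))
    ):
        bad = int(
            np.argmax(~(np.isfinite(tv.heading) & np.isfinite(tv.speed) & np.isfinite(tv.dz)))
        )
        raise ValueError(f"non-finite travel vector at index {bad}")

    h_rad = np.radians(tv.heading)
    de_powered = tv.speed * dt * np.sin(h_rad)
    dn_powered = tv.speed * dt * np.cos(h_rad)

    lat = np.empty(n + 1)
    lon = np.empty(n + 1)
    lat[0], lon[0] = lat0, lon0

    if current is None:
        # fully powered: bearings/magnitudes known up front
        dist = np.hypot(de_powered, dn_powered)
        bearing = wrap_heading(np.degrees(np.arctan2(de_powered, dn_powered)))
        cur_lat, cur_lon = lat0, lon0
        for i in range(n):
            if dist[i] > 0:
                cur_lat, cur_lon = forward_step(cur_lat, cur_lon, bearing[i], dist[i])
            lat[i + 1], lon[i + 1] = cur_lat, cur_lon
    else:
        cur_lat, cur_lon = lat0, lon0
        for i in range(n):
            u, v = current_lookup(current, cur_lat, cur_lon, tv.t[i])
            de = de_powered[i] + u * dt
            dn = dn_powered[i] + v * dt
            step = float(np.hypot(de, dn))
            if step > 0:
                b = float(np.degrees(np.arctan2(de, dn)))
                cur_lat, cur_lon = forward_step(cur_lat, cur_lon, wrap_heading(b), step)
            lat[i + 1], lon[i + 1] = cur_lat, cur_lon

    z = np.concatenate([[z0], z0 + np.cumsum(tv.dz)])
    # position k is occupied at the start of step k; the final position
    # carries one step beyond the last sample time
    t = np.concatenate([tv.t, [tv.t[-1] + dt]])
    return GeoTrack(t=t, lat=lat, lon=lon, z=z, kind="dead_reckoned")
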