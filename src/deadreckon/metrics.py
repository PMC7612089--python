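"""Track accuracy and movement metrics.

- *net error*: haversine distance between every verified position and the
  time-matched corrected dead-reckoned position (2-D, spherical Earth);
- *distance moved*: summed between consecutive positions, 2-D (haversine)
  or 3-D (Pythagorean distance between WGS-84 Earth-centred Cartesian
  coordinates, so the oblate spheroid enters only here);
- *thinning sweep*: re-run the VP correction at a schedule of correction
  intervals and tabulate net error, distance moved and the error rate
  standardised by the mean time between corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import correct as _correct
from .geodesy import geodetic_to_ecef, haversine_m
from .types import CurrentField, GeoTrack, NetErrorSeries, TravelVectorSeries

# the paper-style schedule of correction intervals, in seconds
DEFAULT_THINNING_SCHEDULE_S: tuple[float, ...] = (
    24 * 3600.0,
    12 * 3600.0,
    6 * 3600.0,
    3 * 3600.0,
    3600.0,
    1800.0,
    900.0,
    300.0,
    60.0,
    30.0,
    1.0,
)


def haversine(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Great-circle distance (m) between two (lat, lon) points in degrees."""
    return float(haversine_m(p1[0], p1[1], p2[0], p2[1]))


def geodetic_to_cartesian(
    lat, lon, z, medium: str = "water"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """WGS-84 geodetic to Earth-centred Cartesian (m).

    ``z`` is depth (m, positive down) for water or altitude (m, positive
    up) for air/land; it enters as ellipsoidal height with the matching
    sign.
    """
    if medium == "water":
        h = -np.asarray(z, dtype=float)
    elif medium in ("air", "land"):
        h = np.asarray(z, dtype=float)
    else:
        raise ValueError(f"unknown medium {medium!r}")
    return geodetic_to_ecef(lat, lon, h)


def distance_moved(track: GeoTrack, mode: str = "2d", medium: str = "water") -> float:
    """Total path length (m): 2-D haversine sum or 3-D Cartesian chord sum."""
    if track.n < 2:
        raise ValueError("need at least 2 positions")
    if mode == "2d":
        return float(
            np.sum(haversine_m(track.lat[:-1], track.lon[:-1], track.lat[1:], track.lon[1:]))
        )
    if mode == "3d":
        x, y, z = geodetic_to_cartesian(track.lat, track.lon, track.z, medium)
        return float(np.sum(np.sqrt(np.diff(x) ** 2 + np.diff(y) ** 2 + np.diff(z) ** 2)))
    raise ValueError(f"unknown mode {mode!r}")


def net_error(corrected: GeoTrack, all_vps: GeoTrack) -> NetErrorSeries:
    """Per-VP net error: haversine between each VP and the time-matched
    corrected position, for every VP regardless of whether it anchored the
    correction."""
    track_idx, vp_idx, _ = _correct.time_match(corrected, all_vps)
    err = haversine_m(
        corrected.lat[track_idx],
        corrected.lon[track_idx],
        all_vps.lat[vp_idx],
        all_vps.lon[vp_idx],
    )
    return NetErrorSeries(t=all_vps.t[vp_idx], error_m=np.atleast_1d(err))


@dataclass
class ThinningResult:
    """Tidy per-interval summary of the VP-thinning sweep."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def thinning_sweep(
    track: GeoTrack,
    vps: GeoTrack,
    schedule: Sequence[float] = DEFAULT_THINNING_SCHEDULE_S,
    medium: str = "land",
    mode_3d: bool = False,
    current: Optional[CurrentField] = None,
    tv: Optional[TravelVectorSeries] = None,
) -> ThinningResult:
    """Thin -> correct -> evaluate at each correction interval of the schedule.

    For every interval: thin the VPs, correct the uncorrected track against
    the thinned fixes, compute mean/median net error against *all* supplied
    VPs, the dead-reckoned distance moved (2-D, or 3-D when ``mode_3d``),
    the 2-D VP-path distance over the thinned fixes, the realised mean time
    between corrections and the standardised error rate (mean net error /
    mean time between corrections). Intervals longer than the VP span fall
    back to the first-and-last-fix correction.
    """
    if not len(schedule):
        raise ValueError("empty thinning schedule")
    rows = []
    for interval in schedule:
        thinned = _correct.thin_vps(vps, interval)
        corrected, report = _correct.correct_track(track, thinned)
        errs = net_error(corrected, vps)
        dr_dist = distance_moved(corrected, "3d" if mode_3d else "2d", medium)
        vp_dist = distance_moved(thinned, "2d") if thinned.n > 1 else 0.0
        mean_gap = float(np.mean(np.diff(thinned.t))) if thinned.n > 1 else np.nan
        rows.append(
            {
                "interval_s": float(interval),
                "n_vps_used": report.vps_used,
                "mean_net_error_m": errs.mean,
                "median_net_error_m": errs.median,
                "dr_distance_m": dr_dist,
                "vp_distance_m": vp_dist,
                "mean_time_between_corrections_s": mean_gap,
                "error_rate_m_per_s": errs.mean / mean_gap if mean_gap else np.nan,
            }
        )
    return ThinningResult(table=pd.DataFrame(rows))
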