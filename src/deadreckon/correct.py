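"""Drift correction of dead-reckoned tracks against verified positions (VPs).

Between each pair of consecutive matched VPs the dead-reckoned segment is
rotated and scaled so its endpoints land on the VPs:

- distance correction factor (DCF): ratio of the VP beeline to the
  dead-reckoned beeline, multiplied onto every intermediate step distance;
- heading correction factor (HCF): bearing difference between the VP
  beeline and the dead-reckoned beeline, added to every intermediate
  heading (positive = clockwise).

Because a per-segment rotation plus uniform scaling is applied to the step
displacement vectors, the corrected endpoint coincides with the VP anchor
(to planar-approximation error), stationary steps stay stationary
(zero times any factor is zero), and the within-segment turn-angle
sequence — the track's shape — is preserved.

Correction is computed in a local tangent plane at the segment's starting
VP and mapped back; the reported residual tracks the planar-approximation
error at the anchor.
"""

from __future__ import annotations

import numpy as np

from .geodesy import (
    from_local_enu,
    haversine_m,
    initial_bearing_deg,
    to_local_enu,
    wrap_signed_angle,
)
from .types import CorrectionReport, CorrectionSegment, GeoTrack

EXTREME_DCF_HIGH = 10.0
EXTREME_DCF_LOW = 0.1
DEGENERATE_BEELINE_M = 1e-9


def thin_vps(vps: GeoTrack, interval_s: float) -> GeoTrack:
    """Greedy temporal thinning: keep the first fix, then the earliest fix at
    least ``interval_s`` later, repeating; the final fix is always kept.

    Mimics sub-sampling a VP stream to a lower correction rate; with
    dropouts the next available fix after a gap is kept, so realised
    intervals can exceed the nominal one.
    """
    if interval_s <= 0:
        raise ValueError("interval_s must be > 0")
    keep = [0]
    for i in range(1, vps.n):
        if vps.t[i] >= vps.t[keep[-1]] + interval_s:
            keep.append(i)
    if keep[-1] != vps.n - 1:
        keep.append(vps.n - 1)
    return vps.subset(np.array(keep, dtype=int))


def screen_vps(vps: GeoTrack, max_speed: float) -> GeoTrack:
    """Drop fixes whose implied speed from the previous kept fix exceeds
    ``max_speed`` (m/s) — a programmatic screen for erroneous VP estimates."""
    if vps.n < 2:
        return vps
    keep = [0]
    for i in range(1, vps.n):
        j = keep[-1]
        d = haversine_m(vps.lat[j], vps.lon[j], vps.lat[i], vps.lon[i])
        if d / (vps.t[i] - vps.t[j]) <= max_speed:
            keep.append(i)
    return vps.subset(np.array(keep, dtype=int))


def time_match(track: GeoTrack, vps: GeoTrack) -> tuple[np.ndarray, np.ndarray, int]:
    """Match each VP to the nearest track sample within half a sample step.

    Returns (track indices, VP indices, skipped count). VPs falling in a
    logger gap (no sample within dt/2) or colliding with an already-matched
    sample are skipped and counted.
    """
    if track.n == 0 or vps.n == 0:
        raise ValueError("empty track or VP series")
    dt = float(np.median(np.diff(track.t))) if track.n > 1 else 1.0
    idx = np.searchsorted(track.t, vps.t)
    track_idx, vp_idx, skipped = [], [], 0
    for k, tq in enumerate(vps.t):
        candidates = [c for c in (idx[k] - 1, idx[k]) if 0 <= c < track.n]
        best = min(candidates, key=lambda c: abs(track.t[c] - tq))
        if abs(track.t[best] - tq) <= dt / 2 + 1e-9 and (
            not track_idx or best > track_idx[-1]
        ):
            track_idx.append(best)
            vp_idx.append(k)
        else:
            skipped += 1
    if not track_idx:
        raise ValueError("no VP matched any track sample within tolerance")
    return np.array(track_idx, dtype=int), np.array(vp_idx, dtype=int), skipped


def segment_factors(
    dr_start: tuple[float, float],
    dr_end: tuple[float, float],
    vp_start: tuple[float, float],
    vp_end: tuple[float, float],
) -> tuple[float, float, bool]:
    """(dcf, hcf, degenerate) for one correction segment.

    dcf = haversine(vp beeline) / haversine(dead-reckoned beeline);
    hcf = bearing(vp beeline) - bearing(dead-reckoned beeline), wrapped to
    (-180, 180]. A zero dead-reckoned beeline flags the segment degenerate
    (dcf reported as 0, hcf as 0) rather than raising.
    """
    d_dr = haversine_m(dr_start[0], dr_start[1], dr_end[0], dr_end[1])
    d_vp = haversine_m(vp_start[0], vp_start[1], vp_end[0], vp_end[1])
    if d_dr <= DEGENERATE_BEELINE_M:
        return 0.0, 0.0, True
    b_dr = initial_bearing_deg(dr_start[0], dr_start[1], dr_end[0], dr_end[1])
    b_vp = initial_bearing_deg(vp_start[0], vp_start[1], vp_end[0], vp_end[1])
    return d_vp / d_dr, float(wrap_signed_angle(b_vp - b_dr)), False


def _rotate_scale(de: np.ndarray, dn: np.ndarray, hcf_deg: float, dcf: float):
    """Rotate step displacements clockwise by hcf and scale by dcf."""
    a = np.radians(hcf_deg)
    e = dcf * (de * np.cos(a) + dn * np.sin(a))
    n = dcf * (dn * np.cos(a) - de * np.sin(a))
    return e, n


def correct_track(
    track: GeoTrack, vps_thinned: GeoTrack
) -> tuple[GeoTrack, CorrectionReport]:
    """Apply segment-wise heading/distance correction factors to a track.

    Per segment between consecutive matched VPs, every step heading gets the
    segment HCF and every step distance the segment DCF, then the segment is
    re-integrated from the starting VP; the corrected endpoint abuts the
    ending VP. Spans before the first and after the last matched VP are
    rigidly translated to their anchor. Degenerate segments (no dead-
    reckoned displacement) are translated to start at the anchor with the
    final position snapped onto the ending VP.

    Returns the corrected track (same times and z) and a report of one
    :class:`CorrectionSegment` per segment.
    """
    track_idx, vp_idx, skipped = time_match(track, vps_thinned)
    if track_idx.size < 2:
        raise ValueError("need at least 2 matched VPs to correct a track")

    lat = track.lat.copy()
    lon = track.lon.copy()
    segments: list[CorrectionSegment] = []
    degenerate_count = 0
    extreme_count = 0

    for s in range(track_idx.size - 1):
        i0, i1 = track_idx[s], track_idx[s + 1]
        k0, k1 = vp_idx[s], vp_idx[s + 1]
        vp_a = (vps_thinned.lat[k0], vps_thinned.lon[k0])
        vp_b = (vps_thinned.lat[k1], vps_thinned.lon[k1])
        lat0, lon0 = float(vp_a[0]), float(vp_a[1])

        # work in the tangent plane at the starting VP
        e, n = to_local_enu(track.lat[i0 : i1 + 1], track.lon[i0 : i1 + 1], lat0, lon0)
        eb, nb = to_local_enu(vp_b[0], vp_b[1], lat0, lon0)
        d_dr_e, d_dr_n = e[-1] - e[0], n[-1] - n[0]
        beeline_dr = float(np.hypot(d_dr_e, d_dr_n))
        beeline_vp = float(np.hypot(eb, nb))

        if beeline_dr <= DEGENERATE_BEELINE_M:
            # stationary dead-reckoned segment: anchor start, snap end
            new_e = (e - e[0]).copy()
            new_n = (n - n[0]).copy()
            residual = float(np.hypot(new_e[-1] - eb, new_n[-1] - nb))
            new_e[-1], new_n[-1] = eb, nb
            dcf, hcf, degen = 0.0, 0.0, True
            degenerate_count += 1
        else:
            dcf = beeline_vp / beeline_dr
            b_dr = np.degrees(np.arctan2(d_dr_e, d_dr_n))
            b_vp = np.degrees(np.arctan2(eb, nb)) if beeline_vp > 0 else b_dr
            hcf = float(wrap_signed_angle(b_vp - b_dr))
            de, dn = np.diff(e), np.diff(n)
            ce, cn = _rotate_scale(de, dn, hcf, dcf)
            new_e = np.concatenate([[0.0], np.cumsum(ce)])
            new_n = np.concatenate([[0.0], np.cumsum(cn)])
            residual = float(np.hypot(new_e[-1] - eb, new_n[-1] - nb))
            degen = False
            if dcf > EXTREME_DCF_HIGH or dcf < EXTREME_DCF_LOW:
                extreme_count += 1

        seg_lat, seg_lon = from_local_enu(new_e, new_n, lat0, lon0)
        lat[i0 : i1 + 1] = seg_lat
        lon[i0 : i1 + 1] = seg_lon
        segments.append(
            CorrectionSegment(
                t_start=float(track.t[i0]),
                t_end=float(track.t[i1]),
                vp_start=vp_a,
                vp_end=vp_b,
                dcf=float(dcf),
                hcf=float(hcf),
                residual_m=residual,
                degenerate=degen,
            )
        )

    # rigid translation of the spans outside the matched VPs
    i_first, i_last = track_idx[0], track_idx[-1]
    if i_first > 0:
        lat0, lon0 = float(lat[i_first]), float(lon[i_first])
        e, n = to_local_enu(track.lat[: i_first + 1], track.lon[: i_first + 1], lat0, lon0)
        seg_lat, seg_lon = from_local_enu(e - e[-1], n - n[-1], lat0, lon0)
        lat[:i_first], lon[:i_first] = seg_lat[:-1], seg_lon[:-1]
    if i_last < track.n - 1:
        lat0, lon0 = float(lat[i_last]), float(lon[i_last])
        e, n = to_local_enu(track.lat[i_last:], track.lon[i_last:], lat0, lon0)
        seg_lat, seg_lon = from_local_enu(e - e[0], n - n[0], lat0, lon0)
        lat[i_last + 1 :], lon[i_last + 1 :] = seg_lat[1:], seg_lon[1:]

    corrected = GeoTrack(t=track.t, lat=lat, lon=lon, z=track.z.copy(), kind="dead_reckoned")
    report = CorrectionReport(
        segments=segments,
        vps_used=int(track_idx.size),
        vps_skipped=int(skipped),
        degenerate_count=degenerate_count,
        extreme_dcf_count=extreme_count,
    )
    return corrected, report
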