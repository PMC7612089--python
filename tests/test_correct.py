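"""VP thinning, screening, matching and the segment-wise drift correction."""

import numpy as np
import pytest

import deadreckon as dr
from deadreckon.geodesy import haversine_m, to_local_enu, wrap_signed_angle
from deadreckon.types import GeoTrack, TravelVectorSeries


def walk_track(rng, n=1200, dt=1.0, speed_scale=1.0, heading_offset=0.0, rest=None):
    """Random-walk travel vectors and their integrated track."""
    heading = np.cumsum(rng.normal(0, 5, n)) % 360.0
    speed = rng.uniform(0.5, 1.5, n)
    if rest is not None:
        speed[rest] = 0.0
    tv = TravelVectorSeries(
        t=np.arange(n) * dt,
        heading=(heading + heading_offset) % 360.0,
        speed=speed * speed_scale,
    )
    track = dr.integrate_track((-20.0, 30.0, 0.0), tv)
    return tv, track


class TestThinVps:
    def test_hourly_from_1hz(self):
        vps = GeoTrack(t=np.arange(3601.0), lat=np.zeros(3601), lon=np.zeros(3601), kind="verified")
        out = dr.thin_vps(vps, 3600.0)
        assert out.n == 2
        assert out.t[0] == 0.0 and out.t[-1] == 3600.0

    def test_interval_below_spacing_keeps_all(self):
        vps = GeoTrack(t=np.arange(0, 100, 10.0), lat=np.zeros(10), lon=np.zeros(10), kind="verified")
        assert dr.thin_vps(vps, 5.0).n == 10

    def test_dropout_keeps_next_available_fix(self):
        # fixes every 10 min with a 2-h hole; 1-h thinning resumes after the gap
        t = np.concatenate([np.arange(0, 3600, 600.0), np.arange(3600 + 7200, 14400, 600.0)])
        vps = GeoTrack(t=t, lat=np.zeros(t.size), lon=np.zeros(t.size), kind="verified")
        out = dr.thin_vps(vps, 3600.0)
        assert 10800.0 in out.t  # first fix after the dropout
        assert np.all(np.isin(out.t, t))

    def test_screening_drops_outlier(self):
        t = np.arange(5.0) * 60.0
        lat = np.zeros(5)
        lat[2] = 0.5  # ~55 km jump in one minute
        vps = GeoTrack(t=t, lat=lat, lon=np.zeros(5), kind="verified")
        out = dr.screen_vps(vps, max_speed=10.0)
        assert out.n == 4 and np.all(out.lat == 0.0)


class TestTimeMatch:
    def test_exact_times(self):
        track = GeoTrack(t=np.arange(10.0), lat=np.zeros(10), lon=np.zeros(10))
        vps = GeoTrack(t=np.array([2.0, 7.0]), lat=np.zeros(2), lon=np.zeros(2), kind="verified")
        ti, vi, skipped = dr.time_match(track, vps)
        assert ti.tolist() == [2, 7] and skipped == 0

    def test_nearest_within_half_step(self):
        track = GeoTrack(t=np.arange(10.0), lat=np.zeros(10), lon=np.zeros(10))
        vps = GeoTrack(t=np.array([2.4]), lat=np.zeros(1), lon=np.zeros(1), kind="verified")
        ti, _, _ = dr.time_match(track, vps)
        assert ti.tolist() == [2]

    def test_gap_skipped_and_counted(self):
        track = GeoTrack(
            t=np.concatenate([np.arange(5.0), np.arange(100.0, 105.0)]),
            lat=np.zeros(10),
            lon=np.zeros(10),
        )
        vps = GeoTrack(
            t=np.array([2.0, 50.0, 102.0]), lat=np.zeros(3), lon=np.zeros(3), kind="verified"
        )
        ti, vi, skipped = dr.time_match(track, vps)
        assert skipped == 1 and vi.tolist() == [0, 2]

    def test_no_matches_raises(self):
        track = GeoTrack(t=np.arange(5.0), lat=np.zeros(5), lon=np.zeros(5))
        vps = GeoTrack(t=np.array([99.0]), lat=np.zeros(1), lon=np.zeros(1), kind="verified")
        with pytest.raises(ValueError):
            dr.time_match(track, vps)


class TestSegmentFactors:
    def test_identical_segments(self):
        dcf, hcf, degen = dr.segment_factors((0, 0), (0.01, 0.01), (0, 0), (0.01, 0.01))
        assert dcf == pytest.approx(1.0) and hcf == pytest.approx(0.0) and not degen

    def test_three_times_longer_rotated_90(self):
        a = (0.0, 0.0)
        dr_end = (100.0 / 111195.0, 0.0)  # 100 m north
        vp_end = (0.0, 300.0 / 111195.0)  # 300 m east
        dcf, hcf, degen = dr.segment_factors(a, dr_end, a, vp_end)
        assert dcf == pytest.approx(3.0, rel=1e-6)
        assert hcf == pytest.approx(90.0, abs=1e-6)

    def test_degenerate_flagged(self):
        dcf, hcf, degen = dr.segment_factors((0, 0), (0, 0), (0, 0), (0.01, 0))
        assert degen


class TestCorrectTrack:
    def test_track_through_vps_unchanged(self, rng):
        _, track = walk_track(rng, n=600)
        vps = track.subset(np.arange(0, 601, 60))
        vps.kind = "verified"
        corrected, report = dr.correct_track(track, vps)
        assert np.max(np.abs(corrected.lat - track.lat)) < 1e-9
        assert np.max(np.abs(corrected.lon - track.lon)) < 1e-9
        for s in report.segments:
            assert s.dcf == pytest.approx(1.0, abs=1e-9)
            assert s.hcf == pytest.approx(0.0, abs=1e-9)

    def test_anchor_exactness(self, rng):
        tv, track = walk_track(rng, n=1200, heading_offset=20.0)
        _, truth = walk_track(np.random.default_rng(12345), n=1200)
        vps = truth.subset(np.arange(0, 1201, 120))
        vps.kind = "verified"
        corrected, report = dr.correct_track(track, vps)
        for s in report.segments:
            beeline = haversine_m(s.vp_start[0], s.vp_start[1], s.vp_end[0], s.vp_end[1])
            assert s.residual_m <= max(0.01, 1e-4 * beeline)

    def test_heading_bias_recovered(self, rng):
        rng_t = np.random.default_rng(7)
        tv, truth = walk_track(rng_t, n=1800)
        rng_t2 = np.random.default_rng(7)
        _, biased = walk_track(rng_t2, n=1800, heading_offset=15.0)
        vps = truth.subset(np.arange(0, 1801, 600))
        vps.kind = "verified"
        corrected, report = dr.correct_track(biased, vps)
        hcfs = [s.hcf for s in report.segments if not s.degenerate]
        assert np.mean(hcfs) == pytest.approx(-15.0, abs=1.0)

    def test_speed_scale_recovered_as_inverse_dcf(self):
        for k in (0.5, 2.0):
            rng_t = np.random.default_rng(11)
            _, truth = walk_track(rng_t, n=1800)
            rng_t2 = np.random.default_rng(11)
            _, scaled = walk_track(rng_t2, n=1800, speed_scale=k)
            vps = truth.subset(np.arange(0, 1801, 300))
            vps.kind = "verified"
            _, report = dr.correct_track(scaled, vps)
            dcfs = [s.dcf for s in report.segments if not s.degenerate]
            assert np.mean(dcfs) == pytest.approx(1.0 / k, rel=0.01)

    def test_stationary_cluster_stays_point_coincident(self):
        rng_t = np.random.default_rng(3)
        rest = slice(200, 300)
        _, track = walk_track(rng_t, n=600, rest=rest)
        rng_t2 = np.random.default_rng(3)
        _, truth = walk_track(rng_t2, n=600, rest=rest, speed_scale=1.3)
        vps = truth.subset(np.array([0, 599]))
        vps.kind = "verified"
        corrected, _ = dr.correct_track(track, vps)
        lat_rest = corrected.lat[200:301]
        lon_rest = corrected.lon[200:301]
        assert np.ptp(lat_rest) == 0.0 and np.ptp(lon_rest) == 0.0

    def test_idempotence(self, rng):
        _, track = walk_track(rng, n=900, heading_offset=10.0, speed_scale=1.2)
        _, truth = walk_track(np.random.default_rng(12345), n=900)
        vps = truth.subset(np.arange(0, 901, 300))
        vps.kind = "verified"
        once, _ = dr.correct_track(track, vps)
        twice, report2 = dr.correct_track(once, vps)
        for s in report2.segments:
            assert s.dcf == pytest.approx(1.0, abs=1e-6)
            assert s.hcf == pytest.approx(0.0, abs=1e-6)

    def test_shape_preserved_within_segment(self):
        """Turn-angle sequence is invariant under the per-segment rotation+scale."""
        rng_t = np.random.default_rng(5)
        _, track = walk_track(rng_t, n=400)
        rng_t2 = np.random.default_rng(5)
        _, truth = walk_track(rng_t2, n=400, speed_scale=1.5)
        vps = truth.subset(np.array([0, 399]))
        vps.kind = "verified"
        corrected, _ = dr.correct_track(track, vps)

        def turn_angles(t):
            e, n = to_local_enu(t.lat, t.lon, float(t.lat[0]), float(t.lon[0]))
            de, dn = np.diff(e), np.diff(n)
            bearings = np.degrees(np.arctan2(de, dn))
            return wrap_signed_angle(np.diff(bearings))

        before = turn_angles(track)
        after = turn_angles(corrected)
        assert np.max(np.abs(wrap_signed_angle(after - before))) < 0.1

    def test_needs_two_matched_vps(self, rng):
        _, track = walk_track(rng, n=100)
        vps = track.subset(np.array([50]))
        vps.kind = "verified"
        with pytest.raises(ValueError):
            dr.correct_track(track, vps)
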