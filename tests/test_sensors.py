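"""Sensor-processing oracles: static/dynamic split, VeDBA, posture, compass,
magnetometer calibration and pressure handling."""

import numpy as np
import pytest

import deadreckon as dr
from deadreckon import sensors
from deadreckon.geodesy import wrap_signed_angle
from deadreckon.types import CalibrationModel, ImuSeries, OrientationSeries


def make_imu(n=100, fs=10.0, acc=None, mag=None, pressure=None):
    t = np.arange(n) / fs
    acc = np.tile([0.0, 0.0, 1.0], (n, 1)) if acc is None else np.asarray(acc, float)
    mag = np.tile([1.0, 0.0, 0.0], (n, 1)) if mag is None else np.asarray(mag, float)
    return ImuSeries(
        t=t,
        ax=acc[:, 0], ay=acc[:, 1], az=acc[:, 2],
        mx=mag[:, 0], my=mag[:, 1], mz=mag[:, 2],
        pressure=pressure,
    )


class TestSeparation:
    def test_constant_signal(self):
        imu = make_imu(50)
        split = dr.separate_acceleration(imu, 2.0)
        assert np.allclose(split.static, [0, 0, 1])
        assert np.allclose(split.dynamic, 0.0)

    def test_sine_removed_from_static(self):
        # 0.2 g sine at 2 Hz on the heave axis; a 2-s window spans 4 periods
        fs, n = 20.0, 400
        t = np.arange(n) / fs
        wave = 0.2 * np.sin(2 * np.pi * 2.0 * t)
        acc = np.column_stack([np.zeros(n), np.zeros(n), 1.0 + wave])
        split = dr.separate_acceleration(make_imu(n, fs, acc), 2.0)
        mid = slice(40, n - 40)
        assert np.max(np.abs(split.static[mid, 2] - 1.0)) < 0.01
        assert np.max(np.abs(split.dynamic[mid, 2] - wave[mid])) < 0.01

    def test_exact_reconstruction(self, rng):
        acc = rng.normal(0, 0.5, (200, 3))
        imu = make_imu(200, 10.0, acc)
        split = dr.separate_acceleration(imu, 1.3)
        assert np.max(np.abs(split.static + split.dynamic - acc)) < 1e-12

    def test_short_window_warns_and_passes_through(self):
        imu = make_imu(50, fs=1.0)
        with pytest.warns(UserWarning):
            split = dr.separate_acceleration(imu, 0.1)
        assert np.allclose(split.static, imu.acceleration())


class TestVedba:
    def test_pythagorean_triple_unsmoothed(self):
        split = dr.StaticDynamicSplit(
            t=np.arange(5.0),
            static=np.zeros((5, 3)),
            dynamic=np.tile([0.3, 0.0, 0.4], (5, 1)),
        )
        assert np.allclose(dr.compute_vedba(split, smooth_s=0), 0.5)

    def test_zero_dynamic(self):
        split = dr.StaticDynamicSplit(
            t=np.arange(5.0), static=np.zeros((5, 3)), dynamic=np.zeros((5, 3))
        )
        assert np.allclose(dr.compute_vedba(split), 0.0)

    def test_matches_bruteforce_oracle(self, rng):
        """Smoothed VeDBA equals a hand-rolled windowed mean of per-sample norms."""
        n, fs, smooth_s = 200, 5.0, 2.0
        dyn = rng.normal(0, 0.3, (n, 3))
        split = dr.StaticDynamicSplit(t=np.arange(n) / fs, static=np.zeros((n, 3)), dynamic=dyn)
        got = dr.compute_vedba(split, smooth_s)
        norms = np.sqrt((dyn**2).sum(axis=1))
        w = int(round(smooth_s * fs))
        half_lo, half_hi = w // 2, (w - 1) // 2  # even windows extend earlier
        expected = np.array(
            [norms[max(0, i - half_lo) : min(n, i + half_hi + 1)].mean() for i in range(n)]
        )
        assert np.max(np.abs(got - expected)) < 1e-12


class TestPitchRoll:
    def test_flat(self):
        split = dr.StaticDynamicSplit(
            t=np.arange(3.0), static=np.tile([0, 0, 1.0], (3, 1)), dynamic=np.zeros((3, 3))
        )
        ori = dr.estimate_pitch_roll(split)
        assert np.allclose(ori.pitch, 0.0) and np.allclose(ori.roll, 0.0)

    def test_nose_vertical(self):
        split = dr.StaticDynamicSplit(
            t=np.arange(3.0), static=np.tile([1.0, 0, 0], (3, 1)), dynamic=np.zeros((3, 3))
        )
        assert np.allclose(dr.estimate_pitch_roll(split).pitch, 90.0)

    def test_rotation_matrix_oracle(self, rng):
        """Gravity rotated by known Euler angles is inverted exactly."""
        n = 50
        pitch = rng.uniform(-80, 80, n)
        roll = rng.uniform(-170, 170, n)
        static = np.array(
            [
                sensors.rotation_earth_to_body(p, r, rng.uniform(0, 360)) @ [0, 0, 1.0]
                for p, r in zip(pitch, roll)
            ]
        )
        split = dr.StaticDynamicSplit(t=np.arange(float(n)), static=static, dynamic=np.zeros((n, 3)))
        ori = dr.estimate_pitch_roll(split)
        assert np.max(np.abs(ori.pitch - pitch)) < 1e-9
        assert np.max(np.abs(ori.roll - roll)) < 1e-9

    def test_unreliable_carried_forward(self):
        static = np.tile([0, 0, 1.0], (5, 1))
        static[2] = [0.01, 0.0, 0.02]  # free-fall-like, norm << 0.1 g
        split = dr.StaticDynamicSplit(t=np.arange(5.0), static=static, dynamic=np.zeros((5, 3)))
        ori = dr.estimate_pitch_roll(split)
        assert ori.unreliable[2]
        assert ori.pitch[2] == ori.pitch[1]

    def test_all_unreliable_raises(self):
        split = dr.StaticDynamicSplit(
            t=np.arange(3.0), static=np.full((3, 3), 0.01), dynamic=np.zeros((3, 3))
        )
        with pytest.raises(ValueError):
            dr.estimate_pitch_roll(split)


class TestCalibration:
    @staticmethod
    def sphere_points(rng, n=500):
        p = rng.normal(size=(n, 3))
        return p / np.linalg.norm(p, axis=1, keepdims=True)

    def test_centred_sphere_identity(self, rng):
        pts = self.sphere_points(rng) * 0.5
        cal = dr.calibrate_magnetometer(make_imu(500, 10.0, mag=pts), fit_soft_iron=True)
        assert np.allclose(cal.hard_iron_offset, 0.0, atol=1e-6)
        assert np.allclose(cal.soft_iron_matrix, np.eye(3), atol=1e-6)

    def test_translated_sphere_offset_recovered(self, rng):
        b = np.array([0.2, -0.15, 0.1])
        pts = self.sphere_points(rng) * 0.5 + b
        cal = dr.calibrate_magnetometer(make_imu(500, 10.0, mag=pts))
        assert np.allclose(cal.hard_iron_offset, b, atol=1e-6)

    def test_large_offsets_within_one_percent(self, rng):
        """Hard-iron offsets up to 50% of the field norm on 500-point spheres."""
        for frac in (0.2, 0.5):
            b = frac * np.array([1.0, -1.0, 0.5]) / np.sqrt(2.25)
            pts = self.sphere_points(rng) + b
            cal = dr.calibrate_magnetometer(make_imu(500, 10.0, mag=pts))
            assert np.linalg.norm(cal.hard_iron_offset - b) < 0.01

    def test_anisotropic_sphere_soft_iron(self, rng):
        pts = self.sphere_points(rng) @ np.diag([1.0, 2.0, 1.0])
        cal = dr.calibrate_magnetometer(make_imu(500, 10.0, mag=pts), fit_soft_iron=True)
        norms = np.linalg.norm(cal.apply_magnetic(pts), axis=1)
        assert norms.std() / norms.mean() < 1e-6

    def test_degenerate_coverage_raises(self):
        t = np.linspace(0, 2 * np.pi, 100)
        planar = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        with pytest.raises(ValueError, match="degenerate"):
            dr.calibrate_magnetometer(make_imu(100, 10.0, mag=planar))


class TestHeading:
    def test_flat_facing_north(self):
        ori = OrientationSeries(t=[0.0], pitch=[0.0], roll=[0.0])
        mag = sensors.earth_magnetic_field(60.0)[None, :]
        h = dr.tilt_compensated_heading(ori, mag, CalibrationModel(), smooth_s=0)
        assert h[0] == pytest.approx(0.0, abs=1e-9)

    def test_yaw_and_declination_additive(self):
        r = sensors.rotation_earth_to_body(0.0, 0.0, 90.0)
        mag = (r @ sensors.earth_magnetic_field(60.0))[None, :]
        ori = OrientationSeries(t=[0.0], pitch=[0.0], roll=[0.0])
        h = dr.tilt_compensated_heading(ori, mag, CalibrationModel(), smooth_s=0)
        assert h[0] == pytest.approx(90.0, abs=1e-9)
        h10 = dr.tilt_compensated_heading(
            ori, mag, CalibrationModel(declination=10.0), smooth_s=0
        )
        assert h10[0] == pytest.approx(100.0, abs=1e-9)

    def test_tilted_round_trip(self, rng):
        """Forward-simulated field at any attitude inverts to the yaw."""
        for _ in range(100):
            th = rng.uniform(-80, 80)
            ph = rng.uniform(-179, 179)
            ps = rng.uniform(0, 360)
            mag = (
                sensors.rotation_earth_to_body(th, ph, ps)
                @ sensors.earth_magnetic_field(60.0)
            )[None, :]
            ori = OrientationSeries(t=[0.0], pitch=[th], roll=[ph])
            h = dr.tilt_compensated_heading(ori, mag, CalibrationModel(), smooth_s=0)
            assert abs(wrap_signed_angle(h[0] - ps)) < 1e-6

    def test_circular_smoothing_no_discontinuity(self):
        # headings oscillating across North must average near 0, never 180
        n = 20
        ori = OrientationSeries(t=np.arange(float(n)), pitch=np.zeros(n), roll=np.zeros(n))
        angles = np.where(np.arange(n) % 2 == 0, 350.0, 10.0)
        mag = np.array(
            [
                sensors.rotation_earth_to_body(0, 0, a) @ sensors.earth_magnetic_field(60.0)
                for a in angles
            ]
        )
        h = dr.tilt_compensated_heading(ori, mag, CalibrationModel(), smooth_s=2.0)
        mid = h[2:-2]
        assert np.all((mid < 20) | (mid > 340))


class TestTagRotation:
    def test_identity(self):
        imu = make_imu(10)
        out = dr.apply_tag_rotation(imu, CalibrationModel())
        assert np.allclose(out.acceleration(), imu.acceleration())
        assert np.allclose(out.magnetism(), imu.magnetism())

    def test_roll_180_negates_sway_heave(self):
        rot = np.diag([1.0, -1.0, -1.0])
        imu = make_imu(10, acc=np.tile([0.1, 0.2, 0.9], (10, 1)))
        out = dr.apply_tag_rotation(imu, CalibrationModel(tag_rotation=rot))
        assert np.allclose(out.acceleration(), np.tile([0.1, -0.2, -0.9], (10, 1)))

    def test_round_trip_and_norms(self, rng):
        from scipy.spatial.transform import Rotation

        r = Rotation.random(random_state=7).as_matrix()
        acc = rng.normal(size=(20, 3))
        imu = make_imu(20, acc=acc)
        fwd = dr.apply_tag_rotation(imu, CalibrationModel(tag_rotation=r))
        back = dr.apply_tag_rotation(fwd, CalibrationModel(tag_rotation=r.T))
        assert np.max(np.abs(back.acceleration() - acc)) < 1e-12
        assert np.max(
            np.abs(
                np.linalg.norm(fwd.acceleration(), axis=1) - np.linalg.norm(acc, axis=1)
            )
        ) < 1e-12


class TestPressure:
    def test_constant_series(self):
        base = dr.pressure_baseline(np.full(50, 1000.0), smoothness=1e4)
        assert np.max(np.abs(base - 1000.0)) < 1e-2

    def test_ramp_with_dives(self):
        """Lower-envelope baseline recovers a linear surface drift under dives."""
        n = 2000
        ramp = 1013.0 + 0.002 * np.arange(n)
        p = ramp.copy()
        for s in range(100, n - 200, 300):
            p[s : s + 120] += 50 * np.sin(np.linspace(0, np.pi, 120))
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                base = dr.pressure_baseline(p, smoothness=1e7, asymmetry=0.01)
        assert np.max(np.abs(base - ramp)) < 0.02 * 50

    def test_subtracted_baseline_zero_depth(self):
        p = np.full(20, 1013.0)
        z = dr.pressure_to_vertical(p, p, "water")
        assert np.allclose(z, 0.0)

    def test_depth_scaling_and_clamp(self):
        base = np.full(3, 1000.0)
        p = np.array([1000.0, 1100.0, 900.0])
        z = dr.pressure_to_vertical(p, base, "water")
        assert np.allclose(z, [0.0, 1.0, 0.0])  # 100 hPa ~ 1 m; negatives clamped

    def test_altitude_closed_form(self):
        p0 = 1013.25
        # choose P so the closed form gives exactly 100 m
        p = p0 * (1 - 100.0 / 44330.0) ** (1 / 0.1903)
        alt = dr.pressure_to_vertical(np.array([p0, p]), None, "air", reference=p0)
        assert alt[0] == pytest.approx(0.0, abs=1e-9)
        assert alt[1] == pytest.approx(100.0, abs=1e-9)

    def test_air_requires_reference(self):
        with pytest.raises(ValueError):
            dr.pressure_to_vertical(np.full(5, 1000.0), None, "air")

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            dr.pressure_baseline(np.arange(5.0))
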