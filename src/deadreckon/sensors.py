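"""Sensor processing: posture, heading, VeDBA and depth/altitude from raw streams.

The processing chain mirrors standard biologging practice:

1. split raw acceleration into a gravity-dominated *static* part (centred
   running mean) and a movement *dynamic* residual;
2. VeDBA = ||dynamic|| smoothed by ~2 s, the locomotion-intensity speed proxy;
3. pitch/roll from the static (gravity) vector, Euler convention;
4. hard-/soft-iron magnetometer calibration by least-squares sphere or
   ellipsoid fit;
5. tilt-compensated compass heading: de-rotate the magnetic vector by pitch
   and roll, take the horizontal arctangent, add declination, smooth with a
   rolling circular mean;
6. asymmetric-least-squares pressure baseline and conversion to depth or
   barometric altitude.

Frame conventions
-----------------
Body axes are surge (forward), sway (right), heave (up through the back);
an upright motionless animal senses gravity as (0, 0, +1) g. The Earth
frame is North/East/Up. A body attitude (pitch th, roll ph, yaw psi) maps
Earth vectors into the body frame as ``R_roll(ph) @ R_pitch(th) @ R_yaw(psi)``
with yaw measured clockwise from North.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .geodesy import wrap_heading
from .types import CalibrationModel, ImuSeries, OrientationSeries, StaticDynamicSplit

GIMBAL_GUARD_DEG = 89.5
MIN_STATIC_NORM_G = 0.1


# ---------------------------------------------------------------------------
# rotation helpers (shared with the simulator, which inverts this model)

def rotation_earth_to_body(pitch_deg, roll_deg, yaw_deg) -> np.ndarray:
    """Rotation matrix mapping Earth-frame (N, E, Up) vectors to body frame.

    Accepts scalars; returns (3, 3). Yaw is heading clockwise from North,
    pitch positive nose-up, roll positive right-side-down.
    """
    th, ph, ps = np.radians([pitch_deg, roll_deg, yaw_deg])
    r_yaw = np.array(
        [[np.cos(ps), np.sin(ps), 0.0], [-np.sin(ps), np.cos(ps), 0.0], [0.0, 0.0, 1.0]]
    )
    r_pitch = np.array(
        [[np.cos(th), 0.0, np.sin(th)], [0.0, 1.0, 0.0], [-np.sin(th), 0.0, np.cos(th)]]
    )
    r_roll = np.array(
        [[1.0, 0.0, 0.0], [0.0, np.cos(ph), np.sin(ph)], [0.0, -np.sin(ph), np.cos(ph)]]
    )
    return r_roll @ r_pitch @ r_yaw


def earth_magnetic_field(inclination_deg: float, strength: float = 1.0) -> np.ndarray:
    """Earth-frame magnetic field vector at the given dip angle.

    Points toward magnetic North with a downward component for positive
    inclination (northern-hemisphere convention), in the N/E/Up frame.
    """
    i = np.radians(inclination_deg)
    return strength * np.array([np.cos(i), 0.0, -np.sin(i)])


# ---------------------------------------------------------------------------
# smoothing primitives

def running_mean(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centred running mean with shrinking windows at the edges.

    Preserves series length; a window of 1 returns the input unchanged.
    """
    if window_samples <= 1:
        return np.asarray(x, dtype=float).copy()
    s = pd.Series(np.asarray(x, dtype=float))
    return s.rolling(window_samples, center=True, min_periods=1).mean().to_numpy()


def circular_running_mean_deg(angles_deg: np.ndarray, window_samples: int) -> np.ndarray:
    """Centred rolling circular mean of angles in degrees, result in [0, 360)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    s = running_mean(np.sin(a), window_samples)
    c = running_mean(np.cos(a), window_samples)
    return wrap_heading(np.degrees(np.arctan2(s, c)))


def _window_samples(window_s: float, dt: float) -> int:
    return max(1, int(round(window_s / dt)))


# ---------------------------------------------------------------------------
# static/dynamic split and VeDBA

def separate_acceleration(imu: ImuSeries, window_s: float = 2.0) -> StaticDynamicSplit:
    """Split raw acceleration into static (gravity) and dynamic components.

    Static is the centred running mean over ``window_s`` per axis; dynamic
    is the exact residual, so ``static + dynamic == raw`` per sample.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    if window_s < imu.dt:
        warnings.warn("static window shorter than one sample; static == raw")
    w = _window_samples(window_s, imu.dt)
    raw = imu.acceleration()
    static = np.column_stack([running_mean(raw[:, k], w) for k in range(3)])
    return StaticDynamicSplit(t=imu.t, static=static, dynamic=raw - static)


def compute_vedba(split: StaticDynamicSplit, smooth_s: float = 2.0) -> np.ndarray:
    """VeDBA: per-sample norm of dynamic acceleration, running-mean smoothed.

    ``smooth_s = 0`` disables smoothing. Result is non-negative, in g.
    """
    norm = np.linalg.norm(split.dynamic, axis=1)
    if smooth_s <= 0:
        return norm
    return running_mean(norm, _window_samples(smooth_s, split.dt))


# ---------------------------------------------------------------------------
# posture

def estimate_pitch_roll(split: StaticDynamicSplit) -> OrientationSeries:
    """Pitch and roll (deg) from the static-acceleration gravity estimate.

    pitch = arcsin(static_surge / ||static||), roll = atan2(sway, heave).
    Samples whose static norm is <= 0.1 g are flagged unreliable and carry
    forward the last reliable value.
    """
    s = split.static
    norm = np.linalg.norm(s, axis=1)
    reliable = norm > MIN_STATIC_NORM_G
    if not np.any(reliable):
        raise ValueError("no sample has a reliable static-acceleration norm (> 0.1 g)")
    safe_norm = np.where(reliable, norm, 1.0)
    pitch = np.degrees(np.arcsin(np.clip(s[:, 0] / safe_norm, -1.0, 1.0)))
    roll = np.degrees(np.arctan2(s[:, 1], s[:, 2]))
    pitch = _carry_forward(pitch, reliable)
    roll = _carry_forward(roll, reliable)
    return OrientationSeries(t=split.t, pitch=pitch, roll=roll, unreliable=~reliable)


def _carry_forward(values: np.ndarray, good: np.ndarray) -> np.ndarray:
    """Replace bad samples by the last good value (first good value if leading)."""
    out = values.copy()
    idx = np.where(good, np.arange(good.size), -1)
    idx = np.maximum.accumulate(idx)
    first_good = int(np.argmax(good))
    idx[idx < 0] = first_good
    return out[idx]


# ---------------------------------------------------------------------------
# magnetometer calibration

def calibrate_magnetometer(
    imu: ImuSeries,
    fit_soft_iron: bool = False,
    declination: float = 0.0,
    tag_rotation: np.ndarray | None = None,
) -> CalibrationModel:
    """Least-squares magnetometer calibration from orientation-diverse data.

    The default fits the hard-iron offset only (sphere fit); with
    ``fit_soft_iron`` an ellipsoid fit also recovers the symmetric
    positive-definite soft-iron correction that restores a spherical
    field locus at the mean field strength.
    """
    m = imu.magnetism()
    centred = m - m.mean(axis=0)
    svals = np.linalg.svd(centred, compute_uv=False)
    if svals.size < 3 or svals[-1] <= 1e-9 * max(svals[0], 1e-30):
        axis = np.abs(np.linalg.svd(centred, full_matrices=False)[2][-1]).argmax()
        raise ValueError(
            f"degenerate orientation coverage: magnetic data nearly planar along axis "
            f"{'xyz'[axis]}"
        )
    if fit_soft_iron:
        offset, soft, strength = _fit_ellipsoid(m)
    else:
        offset, strength = _fit_sphere(m)
        soft = np.eye(3)
    return CalibrationModel(
        hard_iron_offset=offset,
        soft_iron_matrix=soft,
        declination=declination,
        tag_rotation=np.eye(3) if tag_rotation is None else tag_rotation,
        field_strength=strength,
    )


def _fit_sphere(m: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere fit: centre and radius."""
    a = np.column_stack([2.0 * m, np.ones(m.shape[0])])
    b = np.sum(m**2, axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    centre = sol[:3]
    radius = float(np.sqrt(max(sol[3] + centre @ centre, 0.0)))
    return centre, radius


def _fit_ellipsoid(m: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Algebraic ellipsoid fit x'Ax + 2b'x = 1; returns (centre, W, strength).

    W is the symmetric positive-definite matrix mapping centred data onto a
    sphere of the mean centred-norm radius.
    """
    x, y, z = m[:, 0], m[:, 1], m[:, 2]
    d = np.column_stack(
        [x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z, 2 * x, 2 * y, 2 * z]
    )
    sol, *_ = np.linalg.lstsq(d, np.ones(m.shape[0]), rcond=None)
    a_mat = np.array(
        [
            [sol[0], sol[3], sol[4]],
            [sol[3], sol[1], sol[5]],
            [sol[4], sol[5], sol[2]],
        ]
    )
    b_vec = sol[6:9]
    centre = -np.linalg.solve(a_mat, b_vec)
    k = 1.0 + b_vec @ np.linalg.solve(a_mat, b_vec)
    m_norm = a_mat / k  # (x-c)' M (x-c) = 1 on the fitted surface
    eigval, eigvec = np.linalg.eigh(m_norm)
    if np.any(eigval <= 0):
        raise ValueError("ellipsoid fit produced a non-positive-definite shape matrix")
    w_unit = eigvec @ np.diag(np.sqrt(eigval)) @ eigvec.T  # maps onto unit sphere
    centred = m - centre
    strength = float(np.mean(np.linalg.norm(centred, axis=1)))
    return centre, strength * w_unit, strength


# ---------------------------------------------------------------------------
# heading

def tilt_compensated_heading(
    orientation: OrientationSeries,
    mag_calibrated: np.ndarray,
    cal: CalibrationModel,
    smooth_s: float = 1.0,
) -> np.ndarray:
    """Heading (deg clockwise from true North) by the tilt-compensated compass.

    De-rotates the calibrated magnetic vector to the Earth-horizontal plane
    using pitch and roll, takes the horizontal arctangent, adds the magnetic
    declination, and applies a rolling circular mean over ``smooth_s``.
    Gimbal-adjacent samples (|pitch| >= 89.5 deg) and samples whose
    horizontal field nearly vanishes carry forward the last reliable value.
    """
    mag = np.asarray(mag_calibrated, dtype=float)
    if mag.shape != (orientation.t.size, 3):
        raise ValueError("mag_calibrated must be (n, 3) aligned with orientation")
    th = np.radians(orientation.pitch)
    ph = np.radians(orientation.roll)
    # undo roll: R_roll(ph)^T
    m1x = mag[:, 0]
    m1y = np.cos(ph) * mag[:, 1] - np.sin(ph) * mag[:, 2]
    m1z = np.sin(ph) * mag[:, 1] + np.cos(ph) * mag[:, 2]
    # undo pitch: R_pitch(th)^T
    mhx = np.cos(th) * m1x - np.sin(th) * m1z
    mhy = m1y
    heading_mag = np.degrees(np.arctan2(-mhy, mhx))
    heading = wrap_heading(heading_mag + cal.declination)

    total = np.linalg.norm(mag, axis=1)
    horizontal = np.hypot(mhx, mhy)
    ok = (np.abs(orientation.pitch) < GIMBAL_GUARD_DEG) & (
        horizontal > 1e-9 * np.maximum(total, 1e-30)
    )
    if not np.any(ok):
        raise ValueError("no sample yields a reliable heading")
    heading = _carry_forward(heading, ok)
    if smooth_s > 0:
        dt = float(orientation.t[1] - orientation.t[0]) if orientation.t.size > 1 else 1.0
        heading = circular_running_mean_deg(heading, _window_samples(smooth_s, dt))
    return heading


def apply_tag_rotation(imu: ImuSeries, cal: CalibrationModel) -> ImuSeries:
    """Rotate acceleration and magnetism from tag frame into body frame."""
    r = cal.tag_rotation
    if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
        raise ValueError("tag_rotation must be orthonormal")
    acc = imu.acceleration() @ r.T
    mag = imu.magnetism() @ r.T
    return ImuSeries(
        t=imu.t,
        ax=acc[:, 0],
        ay=acc[:, 1],
        az=acc[:, 2],
        mx=mag[:, 0],
        my=mag[:, 1],
        mz=mag[:, 2],
        pressure=None if imu.pressure is None else imu.pressure.copy(),
        dropped_rows=imu.dropped_rows,
    )


# ---------------------------------------------------------------------------
# pressure

def pressure_baseline(
    pressure: np.ndarray,
    smoothness: float = 1e7,
    asymmetry: float = 0.01,
    max_iter: int = 20,
    tol: float = 1e-8,
) -> np.ndarray:
    """Baseline drift of a pressure series by asymmetric penalised least squares.

    Iteratively reweighted Whittaker smoother: points above the baseline get
    weight ``asymmetry`` and points below ``1 - asymmetry``, so with
    ``asymmetry < 0.5`` the baseline tracks the lower envelope (the surface
    pressure under positive dive excursions). Iterates until the baseline
    changes by < ``tol`` (sup-norm) or ``max_iter`` sweeps, returning the
    last iterate with a warning on non-convergence.
    """
    y = np.asarray(pressure, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("pressure series must have at least 10 samples")
    if not 0.0 < asymmetry < 1.0:
        raise ValueError("asymmetry must be in (0, 1)")
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = smoothness * (d.T @ d)
    w = np.ones(n)
    z = y.copy()
    for _ in range(max_iter):
        lhs = sparse.diags(w, format="csc") + penalty
        z_new = spsolve(lhs, w * y)
        delta = float(np.max(np.abs(z_new - z)))
        z = z_new
        w = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if delta < tol:
            break
    else:
        warnings.warn("pressure baseline did not converge in 20 iterations")
    return z


def pressure_to_vertical(
    pressure: np.ndarray,
    baseline: np.ndarray | None = None,
    medium: str = "water",
    reference: float | np.ndarray | None = None,
    metres_per_unit: float = 0.01,
    t: np.ndarray | None = None,
    reference_t: np.ndarray | None = None,
) -> np.ndarray:
    """Convert pressure to depth (m, positive down) or altitude (m, positive up).

    Water: depth = (pressure - baseline) * metres_per_unit, clamped at >= 0
    (default 0.01 m per hPa: 1 hPa ~ 1 cm of water column). Air: barometric
    altitude = 44330 * (1 - (P / P0)**0.1903) with P0 the reference sea-level
    pressure, a scalar or a series linearly interpolated onto the sample
    times.
    """
    p = np.asarray(pressure, dtype=float)
    if medium == "water":
        if baseline is None:
            raise ValueError("water medium requires a baseline series")
        depth = (p - np.asarray(baseline, dtype=float)) * metres_per_unit
        return np.clip(depth, 0.0, None)
    if medium == "air":
        if reference is None:
            raise ValueError("air medium requires a reference sea-level pressure")
        p0 = np.asarray(reference, dtype=float)
        if p0.ndim > 0 and p0.size != p.size:
            if t is None or reference_t is None:
                raise ValueError("reference series needs t and reference_t for interpolation")
            p0 = np.interp(t, reference_t, p0)
        return 44330.0 * (1.0 - (p / p0) ** 0.1903)
    raise ValueError(f"unknown medium {medium!r}")
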