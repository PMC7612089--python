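"""Core containers for the dead-reckoning pipeline.

Lightweight dataclasses over numpy arrays, validated on construction.
Series types are uniformly sampled (``ImuSeries``) or timestamped
(``GeoTrack``); all keep time as float seconds since an arbitrary epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


def _as_f64(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


@dataclass
class ImuSeries:
    """Uniformly sampled tri-axial inertial/magnetic (+ optional pressure) stream.

    Axes follow the surge / sway / heave body convention: ``ax`` anterior-
    posterior (positive forward), ``ay`` medio-lateral (positive right),
    ``az`` dorsal-ventral (positive up through the back, so ``az ~ +1 g``
    for an upright, motionless animal). Acceleration is in g; magnetism in
    any consistent unit (heading needs only ratios); pressure in hPa or an
    equivalent depth-pressure unit.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    mx: np.ndarray
    my: np.ndarray
    mz: np.ndarray
    pressure: Optional[np.ndarray] = None
    dropped_rows: int = 0

    def __post_init__(self) -> None:
        self.t = _as_f64(self.t)
        for name in ("ax", "ay", "az", "mx", "my", "mz"):
            setattr(self, name, _as_f64(getattr(self, name)))
        if self.pressure is not None:
            self.pressure = _as_f64(self.pressure)
        n = self.t.size
        if n == 0:
            raise ValueError("empty ImuSeries")
        for name in ("ax", "ay", "az", "mx", "my", "mz"):
            if getattr(self, name).size != n:
                raise ValueError(f"length mismatch for {name}")
        if self.pressure is not None and self.pressure.size != n:
            raise ValueError("length mismatch for pressure")
        if n > 1:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.ptp(steps) > 1e-6:
                raise ValueError("non-uniform sampling beyond 1e-6 s tolerance")
        for name in ("t", "ax", "ay", "az", "mx", "my", "mz"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        """Sample step in seconds (1.0 for a single-sample series)."""
        return float(self.t[1] - self.t[0]) if self.n > 1 else 1.0

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    def acceleration(self) -> np.ndarray:
        """(n, 3) acceleration array in g."""
        return np.column_stack([self.ax, self.ay, self.az])

    def magnetism(self) -> np.ndarray:
        """(n, 3) magnetic-field array."""
        return np.column_stack([self.mx, self.my, self.mz])


@dataclass
class StaticDynamicSplit:
    """Gravity (static) vs movement (dynamic) partition of raw acceleration.

    Invariant: ``static + dynamic`` reconstructs the raw signal exactly.
    """

    t: np.ndarray
    static: np.ndarray  # (n, 3) in g
    dynamic: np.ndarray  # (n, 3) in g

    def __post_init__(self) -> None:
        self.t = _as_f64(self.t)
        self.static = _as_f64(self.static)
        self.dynamic = _as_f64(self.dynamic)
        if self.static.shape != (self.t.size, 3) or self.dynamic.shape != (self.t.size, 3):
            raise ValueError("static/dynamic must be (n, 3)")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else 1.0


@dataclass
class OrientationSeries:
    """Per-sample posture (pitch, roll) and optionally heading, in degrees.

    pitch in [-90, 90] positive nose-up; roll in (-180, 180]; heading
    clockwise from true North in [0, 360). ``unreliable`` flags samples
    where the static-acceleration norm was too small for a trustworthy
    gravity direction (value carried forward from the last good sample).
    """

    t: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    heading: Optional[np.ndarray] = None
    unreliable: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = _as_f64(self.t)
        self.pitch = _as_f64(self.pitch)
        self.roll = _as_f64(self.roll)
        if self.heading is not None:
            self.heading = _as_f64(self.heading)
        if self.unreliable is None:
            self.unreliable = np.zeros(self.t.size, dtype=bool)
        if np.any(np.abs(self.pitch) > 90.0 + 1e-9):
            raise ValueError("pitch out of [-90, 90]")


@dataclass
class CalibrationModel:
    """Magnetometer + tag-placement calibration.

    ``hard_iron_offset`` is subtracted from raw magnetism;
    ``soft_iron_matrix`` (symmetric positive-definite) then maps the
    residual onto a sphere of the mean field strength. ``declination``
    (deg, positive East) converts magnetic to true heading.
    ``tag_rotation`` maps tag frame -> body frame.
    """

    hard_iron_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    soft_iron_matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    declination: float = 0.0
    tag_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    field_strength: float = 1.0

    def __post_init__(self) -> None:
        self.hard_iron_offset = _as_f64(self.hard_iron_offset).reshape(3)
        self.soft_iron_matrix = _as_f64(self.soft_iron_matrix).reshape(3, 3)
        self.tag_rotation = _as_f64(self.tag_rotation).reshape(3, 3)
        eigvals = np.linalg.eigvalsh(0.5 * (self.soft_iron_matrix + self.soft_iron_matrix.T))
        if np.any(eigvals <= 0):
            raise ValueError("soft_iron_matrix must be positive-definite")
        r = self.tag_rotation
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9) or not np.isclose(
            np.linalg.det(r), 1.0, atol=1e-9
        ):
            raise ValueError("tag_rotation must be a proper rotation matrix")

    def apply_magnetic(self, mag: np.ndarray) -> np.ndarray:
        """Correct (n, 3) raw magnetism for hard- and soft-iron distortion."""
        return (np.asarray(mag, dtype=float) - self.hard_iron_offset) @ self.soft_iron_matrix.T


@dataclass
class SpeedSeries:
    """Per-sample speed (m/s) with a provenance label per sample.

    Labels: ``vedba``, ``behaviour``, ``vertical``, ``gps``, ``gated-zero``.
    """

    t: np.ndarray
    speed: np.ndarray
    source: np.ndarray

    def __post_init__(self) -> None:
        self.t = _as_f64(self.t)
        self.speed = _as_f64(self.speed)
        self.source = np.asarray(self.source, dtype=object)
        if self.speed.size != self.t.size or self.source.size != self.t.size:
            raise ValueError("length mismatch in SpeedSeries")
        if np.any(self.speed < 0):
            raise ValueError("speeds must be >= 0")


@dataclass
class TravelVectorSeries:
    """Per-step travel vectors: heading (deg), speed (m/s), vertical step dz (m).

    ``dz`` is the signed vertical displacement per step; positive means
    deeper for aquatic media (``medium='water'``) and higher for aerial.
    Each row is one integration step of duration ``dt``.
    """

    t: np.ndarray
    heading: np.ndarray
    speed: np.ndarray
    dz: Optional[np.ndarray] = None
    medium: str = "land"

    def __post_init__(self) -> None:
        self.t = _as_f64(self.t)
        self.heading = _as_f64(self.heading)
        self.speed = _as_f64(self.speed)
        n = self.t.size
        if n == 0:
            raise ValueError("empty TravelVectorSeries")
        if self.heading.size != n or self.speed.size != n:
            raise ValueError("length mismatch in TravelVectorSeries")
        if self.dz is None:
            self.dz = np.zeros(n)
        else:
            self.dz = _as_f64(self.dz)
            if self.dz.size != n:
                raise ValueError("length mismatch for dz")
        if np.any(self.speed < 0):
            raise ValueError("speeds must be >= 0")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else 1.0


@dataclass
class GeoTrack:
    """Ordered timestamped positions (WGS-84 decimal degrees, z in metres).

    ``kind`` is ``dead_reckoned`` or ``verified``. z is depth or altitude
    depending on the medium; 0 for a 2-D track.
    """

    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    z: Optional[np.ndarray] = None
    kind: str = "dead_reckoned"

    def __post_init__(self) -> None:
        self.t = _as_f64(self.t)
        self.lat = _as_f64(self.lat)
        self.lon = _as_f64(self.lon)
        n = self.t.size
        if self.lat.size != n or self.lon.size != n:
            raise ValueError("length mismatch in GeoTrack")
        if self.z is None:
            self.z = np.zeros(n)
        else:
            self.z = _as_f64(self.z)
            if self.z.size != n:
                raise ValueError("length mismatch for z")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(np.abs(self.lat) > 90.0):
            raise ValueError("latitude out of [-90, 90]")
        if np.any((self.lon <= -180.0) | (self.lon > 180.0)):
            raise ValueError("longitude out of (-180, 180]")

    @property
    def n(self) -> int:
        return self.t.size

    def subset(self, idx) -> "GeoTrack":
        return GeoTrack(self.t[idx], self.lat[idx], self.lon[idx], self.z[idx], self.kind)


@dataclass
class CurrentField:
    """Gridded (lon, lat, time) -> (u east, v north) flow field in m/s.

    Regular lon/lat grid, arbitrary (sorted) time layers. Queries outside
    the grid return (0, 0); the miss count is kept for diagnostics.
    """

    lon: np.ndarray  # (nlon,) ascending
    lat: np.ndarray  # (nlat,) ascending
    time: np.ndarray  # (nt,) ascending
    u: np.ndarray  # (nt, nlat, nlon)
    v: np.ndarray  # (nt, nlat, nlon)
    out_of_grid_count: int = 0

    def __post_init__(self) -> None:
        self.lon = _as_f64(self.lon)
        self.lat = _as_f64(self.lat)
        self.time = _as_f64(self.time)
        self.u = _as_f64(self.u)
        self.v = _as_f64(self.v)
        shape = (self.time.size, self.lat.size, self.lon.size)
        if self.u.shape != shape or self.v.shape != shape:
            raise ValueError(f"u/v must have shape {shape}")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("non-finite current components")


@dataclass
class CorrectionSegment:
    """Per-segment drift-correction factors and diagnostics."""

    t_start: float
    t_end: float
    vp_start: tuple
    vp_end: tuple
    dcf: float
    hcf: float
    residual_m: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and self.dcf < 0:
            raise ValueError("dcf must be >= 0")
        if self.residual_m < 0:
            raise ValueError("residual must be >= 0")


@dataclass
class CorrectionReport:
    """Ordered correction segments plus bookkeeping counts."""

    segments: list
    vps_used: int = 0
    vps_skipped: int = 0
    degenerate_count: int = 0
    extreme_dcf_count: int = 0

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "t_start": s.t_start,
                "t_end": s.t_end,
                "dcf": s.dcf,
                "hcf": s.hcf,
                "residual_m": s.residual_m,
                "degenerate": s.degenerate,
            }
            for s in self.segments
        ]
        return pd.DataFrame(rows)


@dataclass
class NetErrorSeries:
    """Per-VP net error (m) of a corrected track, with summary statistics."""

    t: np.ndarray
    error_m: np.ndarray

    def __post_init__(self) -> None:
        self.t = _as_f64(self.t)
        self.error_m = _as_f64(self.error_m)
        if np.any(self.error_m < 0):
            raise ValueError("net error must be >= 0")

    @property
    def mean(self) -> float:
        return float(np.mean(self.error_m))

    @property
    def median(self) -> float:
        return float(np.median(self.error_m))
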