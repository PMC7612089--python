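"""Synthetic study data: ground-truth movement, consistent sensor streams,
noisy dropout-prone verified positions and current fields.

The animal is a state-switching correlated random walk: a semi-Markov state
sequence (exponential dwell times) where each behaviour state sets a mean
speed (positive AR(1) around it), a turn-angle spread for the wrapped-
normal heading walk, and a vertical rate. Sensor streams are generated by
*inverting* the processing model — gravity rotated by the true attitude,
an Earth magnetic field at configurable inclination/declination rotated
into the tag frame (plus an optional hard-iron offset), stride-like
dynamic acceleration whose smoothed VeDBA encodes speed through a linear
coupling, and pressure from depth/altitude — so the whole pipeline closes
the loop on known truth.

Deliberate sensor errors can be injected for identifiability studies:
``heading_bias`` (a tag-yaw offset, deg) and ``speed_scale_error`` (a
multiplicative error on the encoded speed). All randomness derives from
one integer seed via ``numpy.random.SeedSequence`` stream spawning, so a
fixed seed gives bitwise-reproducible outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geodesy import forward_step, wrap_heading
from .sensors import earth_magnetic_field, rotation_earth_to_body
from .sensors import running_mean as _sensors_running_mean
from .types import CurrentField, GeoTrack, ImuSeries

STANDARD_SEA_LEVEL_HPA = 1013.25


@dataclass
class StateSpec:
    """One behaviour state of the movement regime.

    ``speed_mean`` m/s with coefficient of variation ``speed_cv``;
    ``turn_sd_deg`` per-step wrapped-normal heading increment s.d. (0 =
    perfectly straight); ``vertical_rate`` m/s, positive down for water
    and up for air; ``dwell_mean_s`` mean exponential dwell time.
    """

    name: str
    speed_mean: float
    speed_cv: float = 0.0
    turn_sd_deg: float = 5.0
    vertical_rate: float = 0.0
    dwell_mean_s: float = 300.0


@dataclass
class MagSpec:
    """Magnetic environment: dip angle, declination (deg E) and hard-iron offset."""

    inclination_deg: float = 60.0
    declination_deg: float = 0.0
    strength: float = 1.0
    hard_iron_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass
class GpsSpec:
    """Verified-position sampling: fix interval, isotropic error s.d. and the
    depth above which no fix is obtained (None disables dropouts)."""

    fix_interval_s: float = 1.0
    error_sd_m: float = 0.0
    dropout_depth_m: Optional[float] = None


@dataclass
class CurrentSpec:
    """Constant (u, v) flow or a solid-body gyre of given angular rate."""

    kind: str = "constant"  # constant | gyre
    u: float = 0.0
    v: float = 0.0
    gyre_centre: tuple[float, float] = (0.0, 0.0)  # lat, lon
    gyre_omega: float = 1e-4  # rad/s solid-body rotation


@dataclass
class SimConfig:
    """Full scenario description; the defaults are a terrestrial walker."""

    seed: int = 0
    duration_s: float = 3600.0
    fs: float = 1.0
    medium: str = "land"  # land | water | air
    start: tuple[float, float] = (-25.0, 20.0)  # lat, lon
    states: Sequence[StateSpec] = field(
        default_factory=lambda: [
            StateSpec("travel", speed_mean=0.8, speed_cv=0.1, turn_sd_deg=4.0, dwell_mean_s=600.0),
            StateSpec("rest", speed_mean=0.0, turn_sd_deg=0.0, dwell_mean_s=200.0),
        ]
    )
    heading_bias_deg: float = 0.0
    speed_scale_error: float = 1.0
    m_true: float = 2.5  # VeDBA-speed gradient, m/s per g
    c_true: float = 0.0  # intercept, m/s
    vedba_noise_sd: float = 0.0
    speed_ar1: float = 0.9
    mag: MagSpec = field(default_factory=MagSpec)
    gps: GpsSpec = field(default_factory=GpsSpec)
    current: Optional[CurrentSpec] = None
    surface_pressure_hpa: float = STANDARD_SEA_LEVEL_HPA

    def __post_init__(self) -> None:
        if self.fs < 1:
            raise ValueError("fs must be >= 1 Hz")
        if any(s.speed_cv < 0 for s in self.states):
            raise ValueError("speed CV must be >= 0")


@dataclass
class GroundTruth:
    """True positions plus the per-step heading, speed and state labels.

    ``track`` has n + 1 positions; ``heading``/``speed``/``vertical_rate``/
    ``state`` have n entries, one per integration step, timestamped at the
    step start. Consecutive true positions satisfy the destination-point
    relation exactly by construction.
    """

    track: GeoTrack
    t: np.ndarray
    heading: np.ndarray
    speed: np.ndarray
    vertical_rate: np.ndarray
    state: np.ndarray


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_truth(cfg: SimConfig) -> GroundTruth:
    """Generate the ground-truth movement path for a scenario."""
    rng_state, rng_turn, rng_speed, _, _ = _streams(cfg.seed, 5)
    dt = 1.0 / cfg.fs
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) * dt

    # semi-Markov state sequence: exponential dwells, cyclic state order
    state_idx = np.empty(n, dtype=int)
    pos, k = 0, 0
    while pos < n:
        spec = cfg.states[k % len(cfg.states)]
        dwell = max(1, int(round(rng_state.exponential(spec.dwell_mean_s) * cfg.fs)))
        state_idx[pos : pos + dwell] = k % len(cfg.states)
        pos += dwell
        k += 1

    turn_sd = np.array([s.turn_sd_deg for s in cfg.states])[state_idx]
    speed_mean = np.array([s.speed_mean for s in cfg.states])[state_idx]
    speed_sd = speed_mean * np.array([s.speed_cv for s in cfg.states])[state_idx]
    vrate = np.array([s.vertical_rate for s in cfg.states])[state_idx]
    # animals ramp their dive/climb angle rather than flipping it
    # instantaneously: smooth the vertical rate over ~5 s at transitions
    vrate = _sensors_running_mean(vrate, max(1, int(round(5.0 * cfg.fs))))

    heading = np.empty(n)
    heading[0] = rng_turn.uniform(0.0, 360.0)
    increments = rng_turn.normal(0.0, 1.0, size=n) * turn_sd
    heading[1:] = heading[0] + np.cumsum(increments[1:])
    heading = wrap_heading(heading)

    # positive AR(1) speed around the state mean
    phi = cfg.speed_ar1
    innov_sd = speed_sd * np.sqrt(max(1.0 - phi**2, 0.0))
    eps = rng_speed.normal(0.0, 1.0, size=n) * innov_sd
    speed = np.empty(n)
    speed[0] = max(speed_mean[0] + eps[0] * (1 if innov_sd[0] else 0), 0.0)
    for i in range(1, n):
        speed[i] = max(speed_mean[i] + phi * (speed[i - 1] - speed_mean[i]) + eps[i], 0.0)

    lat = np.empty(n + 1)
    lon = np.empty(n + 1)
    lat[0], lon[0] = cfg.start
    cur = cfg.start
    for i in range(n):
        d = speed[i] * dt
        if d > 0:
            cur = forward_step(cur[0], cur[1], heading[i], d)
        lat[i + 1], lon[i + 1] = cur

    z = np.concatenate([[0.0], np.cumsum(vrate * dt)])
    if cfg.medium in ("water", "air"):
        # saturate at the surface/ground: z_i = max(z_{i-1} + dz_i, 0),
        # vectorised via the running-minimum identity; then re-derive the
        # realised vertical rate so pitch stays consistent with the profile
        z = z - np.minimum(0.0, np.minimum.accumulate(z))
        vrate = np.diff(z) / dt
    track_t = np.concatenate([t, [t[-1] + dt]])
    track = GeoTrack(t=track_t, lat=lat, lon=lon, z=z, kind="dead_reckoned")
    states = np.array([cfg.states[i].name for i in state_idx], dtype=object)
    return GroundTruth(
        track=track, t=t, heading=heading, speed=speed, vertical_rate=vrate, state=states
    )


def true_pitch_deg(truth: GroundTruth, medium: str) -> np.ndarray:
    """Body pitch implied by the vertical rate and horizontal speed."""
    up_rate = -truth.vertical_rate if medium == "water" else truth.vertical_rate
    return np.degrees(np.arctan2(up_rate, truth.speed))


def simulate_imu(truth: GroundTruth, cfg: SimConfig) -> ImuSeries:
    """Sensor streams consistent with the truth (inverse sensor model).

    Static acceleration is gravity rotated by the true pitch (roll fixed at
    0); dynamic acceleration is a stride-like heave oscillation alternating
    sign every sample whose magnitude makes the smoothed VeDBA encode
    ``speed_scale_error * speed`` through the linear coupling
    ``speed = m_true * VeDBA + c_true``; magnetism is the Earth field
    rotated into the tag frame at yaw ``true heading + heading_bias`` plus
    the hard-iron offset; pressure follows depth (hydrostatic) or altitude
    (barometric).
    """
    _, _, _, rng_noise, _ = _streams(cfg.seed, 5)
    n = truth.t.size
    pitch = true_pitch_deg(truth, cfg.medium)
    yaw = wrap_heading(truth.heading + cfg.heading_bias_deg)

    # VeDBA target per sample, from the (possibly mis-scaled) speed
    target = (cfg.speed_scale_error * truth.speed - cfg.c_true) / cfg.m_true
    target = np.clip(target, 0.0, None)
    if cfg.vedba_noise_sd > 0:
        target = np.clip(target + rng_noise.normal(0.0, cfg.vedba_noise_sd, n), 0.0, None)
    sign = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)

    d = cfg.mag.declination_deg
    inc = cfg.mag.inclination_deg
    m_mag_frame = earth_magnetic_field(inc, cfg.mag.strength)
    cd, sd_ = np.cos(np.radians(d)), np.sin(np.radians(d))
    # horizontal component points at bearing = declination in the true-North frame
    m_earth = np.array(
        [m_mag_frame[0] * cd, m_mag_frame[0] * sd_, m_mag_frame[2]]
    )

    acc = np.empty((n, 3))
    mag = np.empty((n, 3))
    g_earth = np.array([0.0, 0.0, 1.0])
    for i in range(n):
        r = rotation_earth_to_body(pitch[i], 0.0, yaw[i])
        acc[i] = r @ g_earth
        mag[i] = r @ m_earth
    acc[:, 2] += sign * target  # heave stride impacts
    mag += np.asarray(cfg.mag.hard_iron_offset, dtype=float)

    z = truth.track.z[:-1]
    if cfg.medium == "water":
        pressure = cfg.surface_pressure_hpa + z * 100.0  # 1 cm water ~ 1 hPa
    elif cfg.medium == "air":
        pressure = cfg.surface_pressure_hpa * (1.0 - z / 44330.0) ** (1.0 / 0.1903)
    else:
        pressure = np.full(n, cfg.surface_pressure_hpa)

    return ImuSeries(
        t=truth.t,
        ax=acc[:, 0],
        ay=acc[:, 1],
        az=acc[:, 2],
        mx=mag[:, 0],
        my=mag[:, 1],
        mz=mag[:, 2],
        pressure=pressure,
    )


def simulate_vps(truth: GroundTruth, cfg: SimConfig) -> GeoTrack:
    """Noisy, dropout-prone verified positions along the truth.

    Fixes at the configured interval, displaced by isotropic Gaussian noise
    in the local tangent plane; fixes taken while deeper than the dropout
    threshold are deleted (no fix under water).
    """
    _, _, _, _, rng_gps = _streams(cfg.seed, 5)
    tt = truth.track.t
    fix_t = np.arange(tt[0], tt[-1] + 1e-9, cfg.gps.fix_interval_s)
    idx = np.clip(np.searchsorted(tt, fix_t), 0, tt.size - 1)
    lat = truth.track.lat[idx].copy()
    lon = truth.track.lon[idx].copy()
    z = truth.track.z[idx]
    if cfg.gps.error_sd_m > 0:
        de = rng_gps.normal(0.0, cfg.gps.error_sd_m, idx.size)
        dn = rng_gps.normal(0.0, cfg.gps.error_sd_m, idx.size)
        lat = lat + np.degrees(dn / 6_371_000.0)
        lon = lon + np.degrees(de / (6_371_000.0 * np.cos(np.radians(lat))))
    keep = np.ones(idx.size, dtype=bool)
    if cfg.gps.dropout_depth_m is not None:
        keep = z <= cfg.gps.dropout_depth_m
    if not np.any(keep):
        raise ValueError("dropout rule removed every fix")
    return GeoTrack(
        t=tt[idx][keep], lat=lat[keep], lon=lon[keep], z=np.zeros(int(keep.sum())), kind="verified"
    )


def simulate_current(
    cfg: SimConfig,
    lat_range: tuple[float, float] | None = None,
    lon_range: tuple[float, float] | None = None,
    resolution_deg: float = 0.01,
    n_time_layers: int = 2,
) -> CurrentField:
    """Gridded current field: spatially constant flow or a solid-body gyre."""
    if cfg.current is None:
        raise ValueError("SimConfig.current is not set")
    spec = cfg.current
    lat0, lon0 = cfg.start
    if lat_range is None:
        lat_range = (lat0 - 1.0, lat0 + 1.0)
    if lon_range is None:
        lon_range = (lon0 - 1.0, lon0 + 1.0)
    lats = np.arange(lat_range[0], lat_range[1] + resolution_deg / 2, resolution_deg)
    lons = np.arange(lon_range[0], lon_range[1] + resolution_deg / 2, resolution_deg)
    times = np.linspace(0.0, max(cfg.duration_s, 1.0), n_time_layers)
    shape = (times.size, lats.size, lons.size)
    if spec.kind == "constant":
        u = np.full(shape, spec.u)
        v = np.full(shape, spec.v)
    elif spec.kind == "gyre":
        glat, glon = spec.gyre_centre
        lon_g, lat_g = np.meshgrid(lons, lats)
        x = np.radians(lon_g - glon) * 6_371_000.0 * np.cos(np.radians(glat))
        y = np.radians(lat_g - glat) * 6_371_000.0
        u2 = -spec.gyre_omega * y
        v2 = spec.gyre_omega * x
        u = np.broadcast_to(u2, shape).copy()
        v = np.broadcast_to(v2, shape).copy()
    else:
        raise ValueError(f"unknown current kind {spec.kind!r}")
    return CurrentField(lon=lons, lat=lats, time=times, u=u, v=v)


# ---------------------------------------------------------------------------
# scenario presets mirroring the three movement media

def land_walker(seed: int = 0, duration_s: float = 3600.0, **overrides) -> SimConfig:
    """Terrestrial quadruped: 1 Hz, walk/rest states, VeDBA-encoded speed,
    1-s GPS fixes."""
    cfg = SimConfig(seed=seed, duration_s=duration_s, fs=1.0, medium="land")
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def sea_diver(seed: int = 0, duration_s: float = 3600.0, **overrides) -> SimConfig:
    """Diving swimmer: surface travel and dive cycles with vertical rate,
    GPS dropout below 0.3 m depth."""
    cfg = SimConfig(
        seed=seed,
        duration_s=duration_s,
        fs=1.0,
        medium="water",
        states=[
            StateSpec("surface", speed_mean=0.4, speed_cv=0.1, turn_sd_deg=6.0,
                      vertical_rate=-0.5, dwell_mean_s=120.0),
            StateSpec("descent", speed_mean=2.1, speed_cv=0.05, turn_sd_deg=3.0,
                      vertical_rate=1.0, dwell_mean_s=30.0),
            StateSpec("bottom", speed_mean=0.4, speed_cv=0.1, turn_sd_deg=10.0,
                      vertical_rate=0.0, dwell_mean_s=60.0),
            StateSpec("ascent", speed_mean=2.1, speed_cv=0.05, turn_sd_deg=3.0,
                      vertical_rate=-1.0, dwell_mean_s=30.0),
        ],
        gps=GpsSpec(fix_interval_s=1.0, error_sd_m=0.0, dropout_depth_m=0.3),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def aerial_flyer(seed: int = 0, duration_s: float = 3600.0, **overrides) -> SimConfig:
    """Flying seabird: fast flapping travel and slow surface rest,
    1-min GPS fixes."""
    cfg = SimConfig(
        seed=seed,
        duration_s=duration_s,
        fs=1.0,
        medium="air",
        states=[
            StateSpec("flying", speed_mean=12.0, speed_cv=0.1, turn_sd_deg=3.0,
                      vertical_rate=0.0, dwell_mean_s=900.0),
            StateSpec("resting", speed_mean=0.1, speed_cv=0.0, turn_sd_deg=20.0,
                      vertical_rate=0.0, dwell_mean_s=120.0),
        ],
        m_true=25.0,
        gps=GpsSpec(fix_interval_s=60.0, error_sd_m=0.0),
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


PRESETS = {"land_walker": land_walker, "sea_diver": sea_diver, "aerial_flyer": aerial_flyer}
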