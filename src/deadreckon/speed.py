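"""Per-sample speed estimation (m/s) for travel-vector construction.

Four complementary estimators, reflecting how speed is allocated across
movement media in practice:

- linear VeDBA model ``speed = m * VeDBA + c`` for terrestrial locomotion;
- constant speeds per behaviour state (swimming/flying, where dynamic body
  acceleration is a weak speed proxy);
- vertical-rate speed ``|dz/dt| / tan(pitch)`` for steep dive/climb phases,
  hard-capped (default 3 m/s);
- speed between verified positions (haversine / elapsed time, interpolated).

A movement gate (VeDBA threshold or supplied behaviour labels) zeroes speed
outside genuine travelling so that stationary behaviours imparting dynamic
acceleration do not advance the track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .geodesy import haversine_m
from .types import GeoTrack, SpeedSeries


@dataclass
class SpeedModelConfig:
    """Parameters of the speed estimators.

    ``m`` (m/s per g) and ``c`` (m/s) define the linear VeDBA model;
    ``behaviour_speed_table`` maps state labels to constant speeds;
    ``pitch_threshold`` (deg) and ``speed_cap`` (m/s) govern the
    vertical-rate rule; ``vedba_threshold`` (g) is the movement gate;
    ``travelling_states`` is the label set treated as genuine travel when
    gating on behaviour.
    """

    m: float = 1.0
    c: float = 0.0
    behaviour_speed_table: Mapping[str, float] = field(default_factory=dict)
    pitch_threshold: float = 10.0
    speed_cap: float = 3.0
    vedba_threshold: float = 0.1
    depth_threshold: float = 0.3
    travelling_states: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("m must be >= 0")
        if any(v < 0 for v in self.behaviour_speed_table.values()):
            raise ValueError("behaviour speeds must be >= 0")
        if self.speed_cap <= 0:
            raise ValueError("speed_cap must be > 0")


def vedba_speed(t: np.ndarray, vedba: np.ndarray, cfg: SpeedModelConfig) -> SpeedSeries:
    """Linear VeDBA-to-speed model, floored at zero."""
    speed = np.clip(cfg.m * np.asarray(vedba, dtype=float) + cfg.c, 0.0, None)
    return SpeedSeries(t=t, speed=speed, source=np.full(speed.size, "vedba", dtype=object))


def fit_vedba_speed(
    vedba: np.ndarray,
    vp_speed: np.ndarray,
    method: str = "regression",
    gate: Optional[np.ndarray] = None,
) -> tuple[float, float]:
    """Fit (m, c) of the linear VeDBA-speed model against reference speeds.

    ``regression`` is ordinary least squares. ``scale_match`` fixes c = 0
    and chooses m so the total dead-reckoned path length equals the total
    reference path length (closed-form ratio of sums, equivalent to scaling
    the uncorrected track onto the reference track iteratively). ``gate``
    optionally restricts the fit to open-gate samples.
    """
    v = np.asarray(vedba, dtype=float)
    s = np.asarray(vp_speed, dtype=float)
    if gate is not None:
        v, s = v[np.asarray(gate, dtype=bool)], s[np.asarray(gate, dtype=bool)]
    if v.size < 10:
        raise ValueError("need at least 10 paired samples to fit the speed model")
    if np.ptp(v) == 0:
        raise ValueError("VeDBA has zero variance; cannot fit a speed model")
    if method == "regression":
        m, c = np.polyfit(v, s, 1)
        return float(m), float(c)
    if method == "scale_match":
        total_v = float(np.sum(v))
        if total_v == 0:
            raise ValueError("VeDBA sums to zero; cannot scale-match")
        return float(np.sum(s) / total_v), 0.0
    raise ValueError(f"unknown fit method {method!r}")


def behaviour_speed(
    t: np.ndarray, states: Sequence[str], cfg: SpeedModelConfig
) -> SpeedSeries:
    """Constant speed per behaviour state, looked up from the configured table."""
    states = np.asarray(states, dtype=object)
    table = cfg.behaviour_speed_table
    unknown = sorted({s for s in states if s not in table})
    if unknown:
        raise KeyError(f"behaviour states missing from speed table: {unknown}")
    speed = np.array([table[s] for s in states], dtype=float)
    return SpeedSeries(t=t, speed=speed, source=np.full(speed.size, "behaviour", dtype=object))


def vertical_rate_speed(
    t: np.ndarray,
    z: np.ndarray,
    pitch: np.ndarray,
    cfg: SpeedModelConfig,
    fallback: SpeedSeries,
) -> SpeedSeries:
    """Speed from depth rate and dive angle where the animal is steeply inclined.

    Where depth exceeds 0.3 m and |pitch| >= the pitch threshold:
    ``speed = |dz/dt| / |tan(pitch * pi/180)|`` capped at ``speed_cap``;
    elsewhere the fallback estimate (and its source label) is used. dz/dt
    is a centred first difference over one sample step.
    """
    t = np.asarray(t, dtype=float)
    z = np.asarray(z, dtype=float)
    pitch = np.asarray(pitch, dtype=float)
    if z.size != t.size or pitch.size != t.size or fallback.speed.size != t.size:
        raise ValueError("z, pitch and fallback must align with t")
    dzdt = np.gradient(z, t) if t.size > 1 else np.zeros_like(z)
    applies = (np.abs(pitch) >= cfg.pitch_threshold) & (z > cfg.depth_threshold)
    tan_pitch = np.tan(np.radians(pitch))
    with np.errstate(divide="ignore", invalid="ignore"):
        vert = np.abs(dzdt) / np.abs(tan_pitch)
    vert = np.minimum(np.nan_to_num(vert, nan=0.0, posinf=cfg.speed_cap), cfg.speed_cap)
    speed = np.where(applies, vert, fallback.speed)
    source = np.where(applies, "vertical", fallback.source).astype(object)
    return SpeedSeries(t=t, speed=speed, source=source)


def vp_derived_speed(vps: GeoTrack, t_grid: np.ndarray) -> SpeedSeries:
    """Speed from verified-position displacement, interpolated onto the grid.

    Per fix interval: haversine distance / elapsed time, assigned to the
    interval midpoint and linearly interpolated (end values held constant
    beyond the first/last midpoints).
    """
    if vps.n < 2:
        raise ValueError("need at least 2 fixes for VP-derived speed")
    seg = haversine_m(vps.lat[:-1], vps.lon[:-1], vps.lat[1:], vps.lon[1:])
    dt = np.diff(vps.t)
    rate = np.atleast_1d(seg / dt)
    mid = 0.5 * (vps.t[:-1] + vps.t[1:])
    t_grid = np.asarray(t_grid, dtype=float)
    speed = np.interp(t_grid, mid, rate)
    return SpeedSeries(
        t=t_grid, speed=speed, source=np.full(t_grid.size, "gps", dtype=object)
    )


def movement_gate(
    vedba: np.ndarray,
    cfg: SpeedModelConfig,
    states: Optional[Sequence[str]] = None,
    mode: str = "vedba",
) -> np.ndarray:
    """Boolean mask of samples treated as genuine travelling movement.

    ``vedba`` mode keeps samples above the VeDBA threshold; ``behaviour``
    mode keeps samples whose state label is in the configured travelling
    set (labels required).
    """
    if mode == "vedba":
        return np.asarray(vedba, dtype=float) > cfg.vedba_threshold
    if mode == "behaviour":
        if states is None:
            raise ValueError("behaviour gating requires state labels")
        travelling = set(cfg.travelling_states)
        return np.array([s in travelling for s in states], dtype=bool)
    raise ValueError(f"unknown gate mode {mode!r}")


def apply_gate(speeds: SpeedSeries, gate: np.ndarray) -> SpeedSeries:
    """Zero the speed of gated-out samples and relabel them ``gated-zero``."""
    gate = np.asarray(gate, dtype=bool)
    if gate.size != speeds.speed.size:
        raise ValueError("gate length mismatch")
    speed = np.where(gate, speeds.speed, 0.0)
    source = np.where(gate, speeds.source, "gated-zero").astype(object)
    return SpeedSeries(t=speeds.t, speed=speed, source=source)
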