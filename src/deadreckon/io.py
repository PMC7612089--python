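"""CSV/GeoJSON input-output, pipeline configuration and the end-to-end run.

The interchange format is plain CSV throughout; column maps accommodate
logger dialects. ``run_pipeline`` ties the stages together in the order a
practitioner would: VP screening -> magnetometer calibration -> tag
rotation and declination -> posture, heading and VeDBA -> speed model ->
optional current integration -> dead-reckoning -> VP correction ->
net-error metrics and the thinning sweep. Outputs carry a provenance
header (package version + configuration hash) and a resolved copy of the
configuration is written beside them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import correct as _correct
from . import metrics as _metrics
from . import reckon as _reckon
from . import sensors as _sensors
from . import speed as _speed
from .types import CurrentField, GeoTrack, ImuSeries, TravelVectorSeries

logger = logging.getLogger("deadreckon")

DEFAULT_IMU_COLUMNS = {
    "time": "time",
    "ax": "ax",
    "ay": "ay",
    "az": "az",
    "mx": "mx",
    "my": "my",
    "mz": "mz",
    "pressure": "pressure",
}


def _parse_time(col: pd.Series) -> np.ndarray:
    """Epoch seconds from a column of epoch floats or ISO-8601 strings."""
    try:
        return col.astype(float).to_numpy()
    except (ValueError, TypeError):
        ts = pd.to_datetime(col, utc=True, format="ISO8601")
        return ts.astype("int64").to_numpy() / 1e9


def read_imu_csv(path, column_map: Optional[dict] = None) -> ImuSeries:
    """Read an inertial stream CSV into an :class:`ImuSeries`.

    Rows with non-finite values are dropped and counted; timestamps must be
    uniform within 1e-6 s after the drop.
    """
    cmap = {**DEFAULT_IMU_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path)
    required = [cmap[k] for k in ("time", "ax", "ay", "az", "mx", "my", "mz")]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    has_pressure = cmap["pressure"] in df.columns
    cols = required + ([cmap["pressure"]] if has_pressure else [])
    sub = df[cols].apply(pd.to_numeric, errors="coerce") if _all_numeric(df[cols]) else df[cols]
    if not _all_numeric(sub):
        t = _parse_time(df[cmap["time"]])
        sub = df[cols[1:]].apply(pd.to_numeric, errors="coerce")
        sub.insert(0, cmap["time"], t)
    good = np.isfinite(sub.to_numpy(dtype=float)).all(axis=1)
    dropped = int((~good).sum())
    if dropped:
        logger.info("read_imu_csv: dropped %d rows with non-finite values", dropped)
    sub = sub[good]
    t = sub[cmap["time"]].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0))
        raise ValueError(f"timestamps not strictly increasing (first offence at row {bad + 1})")
    return ImuSeries(
        t=t,
        ax=sub[cmap["ax"]].to_numpy(float),
        ay=sub[cmap["ay"]].to_numpy(float),
        az=sub[cmap["az"]].to_numpy(float),
        mx=sub[cmap["mx"]].to_numpy(float),
        my=sub[cmap["my"]].to_numpy(float),
        mz=sub[cmap["mz"]].to_numpy(float),
        pressure=sub[cmap["pressure"]].to_numpy(float) if has_pressure else None,
        dropped_rows=dropped,
    )


def _all_numeric(df: pd.DataFrame) -> bool:
    return all(pd.api.types.is_numeric_dtype(dt) for dt in df.dtypes)


def read_vps_csv(path, kind: str = "verified") -> GeoTrack:
    """Read timestamped lat/lon fixes (columns: time, lat, lon[, z])."""
    df = pd.read_csv(path, comment="#")
    for col in ("time", "lat", "lon"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    t = _parse_time(df["time"])
    z = df["z"].to_numpy(float) if "z" in df.columns else None
    return GeoTrack(t=t, lat=df["lat"].to_numpy(float), lon=df["lon"].to_numpy(float), z=z, kind=kind)


def read_states_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read per-sample behaviour labels (columns: time, state)."""
    df = pd.read_csv(path, comment="#")
    return _parse_time(df["time"]), df["state"].to_numpy(dtype=object)


def read_current_csv(path) -> CurrentField:
    """Read a gridded current field CSV (columns: lon, lat, time, u, v).

    The (lon, lat, time) combinations must form a complete regular grid.
    """
    df = pd.read_csv(path, comment="#")
    for col in ("lon", "lat", "time", "u", "v"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    lons = np.unique(df["lon"].to_numpy(float))
    lats = np.unique(df["lat"].to_numpy(float))
    times = np.unique(_parse_time(df["time"]))
    if len(df) != lons.size * lats.size * times.size:
        raise ValueError("current CSV does not form a complete regular grid")
    pivot = df.sort_values(["time", "lat", "lon"])
    shape = (times.size, lats.size, lons.size)
    return CurrentField(
        lon=lons,
        lat=lats,
        time=times,
        u=pivot["u"].to_numpy(float).reshape(shape),
        v=pivot["v"].to_numpy(float).reshape(shape),
    )


def _provenance(extra: str = "") -> str:
    return f"deadreckon {__version__}" + (f" config={extra}" if extra else "")


def write_track(
    track: GeoTrack,
    path,
    fmt: str = "csv",
    speed: Optional[np.ndarray] = None,
    heading: Optional[np.ndarray] = None,
    source: Optional[np.ndarray] = None,
    config_hash: str = "",
) -> None:
    """Write a track as CSV (with provenance header comment) or GeoJSON
    LineString (z as third coordinate when the track is 3-D)."""
    path = Path(path)
    if fmt == "csv":
        df = pd.DataFrame({"time": track.t, "lat": track.lat, "lon": track.lon, "z": track.z})
        for name, arr in (("speed", speed), ("heading", heading), ("source", source)):
            if arr is not None:
                n = min(len(arr), track.n)
                col = np.full(track.n, np.nan, dtype=object)
                col[:n] = np.asarray(arr)[:n]
                df[name] = col
        with open(path, "w") as fh:
            fh.write(f"# {_provenance(config_hash)}\n")
            df.to_csv(fh, index=False)
    elif fmt == "geojson":
        three_d = bool(np.any(track.z != 0))
        coords = [
            [float(lo), float(la)] + ([float(zz)] if three_d else [])
            for la, lo, zz in zip(track.lat, track.lon, track.z)
        ]
        gj = {
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": coords},
            "properties": {
                "kind": track.kind,
                "provenance": _provenance(config_hash),
                "times": [float(x) for x in track.t],
            },
        }
        path.write_text(json.dumps(gj))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_track_csv(path) -> GeoTrack:
    """Round-trip reader for :func:`write_track` CSV output."""
    df = pd.read_csv(path, comment="#")
    for col in ("lat", "lon"):
        if np.any(np.abs(df[col]) > (90 if col == "lat" else 180)):
            raise ValueError(f"{col} out of bounds in {path}")
    return GeoTrack(
        t=_parse_time(df["time"]),
        lat=df["lat"].to_numpy(float),
        lon=df["lon"].to_numpy(float),
        z=df["z"].to_numpy(float) if "z" in df.columns else None,
    )


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    """Everything needed for an end-to-end run. Unknown YAML keys are rejected."""

    imu_csv: str = ""
    vps_csv: str = ""
    current_csv: Optional[str] = None
    states_csv: Optional[str] = None
    output_dir: str = "out"
    seed: int = 0
    column_map: dict = field(default_factory=dict)
    medium: str = "land"  # land | water | air
    declination: float = 0.0
    fit_soft_iron: bool = False
    static_window_s: float = 2.0
    vedba_smooth_s: float = 2.0
    heading_smooth_s: float = 1.0
    pitch_smooth_s: float = 1.0
    metres_per_pressure_unit: float = 0.01
    reference_pressure: Optional[float] = None
    baseline_smoothness: float = 1e7
    baseline_asymmetry: float = 0.01
    speed_method: str = "vedba"  # vedba | behaviour | gps
    speed_m: float = 1.0
    speed_c: float = 0.0
    speed_fit: str = "none"  # none | regression | scale_match
    behaviour_speed_table: dict = field(default_factory=dict)
    travelling_states: list = field(default_factory=list)
    gate_mode: str = "none"  # none | vedba | behaviour
    vedba_threshold: float = 0.1
    pitch_threshold: float = 10.0
    speed_cap: float = 3.0
    use_vertical_speed: bool = False
    screening_max_speed: Optional[float] = None
    correction_interval_s: float = 60.0
    anchor_tolerance_m: float = 0.01
    thinning_schedule: Optional[list] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """In-memory bundle from :func:`run_pipeline`."""

    uncorrected: GeoTrack
    corrected: GeoTrack
    report: object
    net_errors: object
    thinning: object
    speeds: object
    heading: np.ndarray
    output_dir: Path


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full VP-corrected dead-reckoning pipeline from files."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_pipeline(cfg, out)
    except Exception as exc:  # annotate with the failing stage where known
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _stage(name: str):
    logger.info("stage: %s", name)


def _run_pipeline(cfg: PipelineConfig, out: Path) -> PipelineResult:
    chash = cfg.hash()
    cfg.to_yaml(out / "config.resolved.yaml")

    _stage("load inputs")
    imu = read_imu_csv(cfg.imu_csv, cfg.column_map)
    vps = read_vps_csv(cfg.vps_csv)
    logger.info("imu: %d samples at %.3f Hz (%d rows dropped)", imu.n, imu.fs, imu.dropped_rows)

    _stage("VP screening")
    if cfg.screening_max_speed is not None:
        before = vps.n
        vps = _correct.screen_vps(vps, cfg.screening_max_speed)
        logger.info("screening removed %d of %d fixes", before - vps.n, before)

    _stage("magnetometer calibration")
    try:
        cal = _sensors.calibrate_magnetometer(
            imu, fit_soft_iron=cfg.fit_soft_iron, declination=cfg.declination
        )
    except ValueError as exc:
        # e.g. flat-terrain deployments never tilt: offset not identifiable
        logger.warning("calibration skipped (%s); using identity model", exc)
        cal = _sensors.CalibrationModel(declination=cfg.declination)
    imu = _sensors.apply_tag_rotation(imu, cal)

    _stage("orientation and VeDBA")
    split = _sensors.separate_acceleration(imu, cfg.static_window_s)
    vedba = _sensors.compute_vedba(split, cfg.vedba_smooth_s)
    ori = _sensors.estimate_pitch_roll(split)
    if cfg.pitch_smooth_s > 0:
        ori.pitch = _sensors.running_mean(
            ori.pitch, max(1, int(round(cfg.pitch_smooth_s * imu.fs)))
        )
    mag_cal = cal.apply_magnetic(imu.magnetism())
    heading = _sensors.tilt_compensated_heading(ori, mag_cal, cal, cfg.heading_smooth_s)
    logger.info("flagged unreliable posture samples: %d", int(np.sum(ori.unreliable)))

    _stage("vertical axis")
    z = np.zeros(imu.n)
    if imu.pressure is not None and cfg.medium == "water":
        baseline = _sensors.pressure_baseline(
            imu.pressure, cfg.baseline_smoothness, cfg.baseline_asymmetry
        )
        z = _sensors.pressure_to_vertical(
            imu.pressure, baseline, "water", metres_per_unit=cfg.metres_per_pressure_unit
        )
    elif imu.pressure is not None and cfg.medium == "air":
        if cfg.reference_pressure is None:
            raise ValueError("air medium requires reference_pressure")
        z = _sensors.pressure_to_vertical(
            imu.pressure, None, "air", reference=cfg.reference_pressure
        )

    _stage("speed model")
    scfg = _speed.SpeedModelConfig(
        m=cfg.speed_m,
        c=cfg.speed_c,
        behaviour_speed_table=cfg.behaviour_speed_table,
        pitch_threshold=cfg.pitch_threshold,
        speed_cap=cfg.speed_cap,
        vedba_threshold=cfg.vedba_threshold,
        travelling_states=tuple(cfg.travelling_states),
    )
    states = None
    if cfg.states_csv:
        _, states = read_states_csv(cfg.states_csv)
    if cfg.speed_fit != "none":
        ref = _speed.vp_derived_speed(vps, imu.t)
        m_fit, c_fit = _speed.fit_vedba_speed(vedba, ref.speed, cfg.speed_fit)
        scfg.m, scfg.c = m_fit, c_fit
        logger.info("fitted speed model m=%.4f c=%.4f (%s)", m_fit, c_fit, cfg.speed_fit)
    if cfg.speed_method == "vedba":
        speeds = _speed.vedba_speed(imu.t, vedba, scfg)
    elif cfg.speed_method == "behaviour":
        if states is None:
            raise ValueError("behaviour speed method requires states_csv")
        speeds = _speed.behaviour_speed(imu.t, states, scfg)
    elif cfg.speed_method == "gps":
        speeds = _speed.vp_derived_speed(vps, imu.t)
    else:
        raise ValueError(f"unknown speed method {cfg.speed_method!r}")
    if cfg.use_vertical_speed:
        speeds = _speed.vertical_rate_speed(imu.t, z, ori.pitch, scfg, speeds)
    if cfg.gate_mode != "none":
        gate = _speed.movement_gate(vedba, scfg, states=states, mode=cfg.gate_mode)
        speeds = _speed.apply_gate(speeds, gate)

    _stage("dead-reckoning")
    dz = np.zeros(imu.n)
    if imu.n > 1:
        dz[:-1] = np.diff(z)
    tv = TravelVectorSeries(t=imu.t, heading=heading, speed=speeds.speed, dz=dz, medium=cfg.medium)
    current = read_current_csv(cfg.current_csv) if cfg.current_csv else None
    start = (float(vps.lat[0]), float(vps.lon[0]), float(z[0]))
    track = _reckon.integrate_track(start, tv, current)
    if current is not None:
        logger.info("current lookups outside grid: %d", current.out_of_grid_count)

    _stage("VP correction")
    thinned = _correct.thin_vps(vps, cfg.correction_interval_s)
    corrected, report = _correct.correct_track(track, thinned)
    logger.info(
        "correction: %d VPs used, %d skipped, %d degenerate segments, %d extreme DCFs",
        report.vps_used,
        report.vps_skipped,
        report.degenerate_count,
        report.extreme_dcf_count,
    )

    _stage("metrics")
    errs = _metrics.net_error(corrected, vps)
    schedule = cfg.thinning_schedule or [
        s
        for s in _metrics.DEFAULT_THINNING_SCHEDULE_S
        if s <= (vps.t[-1] - vps.t[0])
    ] or [cfg.correction_interval_s]
    sweep = _metrics.thinning_sweep(
        track, vps, schedule, medium=cfg.medium, mode_3d=cfg.medium != "land"
    )

    _stage("write outputs")
    write_track(
        corrected,
        out / "corrected_track.csv",
        speed=speeds.speed,
        heading=heading,
        source=speeds.source,
        config_hash=chash,
    )
    write_track(corrected, out / "corrected_track.geojson", fmt="geojson", config_hash=chash)
    write_track(track, out / "uncorrected_track.csv", config_hash=chash)
    with open(out / "correction_report.csv", "w") as fh:
        fh.write(f"# {_provenance(chash)}\n")
        report.to_frame().to_csv(fh, index=False)
    with open(out / "net_error.csv", "w") as fh:
        fh.write(f"# {_provenance(chash)}\n")
        pd.DataFrame({"time": errs.t, "net_error_m": errs.error_m}).to_csv(fh, index=False)
    with open(out / "thinning.csv", "w") as fh:
        fh.write(f"# {_provenance(chash)}\n")
        sweep.table.to_csv(fh, index=False)
    logger.info("mean net error %.3f m over %d VPs", errs.mean, errs.t.size)

    return PipelineResult(
        uncorrected=track,
        corrected=corrected,
        report=report,
        net_errors=errs,
        thinning=sweep,
        speeds=speeds,
        heading=heading,
        output_dir=out,
    )


# ---------------------------------------------------------------------------
# simulation output helpers (used by the CLI's `simulate` subcommand)

def write_simulation(cfg_sim, out_dir) -> dict:
    """Generate a scenario and write imu/vps/truth (and current) CSVs."""
    from . import simulate as _sim

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = _sim.simulate_truth(cfg_sim)
    imu = _sim.simulate_imu(truth, cfg_sim)
    vps = _sim.simulate_vps(truth, cfg_sim)
    imu_df = pd.DataFrame(
        {
            "time": imu.t,
            "ax": imu.ax,
            "ay": imu.ay,
            "az": imu.az,
            "mx": imu.mx,
            "my": imu.my,
            "mz": imu.mz,
            "pressure": imu.pressure,
        }
    )
    imu_df.to_csv(out / "imu.csv", index=False)
    pd.DataFrame({"time": vps.t, "lat": vps.lat, "lon": vps.lon}).to_csv(
        out / "vps.csv", index=False
    )
    pd.DataFrame(
        {
            "time": truth.track.t,
            "lat": truth.track.lat,
            "lon": truth.track.lon,
            "z": truth.track.z,
        }
    ).to_csv(out / "truth.csv", index=False)
    pd.DataFrame({"time": truth.t, "state": truth.state}).to_csv(
        out / "states.csv", index=False
    )
    paths = {
        "imu": out / "imu.csv",
        "vps": out / "vps.csv",
        "truth": out / "truth.csv",
        "states": out / "states.csv",
    }
    if cfg_sim.current is not None:
        fld = _sim.simulate_current(cfg_sim)
        lon_g, lat_g, t_g = np.meshgrid(fld.lon, fld.lat, fld.time, indexing="ij")
        pd.DataFrame(
            {
                "lon": lon_g.ravel(),
                "lat": lat_g.ravel(),
                "time": t_g.ravel(),
                "u": np.transpose(fld.u, (2, 1, 0)).ravel(),
                "v": np.transpose(fld.v, (2, 1, 0)).ravel(),
            }
        ).to_csv(out / "current.csv", index=False)
        paths["current"] = out / "current.csv"
    return paths
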