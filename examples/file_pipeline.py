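"""The end-to-end file pipeline: CSVs in, corrected track + reports out.

Writes a simulated scenario to CSV files (as a logger download would
provide), then runs the full pipeline from a configuration object:
screening -> calibration -> orientation/VeDBA -> speed -> dead-reckoning
-> VP correction -> metrics. Equivalent to `deadreckon run config.yaml`.
"""

import tempfile
from pathlib import Path

import deadreckon as dr
from deadreckon.io import PipelineConfig, run_pipeline, write_simulation

workdir = Path(tempfile.mkdtemp(prefix="deadreckon_demo_"))
paths = write_simulation(dr.land_walker(seed=3, duration_s=1800), workdir / "sim")

cfg = PipelineConfig(
    imu_csv=str(paths["imu"]),
    vps_csv=str(paths["vps"]),
    output_dir=str(workdir / "out"),
    speed_m=2.5,  # VeDBA-speed gradient, m/s per g
    screening_max_speed=20.0,
    correction_interval_s=120.0,
    thinning_schedule=[600.0, 120.0, 30.0],
)
result = run_pipeline(cfg)

print(f"outputs written to {result.output_dir}:")
for p in sorted(result.output_dir.iterdir()):
    print(f"  {p.name}")
print(f"mean net error vs all fixes: {result.net_errors.mean:.2f} m")
print(result.thinning.table[["interval_s", "mean_net_error_m"]].to_string(index=False))
print("-> every artefact carries a provenance header; rerunning the same")
print("   configuration and inputs reproduces the outputs bit for bit.")
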