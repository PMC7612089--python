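"""How often should drift be corrected? Net error vs VP correction rate.

Simulates 12 hours of terrestrial movement with a noisy speed channel,
then repeats the VP correction at intervals from 3 hours down to 30
seconds and tabulates net error (vs all fixes), dead-reckoned distance
moved, and the VP-path distance on the thinned fixes.
"""

import deadreckon as dr

cfg = dr.land_walker(seed=2, duration_s=12 * 3600, vedba_noise_sd=0.05)
truth = dr.simulate_truth(cfg)
imu = dr.simulate_imu(truth, cfg)
vps = dr.simulate_vps(truth, cfg)

split = dr.separate_acceleration(imu, 2.0)
ori = dr.estimate_pitch_roll(split)
cal = dr.CalibrationModel()
heading = dr.tilt_compensated_heading(ori, cal.apply_magnetic(imu.magnetism()), cal, 1.0)
speeds = dr.vedba_speed(imu.t, dr.compute_vedba(split, 2.0), dr.SpeedModelConfig(m=cfg.m_true))
tv = dr.TravelVectorSeries(t=imu.t, heading=heading, speed=speeds.speed)
track = dr.integrate_track((truth.track.lat[0], truth.track.lon[0], 0.0), tv)

schedule = [3 * 3600.0, 3600.0, 1800.0, 900.0, 300.0, 60.0, 30.0]
sweep = dr.thinning_sweep(track, vps, schedule)
cols = ["interval_s", "n_vps_used", "mean_net_error_m", "dr_distance_m", "vp_distance_m"]
print(sweep.table[cols].to_string(index=False, float_format=lambda x: f"{x:.2f}"))
print("-> net error shrinks monotonically with the correction rate, while the")
print("   dead-reckoned distance stays stable and the VP-path distance grows")
print("   (straight lines between sparse fixes always under-measure the path).")
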