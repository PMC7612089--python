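"""Current integration: advect the travel vector by an external flow field.

A passively drifting animal (zero powered speed) in a steady 1 m/s
eastward current. Dead-reckoning that ignores the current accumulates
error at exactly the current speed; adding the flow vector to each travel
vector before integration removes the drift.
"""

import deadreckon as dr
from deadreckon.simulate import CurrentSpec, GpsSpec, SimConfig, StateSpec

T = 600.0
cfg = SimConfig(
    seed=4,
    duration_s=T,
    medium="water",
    states=[StateSpec("drift", speed_mean=0.0, turn_sd_deg=0.0)],
    current=CurrentSpec(kind="constant", u=1.0, v=0.0),
    gps=GpsSpec(fix_interval_s=60.0),
)
truth = dr.simulate_truth(cfg)
field = dr.simulate_current(cfg)
tv = dr.TravelVectorSeries(t=truth.t, heading=truth.heading, speed=truth.speed)
start = (cfg.start[0], cfg.start[1], 0.0)

no_cur = dr.integrate_track(start, tv)
with_cur = dr.integrate_track(start, tv, field)
true_end = dr.forward_step(cfg.start[0], cfg.start[1], 90.0, 1.0 * T)

err_without = dr.haversine((no_cur.lat[-1], no_cur.lon[-1]), true_end)
err_with = dr.haversine((with_cur.lat[-1], with_cur.lon[-1]), true_end)
print(f"after {T:.0f} s in a 1 m/s current:")
print(f"  net error without current integration: {err_without:.1f} m")
print(f"  net error with current integration:    {err_with:.3f} m")
print("-> ignoring the flow costs |current| metres of error per second;")
print("   vector-adding the flow before each geodesic step removes it.")
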