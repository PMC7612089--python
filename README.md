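# deadreckon

**VP-corrected dead-reckoning of animal movement from biologging sensors.**

Animal-attached GPS tags verify an animal's position only periodically, so
movement paths reconstructed from "Verified Positions" (VPs) alone miss the
tortuosity, and the distance moved, between fixes. Dead-reckoning fills the
gaps: tri-axial accelerometers and magnetometers yield a heading and a speed
estimate for every sample (1–40 Hz), and sequentially integrating these
travel vectors from a known start produces a continuous 2-D or 3-D
pseudo-track. Because small travel-vector errors accumulate ("drift"), the
pseudo-track is periodically re-anchored to the sparse VPs. This package —
aimed at movement ecologists working with inertial logger + GPS deployments
on terrestrial, aquatic or aerial species — implements the full chain and
the tools to ask *how often* drift should be corrected.

## The method

Per sample *i* with step `dt`:

- **Posture** from the static (gravity) component of acceleration, split off
  by a centred running mean: `pitch = arcsin(static_surge / ‖static‖)`,
  `roll = atan2(static_sway, static_heave)`.
- **Heading** `h_i` by the tilt-compensated compass: de-rotate the
  (hard-/soft-iron calibrated) magnetic vector by pitch and roll, take
  `atan2` of the horizontal components, add the magnetic declination, and
  smooth with a rolling circular mean.
- **Speed** `s_i` from VeDBA — the Vector of the Dynamic Body Acceleration,
  `VeDBA = sqrt(Dx² + Dy² + Dz²)` smoothed by 2 s — via the linear model
  `s = m · VeDBA + c`; or per-behaviour constants; or the vertical-rate rule
  `s = |Δd| / tan(θ·π/180)` (capped at 3 m/s, pitch ≥ 10°); or
  haversine/Δt between GPS fixes. A movement gate (VeDBA threshold or
  behaviour labels) zeroes speed outside genuine travel.
- **Integration**: advance by `s_i · dt` along `h_i` on a sphere of radius
  6 371 000 m, optionally vector-adding an external current/wind flow
  `(u, v) · dt` first; depth or altitude accumulates from the pressure
  channel.
- **VP correction**: between consecutive matched VPs, the *distance
  correction factor* `DCF = beeline(VP) / beeline(dead-reckoned)` multiplies
  every intermediate step distance and the *heading correction factor*
  `HCF = bearing(VP) − bearing(dead-reckoned)` is added to every heading,
  then the segment is re-integrated from the anchoring VP. Zero-length steps
  stay put (zero times any factor is zero), and the within-segment turn
  angles — the track's shape — are preserved.
- **Accuracy**: *net error* = haversine distance between every VP and the
  time-matched corrected position; distance moved is summed 2-D (haversine)
  or 3-D (Pythagorean on WGS-84 Earth-centred Cartesian coordinates);
  `thinning_sweep` re-runs the correction across a schedule of VP intervals
  (1 fix/24 h … 1 fix/s) to expose the accuracy/fix-budget trade-off.

A closed-loop simulator (`simulate_truth` / `simulate_imu` / `simulate_vps`
/ `simulate_current`) generates state-switching correlated-random-walk
ground truth with sensor streams that are consistent with it, so every
stage is testable without any field data.

## Worked example

Inject a +15° tag-yaw bias and a 2× speed-scale error, dead-reckon, and
correct against GPS thinned to one fix per 10 minutes
(`python examples/vp_correction.py`):

```
segments: 6  (VPs used: 7)
mean heading correction factor: -14.99 deg  (injected bias +15)
mean distance correction factor: 0.500      (injected scale 2.0)
mean net error: 686.0 m uncorrected -> 0.32 m corrected
```

The segment factors identify and cancel the injected sensor errors: the
mean HCF is the negative of the yaw bias, the mean DCF the inverse of the
speed scale, and the corrected track re-joins the fixes to sub-metre net
error. The other scripts in `examples/` demonstrate sensor processing and
integration, the correction-rate sweep, current-flow integration, and the
file-based pipeline (also available as the `deadreckon` command-line tool
with `simulate`, `run`, `correct` and `evaluate` subcommands).

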