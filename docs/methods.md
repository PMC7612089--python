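# Methods

This note records the models, conventions, numerical choices and known
limitations behind `deadreckon`, in the order data flows through the
package.

## Frames and conventions

Body axes are **surge** (anterior–posterior, positive forward), **sway**
(medio-lateral, positive right) and **heave** (dorsal–ventral, positive up
through the back): an upright motionless animal senses gravity as
(0, 0, +1) g. The Earth frame is North/East/Up. Attitude is Euler
(yaw → pitch → roll): yaw = heading, degrees clockwise from true North in
[0, 360); pitch positive nose-up in [−90°, 90°]; roll in (−180°, 180°].
Magnetic declination is positive East and is *added* to magnetic heading.
Latitude/longitude are WGS-84 decimal degrees; depth is metres positive
down (aquatic), altitude metres positive up (aerial), selected by a medium
flag carried on the travel-vector series.

## Sensor processing

**Static/dynamic split.** Gravity is estimated by a centred running mean
per axis (window default 2 s, matching the VeDBA smoothing window; a
high-pass filter is the main alternative in the literature and gives
near-identical results for windows ≫ stride period). The dynamic part is
the exact residual, so the raw signal is always reconstructible. All
running means use shrinking windows at the series edges, preserving length.

**VeDBA.** The norm of the dynamic vector, then a 2-s running mean.
Non-negative by construction.

**Pitch/roll.** From the static vector as above. Samples whose static norm
falls below 0.1 g (free fall, violent manoeuvres) are flagged and carry
forward the last reliable value rather than being interpolated — the Euler
singularity region has no principled in-fill.

**Magnetometer calibration.** The default fits the hard-iron offset only
(algebraic least-squares sphere fit); a full symmetric positive-definite
soft-iron matrix is available behind `fit_soft_iron=True` (algebraic
ellipsoid fit, eigendecomposition square root, scaled to the mean centred
field norm). A conditioning check rejects orientation-poor data — e.g. a
flat-terrain deployment only ever yaws, its field locus is a circle, and
the offset component normal to that plane is unidentifiable. The file
pipeline degrades gracefully to an identity calibration (logged) in that
case.

**Heading.** Tilt-compensated compass: undo roll, undo pitch, take
`atan2(−m_east, m_north)`, add declination, wrap, then a rolling circular
mean (default 1 s; pitch is smoothed over the same window). Guards: samples
within 0.5° of gimbal lock (|pitch| ≥ 89.5°) or whose horizontal field
norm is < 1e−9 of the total are flagged and carried forward.

**Pressure.** Baseline drift is estimated by asymmetric penalised least
squares (a Whittaker smoother with second-difference penalty; weights
`p` above / `1−p` below the current baseline, iterated to a 1e−8 sup-norm
change or 20 sweeps, last iterate returned with a warning otherwise). With
`p ≪ 0.5` the baseline tracks the lower envelope — the surface pressure
under dives. Depth = (pressure − baseline) × 0.01 m/hPa (configurable),
clamped ≥ 0; altitude uses the international barometric formula
`44330 · (1 − (P/P₀)^0.1903)` against a reference sea-level pressure
(scalar or a series interpolated in time).

## Speed models and gating

The linear VeDBA model floors negative extrapolations at zero. Fitting
offers ordinary least squares against a reference speed, or `scale_match`:
c = 0 and `m = Σ(reference speed) / Σ(VeDBA)`, the closed form of scaling
the uncorrected track onto the VP track (total path lengths equalised by
construction). The vertical-rate rule applies where depth > 0.3 m and
|pitch| ≥ 10°, with `|dz/dt|` a centred first difference and a 3 m/s cap;
elsewhere the configured fallback estimate (and its provenance label) is
used. VP-derived speed assigns each fix interval's haversine/Δt to the
interval midpoint and interpolates linearly. Gating (VeDBA threshold,
default 0.1 g, or a travelling-state label set) zeroes speed and relabels
the sample `gated-zero`, so stationary behaviours cannot advance the track.
Every emitted sample carries a provenance label (`vedba`, `behaviour`,
`vertical`, `gps`, `gated-zero`) written through to the output CSV.

## Integration and current flow

Steps use the spherical destination-point formula (R = 6 371 000 m) on the
summed displacement: powered `(speed·dt·sin h, speed·dt·cos h)` plus,
when a current field is supplied, `(u, v)·dt` sampled at the pre-step
position and time (nearest grid node in space, linear between time
layers; queries outside the grid contribute zero and are counted). Heading
is taken as the direction of travel (longitudinal-axis assumption); no
sideslip model.

## VP correction

Fixes are optionally screened by a maximum implied speed, then thinned
greedily (keep the first fix, then the earliest ≥ interval later; the last
fix is always kept, and after a dropout the next available fix is used, so
realised intervals can exceed nominal ones). Each VP matches the nearest
track sample within half a sample step.

Within each segment between consecutive matched VPs the correction is
computed in a local tangent plane at the starting VP (equirectangular
scaling by cos lat): DCF = |VP beeline| / |dead-reckoned beeline|, HCF =
bearing difference (positive = clockwise rotation of the dead-reckoned
headings). The *beeline* (endpoint-to-endpoint) reading of the segment
distance is deliberate: only a uniform scaling plus rotation of the step
displacement vectors makes the corrected endpoint land on the VP, which the
planar vector sum shows directly; the cumulative step distance is available
as a diagnostic. Applying rotation + scale to the per-step displacements is
algebraically identical to "add HCF to every heading, multiply every step
distance by DCF, re-integrate" and has three consequences verified by the
test suite: anchors are hit to numerical precision (the reported residual
is the planar-approximation error, ≤ max(0.01 m, 1e−4 × beeline) at
biologging scales), zero-length steps remain zero (stationary clusters are
never expanded), and within-segment turn angles are unchanged.

Degenerate segments (no dead-reckoned displacement but displaced VPs —
usually VP error over a resting animal) are translated to start at the
anchor with only the final sample snapped to the closing VP, rather than
spreading a phantom path over stationary samples. Spans before the first
and after the last matched VP are rigidly translated to abut their anchor.
Extreme factors (DCF > 10 or < 0.1) are counted and logged, never
auto-rejected. Correction is constant per segment (no gradual distribution
of the heading correction) and rotates about the segment start.

## Metrics

Net error is evaluated against *all* supplied (screened) fixes, not just
the anchors, matching each to the corrected track in time. 2-D distances
are haversine sums on the R = 6 371 000 m sphere; 3-D distances are
Pythagorean sums between WGS-84 geodetic→ECEF coordinates with depth as
negative (altitude positive) ellipsoidal height. Note the two geodesy
models differ: a level track's 3-D chord sum can exceed its 2-D haversine
sum by up to ~0.6% simply because the local ellipsoidal radius differs
from the mean-Earth radius — this is inherent to the mixed convention, not
an integration error. VP-path distance in the thinning sweep is 2-D only
(3-D between sparse, dropout-prone fixes would be meaningless), and the
standardised error rate divides mean net error by the realised mean time
between corrections. Summaries report mean and median per interval.

## Synthetic data

The generator emulates a logger + GPS deployment: a semi-Markov behaviour
sequence (exponential dwell times, states cycled in order) drives a
correlated random walk — wrapped-normal heading increments, positive AR(1)
speed (lag-1 coefficient 0.9) around the state mean, a per-state vertical
rate smoothed over 5 s (animals ramp their dive angle; without the ramp
the instantaneous pitch flip is unresolvable by any gravity filter) and
saturated at the surface/ground, with the realised rate re-derived from
the saturated profile so pitch stays consistent.

Sensors invert the processing model exactly: gravity rotated by the true
attitude (roll fixed at 0 to keep orientation recovery identifiable);
stride-like dynamic acceleration on the heave axis alternating sign every
sample, whose magnitude makes smoothed VeDBA encode the (possibly
deliberately mis-scaled) speed through the linear coupling — stride-level
waveform realism is explicitly out of scope; the Earth field at a
configurable inclination/declination rotated into the tag frame plus an
optional hard-iron offset; hydrostatic or barometric pressure from the
true profile. GPS fixes are taken at a configured interval with white
isotropic tangent-plane noise (no autocorrelated multipath) and a
depth-based dropout rule (no fix under water). Deliberate error injections
— a tag-yaw bias and a multiplicative speed-scale error — exist for
identifiability experiments. All draws derive from one integer seed via
`numpy.random.SeedSequence` stream spawning: one stream each for states,
turning, speed, sensor noise and GPS noise, so outputs are bitwise
reproducible and individual channels can be varied independently.

Default scenario parameters were chosen once as field-plausible: the
terrestrial walker moves at 0.8 m/s (CV 0.1) with 4°-per-step turning and
10-min travel bouts broken by rests, 1 Hz sampling, 1-s GPS; the diver
cycles surface/descent/bottom/ascent phases at 0.4–2.1 m/s with ±1 m/s
vertical rates and loses fixes below 0.3 m; the flyer travels at 12 m/s
with 1-min fixes. The VeDBA coupling gradient is 2.5 m/s per g (walker),
magnetic inclination 60°, field strength 1 (arbitrary units — heading
needs only ratios).

What passing closed-loop tests do and do not show: they verify that the
estimators invert the stated sensor model and that the correction
machinery has the claimed algebraic properties; they do not certify
accuracy on real deployments, where stride dynamics, collar roll, soft-iron
environments, temperature drift and GPS multipath violate the generator's
assumptions in ways the discussion of limitations below only partially
covers.

## Problem sizes

The test suite and the acceptance script run closed-loop scenarios of
600 s–1 h at 1–10 Hz for the recovery and drift experiments and 12 h at
1 Hz (43 200 samples) for the correction-rate sweep, with sensor-math
oracles on 500-point synthetic spheres and n = 1000 regression fits —
sizes at which every quantity of interest is already stable across seeds.

## Known limitations

- Euler attitude only; no gyroscope or quaternion fusion, so heading
  degrades during high centripetal acceleration and near gimbal lock.
- The gravity filter cannot resolve attitude changes faster than its
  window; the simulator's surfacing instants still show this as localised
  pitch error.
- Constant per-segment correction: drift within a segment between anchors
  is linearly redistributed, never re-estimated (no spline/Kalman fusion).
- VP screening is a speed-ceiling surrogate for manual outlier vetting.
- Spherical 2-D geodesy throughout (consistent with haversine-based
  analysis); ellipsoidal geodesics are not used.
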