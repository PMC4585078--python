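# Methods

## The model

The hind leg is idealised as four uniform rigid rods — thigh, shank, paw
(metatarsus) and toe — pinned in a planar chain at the hip, knee, ankle
and paw joints.  The hip is a fixed inertial origin; trunk translation is
ignored.  Default segment parameters are cat-like: masses 200/100/40/20 g,
lengths 10/11/5/2 cm.  Each rod's centre of mass sits at its midpoint,
with moment of inertia `I = m a^2 / 3` about the centre of mass
(`a` = half length, equivalent to `m L^2 / 12`).  Segment angles are
measured anticlockwise from the positive x-axis at each segment's proximal
joint and are kept continuous over a trial (no wrapping); torques are
positive anticlockwise, which makes knee *flexion* negative for this leg
geometry while hip and ankle flexion are positive.  Gravity is 9.81 m/s²
in −y; all internal units are SI, with centimetres appearing only at I/O
boundaries.

Per segment there are three dynamics equations — planar force balance
(`f_x1 − f_x2 = m ẍ`, `f_y1 − f_y2 − mg = m ÿ`) and a moment balance
about the centre of mass
(`τ1 − τ2 + a sinθ (f_x1 + f_x2) − a cosθ (f_y1 + f_y2) = I θ̈`) — plus
two kinematic-chain equations expressing the centre-of-mass acceleration
through the angles, velocities and accelerations of all proximal
segments.  The distal force and torque of the toe are identically zero.
Together: 20 linear equations in 20 unknowns per time step, solved with a
dense LU solve (no symbolic reduction to a 4×4 mass-matrix form).  The
system is assembled once over 24 columns (4 torques, 4 angular
accelerations, 8 joint forces, 8 COM accelerations) and the two modes are
two column selections of that one assembly:

* **inverse mode** — angular accelerations known, torques unknown;
* **forward mode** — torques known, angular accelerations unknown.

This makes the inverse↔forward duality exact up to solver round-off
(tested at 1e−9 relative on random states) and gives a closed-form static
oracle: with all velocities and accelerations zero, each joint torque
must equal the gravitational moment of all distal segment mass about that
joint (e.g. +0.3953 N·m at the hip for the fully horizontal leg).

## Kinematics processing

Raw input is five marker trajectories (iliac crest, hip, ankle, paw
joint, toe tip) at 60 Hz.  The knee is reconstructed by two-circle
intersection from the hip and ankle markers using the model thigh/shank
lengths, choosing the anterior (larger-x, walking direction +x) solution;
distances outside the reachable annulus raise an error when they exceed
tolerance, and the trial pipeline clamps violations up to 3 mm to the
collinear boundary because marker noise routinely pushes a fully extended
or fully folded knee slightly past its geometric limit.  Segment angles
are `atan2` of each proximal→distal vector, unwrapped in time, low-pass
filtered with a 2nd-order Butterworth at 10 Hz and interpolated to a 1-ms
grid with a cubic spline.  Filtering is zero-phase (forward–backward):
offline analysis has no causality constraint and phase lag would bias
onset and slope timing; the effective attenuation at the cutoff is
therefore −6 dB.  Angular velocity and acceleration are forward first
differences at 1 ms (applied twice), the last value repeated to preserve
length.

Trial-level metrics:

* **swing onset** — first sample where toe height exceeds the standing
  baseline (median of the first 100 ms) by 5 mm and stays above it for
  50 ms.  The threshold is configurable; 5 mm is an order of magnitude
  above the filtered marker-noise floor.
* **toe-trajectory slope** — 2 cm of rise divided by the horizontal
  progress between the first upward crossings of 3 cm and 5 cm toe
  height after onset (crossings located by linear interpolation).  A
  backward-moving toe yields a negative, flagged value.
* **initial toe-to-barrier distance** — barrier x minus toe x at swing
  onset, positive behind the barrier.

## Inverse and forward dynamics over trials

Joint torques and interaction forces are solved at every 1-ms step of a
trajectory; profiles are aligned at the detected swing onset.  Subset
averages are sample-wise means over the first 200 ms; the initial-torque
statistic is the mean over the first 30 ms of swing (the highlighted
early-swing window; a window mean was chosen over an onset value or peak,
and the window is configurable).

Forward simulation integrates (θ, θ̇) with classical fixed-step RK4 at
1 ms.  Torque profiles are zero-order held on their own grid — all four
stages of a step see the sample in effect at the step start — and torque
is zero past the profile end.  A simulation is declared divergent if any
angular velocity passes 1000 rad/s.  There are no joint limits or ground
contact; the swing model has none.  Zero-torque simulations conserve
mechanical energy to <0.1% over 0.5 s, and halving the step changes the
200-ms toe position by <1e−6 m.

The fixed-command experiment drives one forward simulation per trial, all
with the same averaged torque profile and the averaged swing-onset
angular velocities of the long-distance (16–25 cm, inclusive) subset,
each from the trial's own swing-onset angles.  Simulations that diverge
or never climb through the slope heights return NaN and are dropped from
regressions rather than aborting the analysis.

## EMG processing

Channels are full-wave rectified, low-pass filtered (zero-phase 2nd-order
Butterworth, 50 Hz), and integrated (trapezoid) over 150 ms from burst
onset.  Burst onset is the first time the envelope exceeds the baseline
mean plus three baseline standard deviations (baseline = first 100 ms)
for at least 20 ms; the rule is configurable plumbing, since burst-onset
detection is not otherwise specified by the analysis design.

## Statistics

Ordinary least squares with a two-sided t-test on the slope (n − 2 df),
via `scipy.stats.linregress`; R² is the squared correlation.  A constant
response is reported as slope 0 with R² = 0; a constant regressor is a
degenerate-regression error.  No multiple-testing correction is applied
and p-values are reported raw.  Analyses are intended per-animal; the
generator labels its cohorts with a pseudo-animal id.

## The synthetic cohort generator

No recordings ship with the package, so the generator produces complete
trials — markers at 60 Hz with Gaussian noise (default SD 0.5 mm, a
typical optical-capture error), EMG at 1 kHz — with the statistical
structure the analysis assumes, plus ground truth for recovery tests.
All randomness flows from a single seed; regeneration is bit-identical.

**Posture family.**  Initial distances are uniform on 5–25 cm.  The
standing posture for a given distance places the toe on the ground that
far behind the barrier (barrier 4 cm ahead of the hip, hip fixed at
0.18 m height — a 0.23 m hip cannot reach the far end of the range with a
0.28 m chain).  The chain is posed as a two-link virtual leg: the thigh,
plus a rigid distal unit of shank and foot (paw + toe collinear), the
foot dorsiflexed by an angle that falls linearly with distance (110° at
5 cm, 10° at 25 cm).  Near-barrier stances are therefore crouched on a
folded foot with the toe under the hip; far stances trail an extended
leg.  The knee takes the anterior circle intersection, consistent with
the triangulation convention.

**Command.**  Each trial's joint-torque command is a distance-independent
base — the static anti-gravity torque of the crouched reference stance
(the knee column taken from the slightly less crouched 10-cm stance, so
trailing legs inherit a mild knee-flexion deficit that lifts the far toe
early) plus raised-cosine-edged plateau pulses at the hip (+0.030 N·m),
ankle (+0.010) and paw (+0.0005), held to the end of the record — and a
**knee modulation pulse**, −gain·(0.25 m − distance) with gain
0.08 N·m/m by default.  Because the base is identical for every trial, a
zero gain makes all commands bit-identical and any slope variation across
distances purely mechanical; crouched legs, nearly balanced by the
baseline, lift steeply in place, while extended legs, over-supported at
the hip, sweep forward in a low arc.  Commands are near-constant over the
whole spread of swing-onset times, so the 30-ms initial-torque window
always samples them at full amplitude — this is what makes the measured
initial hip torque flat across distances and the measured knee trend
equal to the commanded gain.

**Plant.**  The simulated limb is the four-link model plus passive
elements a real leg has and the analysis model deliberately omits: viscous
damping at the ankle (3e−3 N·m·s/rad) and paw (1e−3) joints — without it
the light distal rods ring at their undamped natural frequencies, well
above the 10-Hz analysis band, and the rectified centrifugal load of that
ringing biases recovered torques — and an elastic paw joint
(0.03 N·m/rad toward the stance fold), since a free-swinging 2-cm toe rod
is an extreme idealisation whose tip position would otherwise be
exquisitely sensitive to millinewton-metre torque differences.  The
posture-specific standing hold is released linearly over the first 40 ms
so the command takes over without a step.

**EMG model.**  Knee flexors (ST and, at 70% amplitude, Sart_m) are
Gaussian carriers amplitude-modulated by a pulse envelope proportional to
0.020 N·m plus the trial's knee modulation; the hip flexor (IP) envelope
is distance-independent.  The expected burst magnitude of such a carrier
is `sqrt(2/pi)` times the envelope integral, which the ground truth
records for recovery tests.

**What the generator does and does not emulate.**  It reproduces the
geometry, sampling, noise character and statistical structure of the
study — distance-dependent postures, a fixed command plus knee-specific
neural modulation, EMG co-varying with the knee drive — so pipeline
correctness and parameter recovery are testable end-to-end.  It does not
claim measured cat postures, muscle dynamics, stance-phase mechanics or
any specific animal's coefficients; passing tests demonstrate that the
analysis recovers what this generative structure puts in, not that it
would recover the physiology of a particular animal.

## Known limitations

* With modulation off, the fixed-command experiment's regression of
  simulated on actual slope sits well below one (roughly 0.3-0.6
  depending on the cohort) rather than at 1.  Re-simulating
  each trial under its *own* recovered torques and onset state reproduces
  it essentially exactly (slope 1.00, toe path within 1 mm), so the gap
  is wholly due to the prescribed substitution of subset-*averaged*
  initial velocities and torque profiles: standing-start trials reach the
  onset threshold with velocities that vary mechanically with distance.
  The corresponding acceptance test is left failing with this analysis.
* The recovered initial ankle torque carries a small systematic distance
  trend (~0.015 N·m across the full range) from the plant's passive ankle
  damping and from measurement-side distortion of the light foot's
  dynamics.  It is physically negligible but statistically significant at
  n = 100 because the synthetic noise floor is far below real
  motion-capture noise; the flatness test for the ankle is left failing
  rather than masked by inflated noise.
* The hip is fixed: trials whose toe would start ahead of the hip pendulum
  back under lift, which bounds how far forward the barrier can sit.
* Measured initial distances compress somewhat relative to nominal ones
  (the toe advances before the onset threshold trips), monotonically, so
  trend signs and subset structure are preserved.

## Problem sizes

Default test and reproduction runs use cohorts of 30–100 trials with
~0.8 s of data per trial at 1-ms resolution; each trial involves roughly
2–3×10³ dense 20×20 solves.  These sizes give stable regression estimates
while keeping a full run in minutes on one core.
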