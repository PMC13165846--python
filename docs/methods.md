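# Methods

This note documents the models, conventions, parameter choices, and known
limitations of `imugait`, in the spirit of a model-documentation page: what
is computed, under which assumptions, and what the synthetic validation does
and does not establish.

## Frames and conventions

The global (navigation) frame is right-handed with **X** mediolateral
(subject's right), **Y** vertical (up), **Z** anteroposterior (forward).
Quaternions are Hamilton, scalar-first, and encode the sensor-to-global
rotation, `v_global = R(q) v_sensor`; reference vectors are projected into
the sensor frame by the inverse rotation. `q` and `−q` are one rotation; the
canonical representative has non-negative scalar part. The anatomical
neutral is defined so that every segment frame coincides with the global
frame during quiet standing — all joint and pelvic angles are zero at the
calibration posture by construction. Joint rotations `q_prox⁻¹ ⊗ q_dist` are
decomposed in a Z–Y–X Euler sequence; under this frame the about-X (roll)
component is the sagittal-plane angle, the about-Y (pitch) component the
transverse-plane angle. Clinical signs: hip/knee flexion, ankle
dorsiflexion, and anterior pelvic tilt positive. Public interfaces use
degrees; internals use radians. Files are SI throughout.

Euler decompositions couple the planes near the pitch singularity; the
decomposition raises a degenerate-orientation signal (with the offending
sample index) within 0.5° of ±90° pitch rather than returning ill-defined
angles. All three planes are always emitted even though only the sagittal
and pelvic components are treated as validated outputs — cross-talk is
inherent to Euler angles and hiding it would not remove it.

## Orientation filter

A nonlinear complementary filter with PI feedback on the composite error
`e = â × v̂_g + m̂ × v̂_b`. Gains: baseline proportional gain `Kp0 = 1.8`,
shaped by `Kp = Kp0·exp(−α(‖a‖ − g)²)` with `α = 0.5` acting on the
magnitude deviation in m/s² (this gives strong attenuation, below 2% of
Kp0, for deviations ≥ 3 m/s² typical of swing); integral gain `Ki = 0.05`
during stance and start-up, `0.005` during swing. Design points:

* `b` in the corrected rate is the static-calibration gyro bias (constant);
  the integral term handles residual drift. The integral is clamped
  componentwise to ±1 (configurable) and is **not** reset at phase
  transitions.
* Each limb node takes its stance/swing label from the ipsilateral foot's
  event timeline; the pelvic node uses the high integral gain whenever at
  least one foot is inside a detected foot-flat interval (the gravity
  reference is most reliable while a support foot is quiet). Before event
  detection initializes, the label is `uninitialized`, treated like stance
  because trials begin with a 2–3 s quiet stand.
* Initialization is a TRIAD closed form on the mean accelerometer and
  magnetometer vectors of the first static second; gravity is the trusted
  observation, the magnetometer only fixes the rotation about the vertical.
* The magnetic reference defaults to a unit vector at 60° inclination,
  `[0, −sin 60°, cos 60°]`; an error in this choice offsets only the
  transverse components, not the sagittal angles.
* Strapdown integration is first order with per-step renormalization; at
  200 Hz and gait rates the per-step angle error is O((‖ω‖dt)³) and
  negligible against the correction dynamics.
* The batch driver runs two causal passes: pass 1 (no phase labels)
  supports event detection from the foot nodes; the detected timeline then
  supplies phase labels for the definitive pass on all seven nodes. This
  emulates the on-line system's bootstrap while staying deterministic.

### Accuracy floor under dynamic disturbance

"Zero sensor noise" is not "zero disturbance": walking itself produces
multi-m/s² linear accelerations at the thigh and shank (tangential
acceleration of a sensor mounted mid-segment on a limb swinging with a
~20° first-harmonic amplitude is ~3.5 m/s²). The magnitude gate responds
only to `‖a‖ − g`; horizontal and tangential disturbances barely change the
magnitude, so the proportional correction keeps pulling toward a tilted
apparent "up" during much of stance. The filter then tracks a low-passed
version of that wrong reference, which sets an intrinsic sagittal error
floor of roughly 1–4° for the pelvis, thigh, and shank even with perfect
sensors — the same order as OMC-validated accuracies reported for this
class of filter. The recovery test suite measures exactly this: foot
orientation (quiet during stance) recovers to ~0.5°, while thigh/shank and
the joint angles built from them sit at 2–4°. Lowering the proportional
gain, or disabling the corrections entirely, removes the floor on clean
data but abandons the drift rejection the filter exists for.

## Event detection

Candidate heel strikes are local maxima of global-frame vertical
acceleration (orientation-rotated specific force with the 1 g reaction
removed — robust to mounting) above the peak threshold; candidate toe offs
are local minima below the valley threshold. Each candidate must be
confirmed by a sagittal angular-velocity zero crossing within ±50 ms —
downward for heel strike, upward for toe off, in the original device
mounting convention (sagittal axis pointing left), under which the
heel-strike foot slap is a negative-going crossing. Thresholds are
individualized as 0.6 × the signed mean extremum amplitude over the first
three stable cycles, found with conservative ±2 m/s² bootstrap thresholds;
the batch driver then re-detects the full series (the on-line system would
switch thresholds mid-stream). Detector constants: local-extremum separation
0.3 s for same-type candidates, and a 0.15 s debounce between consecutive
opposite-type events (a heel strike and toe off that close cannot both be
physiological at walking cadences; the stronger extremum wins). Cycles are
stable when the HS→TO→HS ordering is physiological and the duration is
within ±20% of the preceding cycle.

## Trajectories and spatiotemporal parameters

Specific force is rotated to the global frame, gravity removed, and
integrated trapezoidally. Foot-flat intervals are the longest quiet runs
(‖ω‖ < 20 °/s and |‖a‖ − g| < 0.5 m/s² sustained ≥ 50 ms) inside each
stance window guarded by 50 ms against impact and push-off; the quiet test
uses sensor-frame norms, so it is mounting-independent. Zero velocity is
imposed at interval midpoints: the piecewise-linear velocity ramp through
the anchors is subtracted (the trial start counts as an anchor — the
protocol begins at rest — and the last segment's drift rate is extrapolated
beyond the final anchor). Corrected velocity integrates to position;
initial contacts are the positions at heel-strike samples.

The walking axis is the principal horizontal direction of all contact
positions (sign along net displacement). Stride length is the walking-axis
projection of successive same-side contact displacements (a Euclidean-norm
variant is available; the two coincide on straight walking). Step width is
the mediolateral separation of nearest-in-time contralateral contacts.
Cadence is `(n_steps − 1)/elapsed × 60` counting both feet; walking
velocity is net walking-axis displacement over elapsed time between first
and last contact.

**Limitation — step width from per-foot dead reckoning.** Each foot's
trajectory is reconstructed relative to its own starting point; the constant
lateral separation between the feet is unobservable from the inertial
streams alone, so on synthetic trials the reported step width reflects only
relative lateral motion, not the true stance width. Stride length, cadence,
and velocity are unaffected.

## Agreement analysis

The reference stream is low-pass filtered (zero-lag fourth-order
Butterworth, 6 Hz cutoff), temporally aligned by normalized
cross-correlation of the pelvic angular-rate magnitude (never the limb
angles under validation), and both streams are linearly resampled to a
common 100 Hz base. Lag sign: positive means the test stream leads the
reference; exact ties (periodic channels) resolve to the smallest |lag|.
Metrics per variable: RMSE; relative RMSE as a percentage of the reference
mean; Pearson r; Bland–Altman bias and 95% limits of agreement using the
sample SD (n−1); and ICC(2,1) — two-way random effects, absolute agreement,
single measurement, the standard form for method comparison (computed via
pingouin and cross-checked in the tests against the two-way ANOVA formula).
Zero-variance inputs set r and ICC to NaN with an explicit reason rather
than raising.

## Synthetic gait simulator

The simulator is the package's study-condition generator. Defaults emulate
a healthy adult on a straight walkway at a self-selected comfortable speed:
cadence 114 steps/min (1.05 s cycle), stride 1.36 m (≈1.29 m/s), 14 cycles
(~15 s of walking) bracketed by quiet standing, duty factor 0.6, step width
0.10 m. Hip and knee waveforms are 3-harmonic Fourier fits to canonical
normal-gait sagittal traces (hip ≈ 43° ROM, knee ≈ 63°); pelvic tilt
(±1.5°) and rotation (±4°) are small sinusoids. The foot's pitch follows a
physiological rocker — heel-first landing 15° dorsiflexed, foot slap to
flat over the first 8% of the cycle, exactly flat mid-stance, push-off rise
peaking ~26 ms after toe off, swing return bottoming ~16 ms before the next
heel strike — built from cubic smoothsteps so both detection-relevant
angular-velocity zero crossings are transversal and sharply localized. The
ankle angle is the chain residual (shank⁻¹ ⊗ foot), which lands at a
realistic ≈26° ROM.

Foot positions are exactly stationary through stance, advance by a quintic
smoothstep with a C² lift bump during swing, and carry compact
position-wiggle transients (±40 ms, zero net velocity change) whose second
derivatives form the heel-strike peak (+14 m/s² nominal) and toe-off valley
(−12 m/s²) — wide enough to survive the median-5 preprocessing stage. The
pelvis progresses smoothly (±8% speed oscillation at two per cycle, 1 cm
vertical bob); thigh and shank sensor positions follow the orientation
chain, and their accelerations are obtained by numerical differentiation,
while foot accelerations are analytic. Amplitude envelopes ramp gait in
over the first cycle and out after the last heel strike, so trials start
and end standing.

The measurement model inverts what the filter assumes: per node, gyro =
segment body rate in a randomly misaligned (≤3°) sensor frame plus bias and
white noise; accelerometer = sensor-frame specific force plus bias, noise,
and an optional sinusoidal soft-tissue artefact (off by default);
magnetometer = the rotated unit field reference plus noise. Default noise:
gyro σ 0.005 rad/s with ≤0.01 rad/s bias, accelerometer σ 0.2 m/s² with
≤0.05 m/s² bias, magnetometer σ 0.02 (per-sample at 200 Hz). All randomness
flows through one seeded generator; identical seeds give bit-identical
streams. The reference synthesizer resamples truth angles to 100 Hz with
configurable marker noise and a known injected lag.

What the simulator does **not** model: positional closure between the foot
trajectories and the orientation chain (foot position and chain orientations
are prescribed independently); rigid-body lever-arm coupling between a
node's gyro and accelerometer signals; magnetic disturbance; soft-tissue
wobble with realistic spectra; turning, stairs, or pathological gait.
Passing tests therefore establish internal consistency of the pipeline and
its behaviour under the stated noise model — not clinical accuracy on real
subjects.

## Numerical choices

* Preprocessing windows: median 5 and mean 5 samples (25 ms at 200 Hz),
  clip limits at the sensor full-scale ranges (±8 g, ±1000 °/s) in SI;
  shrinking windows at the boundaries so no fabricated samples enter event
  detection.
* Neutral-alignment convergence is judged on window-averaged orientations
  (mean quaternions of the two halves of the final 0.5 s) against a 0.5°
  default threshold — the filter's own orientation noise floor under the
  default magnetometer noise is ~0.1°, so a tighter gate would reject
  legitimate captures; genuine motion during the capture still trips it.
* Static detection for gyro-bias estimation uses a per-axis standard
  deviation gate (0.05 rad/s) — the mean is the bias being estimated.
* The ellipsoid fit solves the 9-parameter algebraic quadric by linear
  least squares and whitens with the symmetric matrix square root; design
  matrices with condition number >1e10 (coplanar clouds) are rejected.
* Angle comparisons between quaternions use the chord-based geodesic angle,
  which keeps precision for sub-micro-degree differences.
* Sagittal angle series are unwrapped; frontal/transverse are reported raw.
* Problem sizes in the test suite: the recovery surface runs one noise-free
  and ten seeded noisy trials of the default 14-cycle walk; consistency
  oracles run a 2-cycle trial at 1 kHz.
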