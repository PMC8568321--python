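# Methods

This note documents the models, conventions, and defaults behind
`gravipoint`, in the order data flows through the pipeline.

## Experimental model

One parabola exposes a seated participant to three measured gravity phases
— steady flight (~1 g, 20 s before parabola entry), pull-up (~1.8 g), and
weightlessness (~0 g) — followed by a rest interval. A campaign is 10
parabolas; local gravity compensation is active on parabolas 5–9
(`default_compensated_parabolas` scales this to shorter simulated
campaigns by compensating the upper half, so both factor levels are always
observed). In every measured phase the participant points from a 60 mm
start circle to a 20 mm target at one of seven distances (8–20 cm in 2 cm
steps) above or below the start, each target appearing once per phase in a
pseudo-random order with no more than three identical consecutive targets.

Screen frame: x horizontal (positive away from the trunk), y vertical
(positive up), z normal to the screen. Positions in mm, time in seconds on
a single per-trial clock shared by the 100 Hz marker channel and the
1 kHz EMG/gravity channels (hardware synchronization is assumed, and made
explicit here because the schema depends on it). Gravity in multiples of
g0, forces in newtons.

## Compensation control law

With `W` the force needed to hold the participant's arm horizontal in 1 g
(calibrated per participant; 18.6 ± 4.8 N across the group) and `g` the
ambient gravity multiple, the wrist load is restored to its 1 g value by a
net vertical force

    F = W · (1 − g)      (positive downward),

clamped to ±30 N. The clamp applies to the *net* force, not per-motor
tension. Tension allocation is this package's explicit convention: the
motor on the pulling side carries `|F| + t_min` and the opposing motor
`t_min` (default 2 N) so both strings stay taut; without compensation both
motors hold a constant 10 N pretension and the net force is zero.
Controller latency is one sample at 1 kHz (the resolution floor of the
stated control rate), with optional first-order smoothing of the gravity
estimate (off by default). The shoulder-torque oracle treats the arm as
loaded at the wrist with a single configurable lever arm: residual torque
`(W·g + F − W) · lever`, identically zero whenever compensation is active
and the clamp does not bind, i.e. for `W ≤ 30/0.8 N` over `g ∈ [0, 1.8]`.

## Synthetic data generator

The generator produces the statistical structure the analysis assumes, not
arm biomechanics. Per movement:

- **Trajectory.** Vertical displacement follows a beta-family profile:
  the speed profile is a Beta(a, b) density with `a = 1 + r·c`,
  `b = 1 + (1−r)·c`, giving relative time to peak velocity exactly `r`
  (defaults r = 0.44 upward, 0.47 downward, concentration c = 5;
  `r = 0.5` recovers a near-minimum-jerk bell). A half-sine horizontal
  bulge of signed amplitude per (gravity, direction) models curvature;
  endpoint = target center + bias + Gaussian touch scatter; Gaussian
  marker noise (SD 0.3 mm) and dropout runs (rate 0.01/sample, max run 3)
  are added on top. Touch events are consistent with the trajectory and
  the press coordinate is the trajectory endpoint.
- **Durations.** `T = (0.35 s + 0.0125 s/cm · distance + participant
  shift) × m(gravity, direction)`, trial noise SD 0.05 s. Default
  multipliers m: microgravity 1.30 (up) / 1.05 (down), hypergravity 0.90
  (up) / 0.85 (down), normogravity 1.
- **Endpoint bias (mm, + above target).** micro +0.5 (up) / +2.0 (down),
  hyper −6.0 (up, the undershoot case) / −1.0 (down); scatter SD 4 mm.
- **Curvature (mm, + away from trunk).** Upward: −4 (normo), −9 (micro,
  the larger toward-trunk bulge), −4.5 (hyper); downward: −6 (normo), −2
  (micro), −2 (hyper); trial SD 1.5 mm.
- **EMG.** Each channel is band-limited Gaussian noise (30–300 Hz, unit
  RMS) modulated by a beta-shaped burst spanning the movement. The burst
  is scaled by its *time integral* (mV·s), so the configured gain is the
  iEMG truth independent of movement duration. For deltoid
  anterior/posterior and trapezius the gain is `amplitude × g_eff`, linear
  in the effective wrist gravity (1.0 under compensation); the pectoralis
  gain is gravity-insensitive, reflecting its line of action roughly
  perpendicular to gravity. Per-trial lognormal gain variability
  (CV 0.15), per-participant lognormal gain (SD 0.10), additive noise
  floor 5 µV.
- **Compensation.** A single attenuation factor λ ∈ [0, 1] multiplies
  every gravity-effect delta (duration, bias, curvature) when compensation
  is on: λ = 0 restores normogravity statistics exactly in law (equal
  seeds give equal trajectories up to labels), λ = 1 removes the benefit.
  Default λ = 0.3, i.e. substantial but incomplete behavioral improvement.
  The wrist-effective gravity used for EMG is exactly 1 under
  compensation; λ models the residual *behavioral* effect, not residual
  force error.
- **Participant random effects.** Duration shift SD 0.04 s, bias SD 1 mm,
  curvature SD 1 mm, arm-support force N(18.6, 4.8) clipped to [5, 40] N.
- **Seeding.** One master seed; per-trial seeds derived by counter
  (`SeedSequence(seed, spawn_key=(k,))`), so any trial is independently
  reproducible.

None of the group effect magnitudes were published with raw data; the
defaults are placeholders chosen once to match the reported effect
*directions* at plausible magnitudes, and they define the package's study
conditions. What passing tests show is that the pipeline recovers whatever
structure the generator embeds — not that these magnitudes match real
flights. The generator also omits: multi-joint arm dynamics, vestibular
and visual adaptation over parabolas, fatigue, EMG cross-talk, and motion
of the aircraft frame.

`simulate_feature_table` is a distribution-level shortcut that draws
durations/deviations/curvatures directly from the same generative model,
bypassing trajectory synthesis; it is used for the large simulation
studies (type-I error, power, contrast patterns) while the full path is
validated separately by generator→extractor round-trip tests.

### Planted defects

`inject_defects` corrupts chosen trials strictly beyond the QC thresholds
so detection is unambiguous: a mid-movement gravity (or hand-gravity) step
between phase levels, a reference-marker random walk rescaled to twice the
4 mm SD limit, a missing run one sample over the limit, an 80 mm marker
step, a release 1.3× the start-circle radius off-center, an initial dip
3× the direction dead-band, and a three-cycle ±50 mm horizontal zigzag
(path/chord well above 2 after filtering). Each planted defect is recorded
with trial id and type.

## Preprocessing and quality control

Interior marker gaps are linearly interpolated per coordinate; gap
metadata (run starts/lengths on the raw data) is kept and the missing-run
rule is evaluated on it, never on the filled series. Leading/trailing gaps
are never extrapolated — they are exclusion-grade. Filtering is a
zero-phase (forward–backward) 2nd-order Butterworth low-pass at 10 Hz:
"2nd order" names the designed filter, and the double pass squares the
magnitude response (gain 0.5 at the cut-off, not 1/√2) while cancelling
phase. Endpoints use odd reflective padding (3 × (2·order + 1) samples).

Movement onset is the stylus release inside the start circle, offset the
next press; duration is therefore a touchscreen quantity, invariant to all
marker processing. Segmentation errors (no release, out-of-order events)
are exceptions; QC rule violations are report entries.

Three exclusion rules have no published thresholds and are operationalized
with configurable defaults, flagged in every report that uses them:
discontinuous jumps (> 50 mm between consecutive valid samples at 100 Hz),
opposite-direction starts (initial excursion beyond a 5 mm dead-band
against the target direction before any 5 mm progress toward it), and
abnormal trajectories (path/chord ratio > 2.0 on the filtered movement
window, or speed > 5 m/s). Start-circle membership is Euclidean distance
against the 30 mm radius. Gravity-phase stability classifies each
in-movement sample to the nearest of {0, 1, 1.8} g and fails on more than
one class. The stationary-marker rule is strict: SD exactly 4 mm passes
("exceeded" means >).

## Kinematic and EMG features

The endpoint source is the touchscreen press coordinate, not the marker.
Signed deviation is vertical distance from the target center (positive
above); overshoot means beyond the target along the movement direction;
at exactly zero the flag is undefined. Movements with absolute deviation
strictly greater than 20 mm (the inter-target spacing) are excluded;
20 mm exactly is retained.

Speed is the 3-D magnitude of the central-difference derivative of the
filtered trajectory (forward/backward differences at the window ends);
using the vertical component instead is a switch. rTPV is
`(argmax time − onset)/duration`, ties to the earliest peak, undefined on
a flat-zero profile. Curvature is measured against the onset→offset chord
(parameterized by vertical fraction); the raw-x-from-start alternative is
available via `chord_relative=False`. Noise-free round-trip recovery is
exact for duration and deviation, within one sample for rTPV, and within
a few percent for curvature (the filter's edge transient at onset/offset
slightly tilts the chord) — the tests assert these bounds.

The EMG envelope is the classic linear envelope — full-wave rectification
then zero-phase 2nd-order Butterworth at 6 Hz, clipped at zero — because
the envelope algorithm is otherwise unspecified; the cut-off is
configurable. iEMG is the trapezoidal integral over [onset, offset],
applying the 100 Hz-derived touch window directly to the 1 kHz envelope.
Normalization divides by the participant × muscle mean of
normogravity-uncompensated movements, chosen because every condition is
interpreted relative to unassisted 1 g.

## Statistical analysis

Statistical units are per-target (kinematics) or per-muscle (EMG) means of
retained movements within participant × direction × gravity ×
compensation; empty cells are simply absent. Each movement direction is
modelled separately and never compared to the other.

The mixed model has the full factorial of gravity (3) × compensation (2) ×
target (7, categorical — the design names seven targets, not a distance
covariate) or muscle (4) as fixed effects and a per-participant random
intercept, estimated by REML (statsmodels MixedLM). The random-effects
structure is a convention (the model family alone does not fix one);
random slopes are deliberately out of scope. A singular random-effects fit
is flagged; if estimation fails outright the model falls back to fixed
effects with a warning. Main effects and the gravity × compensation
interaction are Wald F tests with containment-style denominator df,
`n_obs − rank(X) − (n_participants − 1)` — df conventions differ across
mixed-model implementations, and this one is documented rather than
claimed canonical. With 9 participants and 7 targets this gives 328
denominator df per direction.

The six planned comparisons are contrasts of (gravity, compensation) cell
means averaged over targets/muscles, signed as mean(first) − mean(second)
of the label (so 1g–0g is negative when microgravity durations are
longer). Each is a z statistic (estimate/SE from the fixed-effects
covariance) with Bonferroni adjustment `min(1, 6p)`; significance at 0.05.
Inestimable contrasts (an unobserved cell) are reported as undefined, not
dropped.

Operating characteristics, measured by simulation at the defaults
(`gravipoint.studies`): type-I error of the gravity main effect
0.049–0.054 over 1,000 null replicates (within the 0.03–0.07 band); power
1.0 for the microgravity upward-duration effect over 200 replicates at
n = 9; with λ = 0 the headline contrast pattern (1g–0g and 1g–2g
significant, 1g–0gC and 1g–2gC not) reproduces in ≥ 94% of replicates.
These studies use the distribution-level generator at 9 participants ×
5 repetitions per cell; the acceptance script reruns them at 400/200/50
replicates, sizes chosen to keep the whole script under a minute.

## Numerical and degenerate-input choices

- Filter calls require series longer than 3 × (2·order + 1) samples.
- `rtpv` and `curvature_max_x` raise on flat-zero speed and zero-length
  chords respectively rather than returning sentinels.
- The accuracy rule and the reference-SD rule are strict inequalities at
  the printed thresholds.
- Dataset CSVs are written at full float precision (`%.17g`); round-trips
  preserve gaps sample-exactly and reals to better than 1e-9 relative.
- Pseudo-random target sequences repair runs longer than three by
  deterministic swaps, preserving balance and seed-reproducibility.

## Known limitations

Placeholder effect sizes (above); a single-lever-arm torque model with no
motor/string dynamics; QC rules 5/7/8 are documented stand-ins for
unpublished criteria; EMG normalization and envelope conventions are this
package's choices; Wald/containment inference is approximate relative to
Kenward–Roger-style corrections, though well-calibrated at the design
sizes tested.
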