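# gravipoint

Simulation and analysis pipeline for touchscreen pointing movements
performed under altered gravity — the microgravity (~0 g) and hypergravity
(~1.8 g) phases of parabolic flight — with and without **local gravity
compensation**: a motorized cable device that applies a vertical force at
the wrist so the gravitational torque at the shoulder stays at its 1 g
value regardless of ambient gravity.

The package is aimed at motor-control researchers who want to exercise and
validate this measurement chain end to end without flight data. It
provides:

- **`gravipoint.generate`** — a synthetic experiment generator: stylus
  trajectories with a beta-shaped speed profile (settable relative time to
  peak velocity), touchscreen events, four-channel surface EMG
  (deltoid anterior/posterior, trapezius, pectoralis), ambient and
  wrist-effective gravity traces, participant random effects, and planted
  quality-control defects with ground-truth labels.
- **`gravipoint.compensation`** — the compensation control law
  `F = W·(1 − g)` (positive downward, `W` the per-participant arm-support
  force, nominally 18.6 N), a ±30 N safety clamp, 10 N pretension when
  compensation is off, string-tension allocation, and a 1 kHz closed-loop
  simulation with a shoulder-torque oracle.
- **`gravipoint.preprocess`** — marker-gap interpolation, zero-phase
  2nd-order Butterworth low-pass at 10 Hz, movement segmentation from touch
  events, and the eight trial-exclusion rules (gravity-phase change during
  a movement, hand-gravity change, stationary-marker SD > 4 mm, more than
  five consecutive missing samples, discontinuous jumps, bad start,
  opposite-direction start, abnormal trajectory).
- **`gravipoint.kinematics` / `gravipoint.emg`** — movement duration
  (touchscreen release→press), signed/absolute endpoint deviation with
  overshoot–undershoot semantics and the 20 mm accuracy cutoff, trajectory
  curvature (largest signed horizontal deviation from the onset–offset
  chord), peak speed, rTPV, and the EMG chain (20–350 Hz band-pass, linear
  envelope, integrated EMG, per-participant normalization).
- **`gravipoint.stats`** — linear mixed models for the
  3 gravity × 2 compensation × 7 target (kinematics) and
  3 × 2 × 4 muscle (EMG) designs, fit per movement direction with a
  per-participant random intercept (REML), plus the six planned condition
  contrasts 1g–0g, 0g–0gC, 1g–0gC, 1g–2g, 2g–2gC, 1g–2gC as z tests with
  Bonferroni correction over the family of six.
- **`gravipoint.pipeline` / CLI** — `gravipoint run` orchestrates
  simulate → QC → features → stats into one reproducible, seeded run with
  a manifest and a report mirroring the condition-contrast tables.

## Worked example

```python
from gravipoint import RunConfig, run_experiment

cfg = RunConfig(seed=3, n_participants=3, n_parabolas=2,
                out_dir="results/demo", make_plots=False)
manifest = run_experiment(cfg)
print(open("results/demo/report.txt").read())
```

This simulates 252 pointing movements (3 participants × 2 parabolas ×
3 gravity phases × 14 targets, compensation on in the second parabola),
runs QC and feature extraction, and fits the mixed models. The report's
upward-movement-duration block reads:

```
duration_s [up]
  comparison   z        p(adj)
  1g-0g       -9.821  0.0000 *
  0g-0gC      +6.978  0.0000 *
  1g-0gC      -2.843  0.0268 *
  1g-2g       +4.471  0.0000 *
  2g-2gC      -3.398  0.0041 *
  1g-2gC      +1.072  1.0000
```

Read: upward movements take longer in microgravity than normogravity
(negative 1g–0g), compensation shortens them again (positive 0g–0gC) but
not all the way back (1g–0gC still significant at the generator's default
partial-compensation setting), hypergravity shortens movements (positive
1g–2g), and compensated hypergravity is indistinguishable from
normogravity (1g–2gC). The same run writes `features.csv`,
`emg_features.csv`, `qc_report.csv`, `stats.csv`, and `manifest.json`.

The CLI mirrors the library: `gravipoint simulate`, `gravipoint
compensate`, `gravipoint qc`, `gravipoint features`, `gravipoint stats`,
`gravipoint run`.

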