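# Methods

This note documents the models, defaults and numerical choices behind
`motorequiv`, and what the simulation-based tests do and do not establish
about real motion-capture data.

## Study design the pipeline assumes

A cohort of participants each performs three cyclic tool-use actions —
pounding a nail with a hammer (vertical axis), sweeping with a brush
(lateral axis), painting with a roller (anteroposterior axis) — with four
end-effectors: right foot, right elbow, left hand, right hand.  Tool
motion is captured optically at 200 Hz via six passive markers per tool.
Participants produce 20–25 movement cycles per condition; analysis retains
cycles 6–19 (14 cycles), treating the first five as familiarization.  A
cycle is one forth stroke (the action-directed movement, e.g. raised
position → nail) plus the back stroke.

Axis convention: x anteroposterior, y lateral, z vertical.  Internal
units: mm, s, mm/s, mm/s²; performance summaries use cm where conventional.

## Kinematics

- **Filtering.** Zero-phase (forward–backward) Butterworth low-pass at
  10 Hz cut-off.  The per-pass order is not dictated by the protocol; we
  use 4th order per pass, the movement-science standard.  The dual pass
  squares the magnitude response (|H|² gain), slightly lowering the
  effective −3 dB point; we document rather than compensate this.  Tests
  check the measured gain of pure sinusoids against the dual-pass
  magnitude response (< 1 % loss at 2 Hz, > 99 % attenuation at 50 Hz).
- **Differentiation.** Central differences on the filtered positions
  (one-sided at the ends): exact for quadratics, hence directly testable
  against polynomial oracles.  Speed is the Euclidean norm of 3D
  velocity; *tangential acceleration* is the signed derivative of speed,
  so braking along the path is negative regardless of path curvature.
  Peak deceleration is the magnitude of the most negative value.  A
  config switch can restrict velocity to the primary axis instead of 3D
  speed; 3D speed is the default.

## Cycle segmentation

The protocol defines what a cycle is but not how to find one; the
detection algorithm is this package's own.  Cycle boundaries are local
extrema of the primary-axis coordinate on the stroke-start side (hammer:
z maxima; brush: y maxima, i.e. the right end of the sweep; roller: x
minima, nearest the body — the roller's forth direction is not verifiable
from the protocol and is configurable).  Extrema must exceed a prominence
of 20 % of the coordinate's range and are deduplicated at a minimum
separation of 25 % of the median inter-extremum interval from a first,
prominence-only pass.  The series is reflect-padded so extrema at the
first/last sample are detectable; partial cycles outside the outermost
boundaries are discarded before ordinals are assigned.  The forth/back
switch point is the opposite extremum inside each cycle.  Position extrema
(rather than velocity zero-crossings) are used because they are robust
after 10 Hz filtering and coincide with velocity zero-crossings anyway.

Cycle selection keeps ordinals 6–19 inclusive and errors if fewer than 19
cycles were detected — selection never silently analyzes a different
cycle range than requested.

## Landmarks

Per cycle: cycle duration (boundary to boundary) and vertical amplitude
(z range) over the **whole** cycle; maximum velocity, peak acceleration
and peak deceleration on the **forth stroke only**, since the forth
stroke characterizes the action.  Vertical amplitude is whole-cycle
because it is a spatial attribute, not a stroke-kinematic one.  Cells of
the landmark table are arithmetic means over the retained cycles (means,
not medians, with SD/SE retained for error bars); per-cycle amplitude is
averaged like every other landmark.

## Equivalence statistics

- Pearson correlations across participants for all six effector pairs,
  per tool × landmark; p-values from the exact t-transform
  t = r√(n−2)/√(1−r²), two-tailed by default (a config switch exposes the
  one-tailed variant; published two-decimal correlation tables generally
  cannot disambiguate the tail convention, which is why bundled reference
  flags are treated as data rather than recomputed).
- Holm's step-down correction is applied within each 6-entry matrix at an
  overall α = 0.05 — not across all 90 correlations.  Flags are computed
  via `statsmodels.multipletests(method="holm")` and are verified against
  a literal step-down implementation in the tests.
- Post-hoc power of the two-sided zero-correlation test uses the Fisher z
  approximation with √(n−3) scaling.  At n = 10, α = 0.05 this yields
  power 0.63 at ρ = 0.70, 0.77 at ρ = 0.77, 0.83 at ρ = 0.80 and 0.91 at
  ρ = 0.85 — the three-band structure (< 0.70 below ρ = 0.75, 0.70–0.80
  between, > 0.80 above ρ = 0.80) used to qualify non-significant entries.
- The within-subject (repeated-measures) ANOVA uses the standard one-way
  decomposition F = MS_condition / MS_(condition × participant), df
  (k−1), (k−1)(n−1), with **no** sphericity correction — reported df are
  the uncorrected integers.  The degenerate case of zero interaction
  variance returns F = 0 (equal condition means) or F = ∞ by convention.
  Implementation is `statsmodels.AnovaRM`; tests verify equality with a
  brute-force sum-of-squares decomposition and with `pingouin`.
- The tool comparison is implemented as a univariate one-way ANOVA across
  tools on per-participant effector-mean values (3 groups × n
  observations, df (2, 3n−3)); this is one defensible reading of a
  "one-way MANOVA with Tool as within-subject factor" that matches the
  printed df structure, and it is flagged here as an interpretation.
  Welch-free pairwise t post-hocs with Holm correction are attached when
  the omnibus test is significant.

## The simulator

The generator produces cohorts with the statistical structure the
analysis is designed to detect, so every stage is testable without any
proprietary data.

- **Signatures.** Per participant × tool: stroke amplitude, cycle
  duration and forth fraction drawn from truncated-at-zero normal
  populations; `preserved` mode reuses one signature across all four
  effectors, `null` mode redraws per effector.
- **Strokes.** Minimum-jerk quintic s(τ) = 10τ³ − 15τ⁴ + 6τ⁵, chosen
  because it is the standard smooth point-to-point model *and* has
  closed-form peaks — speed 1.875·A/d at mid-stroke, acceleration
  (10/√3)·A/d² ≈ 5.7735·A/d² — which serve as independent oracles for the
  whole filter–differentiate–segment–extract chain.  Analytic per-cycle
  landmark values and exact cycle boundaries are stored with each
  recording as ground truth.
- **Effector modulation.** Fixed multiplicative amplitude/duration scales
  per effector (defaults: foot 0.80/1.15, elbow 0.85/1.10, left hand
  0.95/1.05, right hand 1.00/1.00) model biomechanical constraints: they
  shift means but, being common to all participants, leave cross-effector
  correlations intact.
- **Secondary axes.** One full sinusoidal cycle at 5 % of stroke
  amplitude on one secondary axis and a half-amplitude, double-frequency
  sinusoid on the other, vanishing at cycle boundaries.  5 % keeps the 3D
  path non-degenerate while biasing the forth-stroke tangential-
  acceleration peak by ≲ 1.5 % relative to the primary-axis closed form
  (at 10 % the off-axis velocity mixes into d|v|/dt strongly enough to
  push the bias near the 5 % oracle tolerance, defeating the closed-form
  checks).  The vertical axis carries the larger secondary component for
  the brush and the smaller for the roller, preserving the qualitative
  ordering hammer ≫ brush > roller in vertical amplitude.
- **Variability and noise.** Optional multiplicative per-cycle jitter of
  amplitude and duration (SD 3 % of the parameter value, on by default)
  represents within-participant cycle-to-cycle variability — a realistic
  magnitude for practiced cyclic movement, not a measured quantity.
  I.i.d. Gaussian positional noise (default SD 1 mm) per sample,
  coordinate and marker models optical capture error.  Six markers sit at
  fixed rigid offsets within a 100 mm cube of the end-point; `marker_1`
  coincides with the end-point and is the designated endpoint marker, so
  the analyzed path carries the nominal noise SD.
- **Defaults.** 10 participants, 22 cycles, 200 Hz; per-tool populations
  (mean ± SD): hammer 300 ± 60 mm, 0.80 ± 0.15 s; brush 400 ± 70 mm,
  1.20 ± 0.20 s; roller 350 ± 60 mm, 1.40 ± 0.25 s; forth fraction
  0.45–0.50 ± 0.05.  These produce hammer-largest amplitude/acceleration
  and roller-smallest orderings; exact values are configuration, not
  contract.

What the simulator does **not** emulate: joint-chain biomechanics,
contact/impact events (nail strikes), marker occlusion and soft-tissue
artifact, non-stationary fatigue or learning trends, and any dependence
between a participant's signatures for different tools beyond
independence.  Passing the structure-recovery tests therefore shows the
*pipeline* recovers preserved signatures when they exist; it does not by
itself validate the biological claim on real recordings.

## Numerical choices and degenerate inputs

- TSV round-trips are exact at the declared 6-decimal precision; NaN
  coordinates and non-uniform time stamps are errors (no gap filling —
  occluded C3D samples likewise raise, listing the affected frames).
- Zero-phase filtering requires > 3(order+1) samples; cut-offs at or
  above Nyquist are rejected.
- Correlations on zero-variance vectors raise rather than return NaN;
  |r| = 1 maps to p = 0 as a boundary value; the Fisher-z power is
  reported as NaN for n < 4.
- Paired t on a zero-variance difference vector returns a flagged
  boundary result (t = 0, p = 1 when the difference is identically zero).
- Problem sizes in the test suite: closed-form checks run on single
  noise-free recordings; detection robustness uses ~100 simulated
  recordings; structure recovery uses a preserved cohort of n = 10
  (120 recordings) and a null cohort of n = 200 (2400 recordings,
  streamed to keep memory flat).

## Known limitations

- The segmentation algorithm is position-extremum based and assumes a
  dominant primary axis; strongly curved or multi-axis strokes are out of
  scope.
- The C3D support is deliberately minimal (little-endian, 3D points
  only, no analog channels) and is validated by round-trip against its
  own writer, not against third-party files.
- The MANOVA reading of the tool comparison is an interpretation (see
  above); alternative multivariate constructions would change that
  statistic but nothing else in the pipeline.
- Published correlation tables rounded to two decimals cannot be used to
  re-derive significance flags exactly; bundled reference flags are
  therefore fixture data.
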