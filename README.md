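# motorequiv

Kinematic motor-equivalence analysis of cyclic tool-use movements.

When people hammer a nail, sweep with a brush or paint with a roller, each
person does it with an individual spatiotemporal "signature" — how wide,
how fast, how briskly they stroke.  The motor-equivalence question is
whether that signature survives a change of end-effector: does someone who
hammers with broad, fast strokes using the right hand also do so with the
left hand, the elbow, or the foot?  `motorequiv` implements the full
analysis chain for answering that question from 3D motion-capture data of
cyclic tool use, plus a simulator for generating cohorts with known
structure:

1. **trajectory I/O** — marker trajectories as plain TSV (and a minimal
   C3D reader/writer), cohort manifests as CSV;
2. **kinematics** — zero-phase Butterworth low-pass filtering (10 Hz
   cut-off, 4th order per pass) and central-difference velocity, speed and
   tangential acceleration;
3. **cycle segmentation** — movement cycles delimited at stroke-start
   extrema of the tool's primary axis, split into forth and back strokes;
   cycles 6–19 (14 cycles) retained for analysis;
4. **landmark extraction** — per cycle: cycle duration, vertical
   amplitude, and the forth-stroke maximum velocity, peak acceleration and
   peak deceleration; averaged per participant × tool × effector;
5. **equivalence statistics** — for each tool × landmark, the six
   across-participant Pearson correlations between effector pairs, with
   Holm step-down correction at an overall α = 0.05 per 6-entry matrix,
   Fisher-z post-hoc power, within-subject ANOVAs and Holm-corrected
   paired *t* post-hocs.

The statistical core: for participants *i* = 1…n and effectors *a*, *b*,
let *x<sub>i</sub><sup>a</sup>* be participant *i*'s mean landmark value
with effector *a*.  The package computes

- *r<sub>ab</sub>* = Pearson correlation of (*x<sup>a</sup>*, *x<sup>b</sup>*) across
  participants, with p from *t* = *r*√(n−2)/√(1−r²), df = n−2;
- Holm flags within each 6-pair family: sort p ascending, reject while
  p₍ₖ₎ ≤ α/(m−k+1);
- power of the two-sided test at population correlation ρ via the Fisher z
  approximation, Φ(√(n−3)·atanh ρ − z₁₋α/₂) + Φ(−√(n−3)·atanh ρ − z₁₋α/₂).

High, significant correlations for most pairs indicate that individual
signatures are preserved across effectors (a generalized rather than
hand-centered motor program); the simulator's `null` mode generates the
contrasting regime with independent signatures per effector.

## Worked example

```python
from motorequiv import SimulationConfig, MotorEquivalence, reporting
from motorequiv.simulate import iter_recordings

cfg = SimulationConfig(n_participants=10, rng_seed=7)   # preserved mode
table, _ = reporting.extract_cohort(iter_recordings(cfg))
res = MotorEquivalence(table).fit()
print(res.summary())
rep = res.summary_report()
print("pct > 0.80:", round(rep.percent_above[(0.80, 'all')], 1))
a = res.effector_anova("hammer", "cycle_duration")
print(f"F({a.df_num},{a.df_den}) = {a.F:.2f}, p = {a.p:.2f}")
```

prints (abridged):

```
Cross-effector motor-equivalence analysis
========================================================================
participants:  10    alpha: 0.05    tails: 2
correlations: 90  significant (Holm): 90 (100.0%)
...
pct > 0.80: 100.0
F(3,27) = 127.69, p = 0.00
```

The 90 correlations are the 3 tools × 5 landmarks × 6 effector pairs.  In
this simulated cohort every signature is preserved across effectors by
construction, so all 90 correlations are Holm-significant and above 0.80 —
the clean-room version of the preserved-signature finding.  The
within-subject ANOVA line shows that *mean* levels still differ between
effectors (the simulated biomechanical modulation): motor equivalence is
about covariation across participants, not identical means.

The same pipeline runs from the shell:

```bash
motorequiv simulate --out-dir cohort --seed 7
motorequiv report --manifest cohort/manifest.csv --out-dir results
motorequiv reproduce-paper            # summary of the published table
```

`reproduce-paper` summarizes the published 90-entry correlation table
bundled in `motorequiv.fixtures` (the study deposited no raw data): 80/90
entries significant (88.9%), non-significant r in [0.43, 0.68], hammering
depth grand mean 2.3 cm.

## Documentation

See `docs/methods.md` for the model assumptions, simulator design,
numerical choices and known limitations.
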