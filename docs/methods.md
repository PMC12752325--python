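# Methods

This note documents the models, conventions and design choices behind
`reachkin`, and what its synthetic-data tests do and do not establish about
real recordings.

## Coordinate and unit conventions

All kinematics are computed in **pixels** and **pixels/second** in image
coordinates (origin top-left, y increasing downward).  Pose-estimator output
in normalized [0, 1] coordinates is converted at ingest by scaling with the
frame width/height (`adapt_pose33`).  Plotting flips the y axis so up is up;
storage never does.  No metric calibration is attempted: a single fixed
camera gives a consistent pixel scale within a participant, which is all the
within-participant contrasts and the mixed models require.  The elapsed time
between frames is taken as exactly 1/fps; per-sample timestamps are not
supported.

## Landmark preprocessing

Pose estimators attach a confidence ("visibility") to each landmark.
Samples with visibility below a threshold (default **0.5**) are treated as
missing; interior missing runs of at most **max_gap = 5** frames per
landmark are linearly interpolated in frame index; frames still missing any
landmark are dropped, and the counts of interpolated and dropped frames are
carried into every downstream summary.  With threshold 0 the step is the
identity.  These defaults are explicit but conventional rather than
validated: confidence handling is rarely reported in pose-based kinematics
studies, so both parameters are exposed.

Dropped frames leave discontinuities.  Framewise speeds are still defined as
step length × fps, but steps spanning a frame-index gap are **excluded from
the mean speed** (configurable): the true path across the gap is unknown and
a single spanning step would register as a spurious velocity spike.  BVE is
unaffected by gaps (it is a property of the position point set).  An
optional median filter on tracks exists but is off by default; no smoothing
or outlier rejection is applied anywhere unless requested.

## Statistics

**BVE** uses population (1/n) normalization and the track's own centroid as
reference point, making BVE² = Var(x) + Var(y) (population variances).  It
is computed over the continuous position data of a whole block, not over
per-trial endpoints, so it mixes trajectory extent with trial-to-trial
variability; that is the intended "movement consistency over a block"
reading.  BVE is translation- and rotation-invariant and scales linearly
with uniform coordinate scale; the test suite asserts these properties.

**Group table.** Across-participant cell statistics use the sample SD
(n−1); a single-participant cell reports SD as absent.  The default
analysis grid is the endpoint design {first, last day} × {first, last
block}.

**Change scores** are last-minus-first endpoint differences per participant
(day 5 block 5 minus day 1 block 1 on the default grid), joined with
FMA-UE; participants missing an endpoint are listed in a skip report, never
silently dropped.

## Mixed models

Each of the two models (palm BVE; mean palm speed) has eight fixed-effect
terms — intercept, Day, Block, Day×Block, trunk BVE, shoulder BVE,
trunk×shoulder BVE, FMA-UE — and two random-intercept variance components:
participant, and day nested within participant.  Choices worth stating:

* **Estimation** is REML via `statsmodels` `MixedLM` with a variance
  component for day within participant.  p-values and 95% CIs are Wald-z on
  the fixed effects.  Kenward-Roger/Satterthwaite corrections are not
  available in this stack; at very small n (7 participants) Wald intervals
  are anti-conservative and the convergence flag matters more than the
  third decimal of p.
* **Coding**: Day and Block are treatment-coded with the first level as
  reference, so a positive Day estimate means a higher value on the last
  day.  Published tables using a different reference or contrast convention
  can show the same effect with flipped sign.
* **Covariates** (trunk BVE, shoulder BVE, FMA-UE) enter uncentered with a
  raw product interaction; centering is available via a flag and changes
  the intercept and main-effect interpretation, not the interaction test.
* **Derived quantities**: ICC = (τ₀₀,participant + τ₀₀,participant:day) /
  (Στ₀₀ + σ²).  Marginal and conditional R² follow the variance
  decomposition Var(Xβ̂)/(Var(Xβ̂)+Στ₀₀+σ²) and
  (Var(Xβ̂)+Στ₀₀)/(Var(Xβ̂)+Στ₀₀+σ²).
* **Failure handling**: incomplete rows are deleted listwise with a
  reported count; a rank-deficient design raises an error naming the
  collinear columns; a non-converged or singular fit is returned with
  `converged=False` and a warning and its text report carries a banner.
  With 7 participants the day-within-participant component is weakly
  identified and non-convergence is common and expected; at 50 simulated
  participants the fits converge and, over 200 replicates, recover planted
  day, shoulder-BVE and FMA-UE effects without bias and with 95% CI
  coverage around 0.93–0.97.

## The synthetic generator

The generator emulates the study structure the pipeline targets — by
default 7 participants × 5 days × 5 blocks × 200 reaches per block (1000
per session, 5000 per participant), 30 Hz, 1920×1080 frame — with these
movement-model choices:

* **Reaches** are straight-line point-to-point movements with the
  minimum-jerk position fraction 10τ³ − 15τ⁴ + 6τ⁵, the standard model for
  unperturbed reaching.  Targets are drawn by direction-resampling inside a
  calibrated workspace rectangle; amplitudes are N(150, 30²) px and
  durations N(0.8, 0.15²) s, clipped.  A reach of duration T at frame rate
  f spans ⌈T·f⌉ frames, so a block's noise-free mean palm speed has the
  closed form (Σ amplitudes)·f/(Σ frames − 1), which `expected_mean_speed`
  returns and the pipeline reproduces to rounding error.  The per-block
  reach plan is keyed by (participant, block) but not day, so with a speed
  gain of 1 the expectation is exactly day-invariant.
* **Compensation** is proportional coupling: trunk displacement =
  `trunk_coupling` × palm displacement (default base 0.08), and the paretic
  shoulder adds `shoulder_coupling` × palm displacement (default 0.15) on
  top of the trunk.  Couplings vary across participants (SD 0.02) and are
  constructed to decrease with FMA-UE, encoding the premise that more
  impaired individuals lean more.  Because the measured trunk is the
  centroid of four landmarks of which one (the paretic shoulder) carries
  the extra excursion, the effective trunk gain is
  trunk_coupling + shoulder_coupling/4; the ground-truth record stores both.
* **Jitter**: landmark measurement noise is isotropic Gaussian (default SD
  2 px).  The three hand landmarks share one jitter vector per frame — a
  pose estimator localizes the hand as a unit, so its finger/wrist
  estimates shake coherently — while elbow, shoulders and hips get
  independent draws.  Hand-landmark offsets are symmetric about the palm,
  so the palm centroid equals the simulated palm path exactly at zero
  jitter, and a stationary palm with jitter σ has BVE → √2·σ (the
  four-landmark trunk centroid: √2·σ/2).
* **Practice effect**: a per-day gain (default 1.1) divides reach
  durations, so speed rises across days while the spatial path is
  unchanged.
* **Determinism**: all draws derive from the config seed through
  per-(participant, day, block) seed-sequence spawn keys; identical configs
  give bit-identical cohorts, and per-block quantities can be regenerated
  in isolation.

Default parameter magnitudes were chosen so that block outcomes land in the
ranges typical of single-camera pixel kinematics (palm BVE of order 10²,
proximal BVE of order 10¹, speeds of order 10² px/s).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: pose-estimation bias and outliers (noise here is
unbiased, near-Gaussian, mostly independent across frames), occlusion
structure (visibility is 1 everywhere unless masked by a test), 3D-to-2D
projection effects, target-dependent movement corrections, fatigue, or any
distinction between interception and throwing movements.  Generator realism
is not a validation surface; only internal consistency and parameter
recovery are.

## Numerical and test-design notes

* Comparisons of analytically zero quantities allow ~1e-9 absolute slack:
  the mean of n identical floating-point values is not bit-exact, so a
  constant track can have BVE ≈ 1e-12 px.
* Landmark CSVs round-trip exactly: floats are written with
  shortest-round-trip representation and re-read with the round-trip float
  parser.
* Monte-Carlo recovery asserts |mean estimate − truth| ≤ 4 Monte-Carlo
  standard errors (three parameters checked simultaneously) and CI coverage
  within [0.90, 0.99] at 200 replicates.
* Under a null with no participant structure, single-fit REML variance
  components are boundary-constrained and positively skewed, so the
  near-zero assertion is made on the mean over 10 replicates.
* Problem sizes in tests are scaled to the property being checked: formula
  oracles use 1,000 random tracks; the jitter limit uses ~10⁵ stationary
  frames; end-to-end pipeline tests use blocks of 2–25 reaches, which
  exercise every code path of the full 200-reach protocol at a fraction of
  the frames.

## Known limitations

* 2D only; out-of-plane motion aliases into pixel displacement.
* BVE over continuous block data conflates movement extent and
  inconsistency; it is a consistency measure only under a stable task
  layout across the blocks being compared.
* Wald inference at n = 7 participants is fragile; treat the small-cohort
  model reports as descriptive, as the convergence banner indicates.
* The 33-landmark adapter assumes the upstream estimator's landmark
  indexing; it flags missing landmarks per frame but does no identity or
  left/right swap correction.
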