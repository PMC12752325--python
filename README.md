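# reachkin

Markerless upper-limb reaching kinematics for post-stroke motor research:
from 2D pose-landmark time series to effector trajectories, per-block
variability and speed outcomes, change scores across practice, and
group-level mixed-effects models of proximal (shoulder/trunk) compensation.

## The problem

After stroke, improvements on a reaching task can come from genuine motor
recovery or from compensatory strategies — leaning the trunk or hiking the
shoulder instead of extending the arm.  Distinguishing the two requires
kinematics, not just task scores.  Single-camera markerless pose estimation
(e.g. the 33-landmark full-body convention used by common pose estimators)
makes frame-wise 2D landmark coordinates cheap to obtain in clinical
settings; this package turns such coordinates into interpretable movement
outcomes and group-level inference.

`reachkin` tracks eight landmarks per frame — pinky, index, wrist and elbow
of the paretic arm, plus both shoulders and both hips — and derives three
effectors per block of practice:

* **palm** — centroid of pinky, index and wrist;
* **shoulder** — the paretic-side shoulder landmark;
* **trunk** — centroid of both shoulders and both hips.

Two statistics summarize each block (coordinates in pixels, image
convention):

* **Bivariate variable error (BVE)**, the movement-consistency measure of
  the motor-control literature:

  BVE = √( (1/n) Σᵢ ((xᵢ − x_c)² + (yᵢ − y_c)²) ),

  with (x_c, y_c) the centroid of the same points — i.e.
  BVE² = Var(x) + Var(y) with population (1/n) normalization, computed over
  the continuous position data of a whole block.

* **Mean landmark speed**: the Euclidean distance between consecutive
  frames divided by the frame period (exactly 1/FPS), averaged over the
  block, in pixels/second.

At the group level, two linear mixed-effects models (one per hand outcome:
palm BVE and mean palm speed) regress the outcome on Day, Block, trunk BVE,
shoulder BVE, FMA-UE (the /66 upper-extremity Fugl-Meyer impairment score)
and the Day×Block and trunk×shoulder interactions, with random intercepts
for participant and for day within participant (REML; Wald 95% CIs).  The
report includes σ², both τ₀₀ components, ICC = Στ₀₀/(Στ₀₀ + σ²), and
marginal/conditional R².

Because raw patient videos are rarely shareable, the package includes a
fully synthetic session generator (`reachkin.synthetic_data`) with known
ground truth — minimum-jerk reaches, trunk/shoulder coupling that scales
with impairment, landmark jitter — so the entire pipeline is testable
end-to-end.

## Worked example

```python
import warnings
from reachkin import (SimConfig, simulate_cohort, preprocess, summarize_block,
                      build_model_table, fit_lme, LmeSpec, report, group_table)

cfg = SimConfig(n_participants=7, days=5, blocks_per_day=5,
                movements_per_block=20, seed=11)
series, participants, truth = simulate_cohort(cfg)
by_id = {p.participant_id: p for p in participants}
summaries = [summarize_block(preprocess(s), by_id[s.participant_id])
             for s in series if s.day in (1, 5) and s.block in (1, 5)]
print(group_table(summaries).round(1).to_string(index=False))
table = build_model_table(summaries, participants)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    print(report(fit_lme(table, LmeSpec("mean_speed_palm"))))
```

The group table reports across-participant mean and SD per outcome on the
2×2 endpoint grid (first/last day × first/last block); with the default
per-day speed gain of 1.1 the mean palm speed rises from ≈223 px/s (day 1
block 1) to ≈298 px/s (day 5 block 5) while BVE stays flat:

```
 day  block  n_participants  bve_palm_mean  bve_palm_sd  ...  mean_speed_palm_mean  mean_speed_palm_sd
   1      1               7          204.6         42.4  ...                 223.4                 9.1
   1      5               7          207.0         38.1  ...                 220.6                10.8
   5      1               7          204.8         42.5  ...                 301.6                14.9
   5      5               7          207.0         38.1  ...                 297.8                13.8
```

The mixed-model report for mean palm speed then recovers the practice
effect as the Day term (+78 px/s here, since speed was simulated to rise
with day), with a non-convergence banner whenever the variance components
are weakly identified — expected with only 7 participants and 28 rows:

```
*** WARNING: model did not converge; estimates unreliable ***
Linear mixed model — outcome: mean_speed_palm
Predictor                         Estimate                95% CI        p
Intercept                           264.53      [155.33, 373.73]    0.000 *
C(day)[T.5]                          78.19        [68.09, 88.30]    0.000 *
...
tau_00 participant               43.77
tau_00 participant:day           0.22
ICC                              0.32
N participants / days / obs      7 / 2 / 28
Marginal R^2 / Conditional R^2   0.919 / 0.945
```

The same pipeline is available from the shell:

```bash
reachkin simulate  --out cohort --seed 1 --participants 7 --movements 20
reachkin summarize --input cohort/landmarks.csv --participants cohort/participants.csv \
                   --out summary --days 1,5 --blocks 1,5
reachkin model     --input summary/block_summaries.csv \
                   --participants cohort/participants.csv --out models
reachkin plot      --input cohort/landmarks.csv --participants cohort/participants.csv \
                   --out figures
```

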