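# gaitbalance

Detecting impaired balance from treadmill walking: which gait metric, and
which kind of detection threshold, can tell that a person's balance has
changed?

`gaitbalance` implements a complete, tested version of that analysis for
laboratory treadmill data (optical motion capture at 100 Hz, per-belt force
plates at 1000 Hz, pelvis-perturbation logs).  Because such datasets are
rarely shareable, the package also ships a synthetic cohort generator that
reproduces the statistical structure the analysis assumes — with known
ground truth, so every stage of the pipeline is verifiable end to end.  It
is intended for biomechanics and human-movement researchers who want to
evaluate balance metrics, detection thresholds, or event-detection choices
before (or instead of) collecting a new cohort.

## The analysis

Subjects walk at 1.25 m s⁻¹ under one unimpaired and several impaired
conditions; in some bouts, pelvis force pulses (7.5/15 % bodyweight, 300 ms,
four directions, onset at left-leg midstance, 16 per bout, 25–30 s apart)
probe perturbation recovery.  Six balance metrics are computed per subject ×
condition, all oriented so higher = worse balance:

| metric | definition |
|---|---|
| step-width variability | SD of the signed ML calcaneus separation at heel strike (negative when crossed), 570 steps |
| step-time variability | per-side demeaned heel-strike intervals pooled, then SD, 570 steps |
| foot-placement predictability | residual SD of OLS: ML swing-foot placement ~ ML CoM position (stance-heel frame) + ML CoM velocity (lab frame) at midstance |
| maximum Lyapunov exponent λ | slope of the mean log divergence of nearest-neighbour trajectories in a delay-embedded C7-velocity space (d = 5 copies, delay T = 10 of 100 normalized samples/stride, 144 strides), fitted over the first stride |
| lateral margin of stability | mean of b − xCoM at heel strike, where xCoM = CoM + v/ω₀, ω₀ = √(g/ℓ), and b is the leading foot's 5th-metatarsal marker |
| CoM displacement | mean ML CoM travel over one gait cycle after the two 7.5 %BW rightward pulses |

Heel strikes are detected post hoc from the 6 Hz zero-lag-filtered resultant
CoP (fore-aft velocity rising above 0 m s⁻¹ or ML speed above 0.7 m s⁻¹,
earliest candidate within a 150/200 ms pairing window), with stutter steps
excluded; per-belt vertical GRF crossings of 100 N give toe-offs.

Detection of impairment is evaluated two ways: a **subject-specific
threshold** (a condition is impaired if its score is strictly worse than the
same subject's unimpaired score; 30 comparisons for 10 subjects × 3
impairments) and a **cohort-based threshold** (weighted logistic regression
on the scalar score, leave-one-subject-out, inverse-class-frequency weights
so chance is exactly 50 %; 40 comparisons).  Accuracy uncertainty comes from
bootstrap resampling of the underlying steps (400 of 570, or 99 of 144
strides for λ), and distributions are compared with Wilcoxon signed-rank /
rank-sum and Kruskal–Wallis tests at a Bonferroni-corrected α = 0.0071.

## Worked example

```python
import numpy as np
from gaitbalance import (SyntheticCohortConfig, cohort_pools,
                         bootstrap_accuracy)

config = SyntheticCohortConfig(n_subjects=10, seed=7)
pools = cohort_pools(config, regime="steady")   # generate + detect + measure

for threshold in ("subject_specific", "cohort"):
    dist = bootstrap_accuracy(pools, "step_width_variability",
                              threshold, n_samples=200, seed=7)
    print(f"{threshold}: {100 * dist.mean:.1f} ± {100 * dist.sd:.1f} %")
```

Output:

```
subject_specific: 100.0 ± 0.0 %
cohort: 77.3 ± 2.6 %
```

Under the default cohort (impairments inflate step-width variability by
~1.5× while subjects' baselines spread by ~20 %), step-width variability
detects the impairments perfectly against each subject's own baseline, and
loses ~23 points when one decision boundary must serve the whole cohort —
the gap grows as inter-subject spread increases relative to the impairment
effect.

A single trial can also be inspected directly:

```python
from gaitbalance import (draw_subject_params, generate_trial,
                         detect_trial_events)

params = draw_subject_params(config, 0)
trial = generate_trial(params, config, "perturbed", seed=(7, 0, 0, 1))
events = detect_trial_events(trial.trial)
print(events["valid"].sum(), "valid events")
```

A thin CLI mirrors the library: `gaitbalance simulate|events|metrics|
evaluate|report --help`.

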