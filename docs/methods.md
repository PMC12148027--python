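# Methods

This note documents the models, parameter choices and numerical decisions
behind `gaitbalance`: what the synthetic cohort generator does and does not
emulate, how each balance metric is computed, how detection is evaluated,
and where the design was genuinely open.

## Synthetic cohort generator

### What it emulates

The generator produces, per subject × condition, two steady-state treadmill
trials (~3 min at 1.25 m s⁻¹) and one perturbation bout (16 pelvis force
pulses: 4 directions × {7.5, 15} % bodyweight, each twice in pseudorandom
order, 300 ms long, onsets at left-leg midstance, 25–30 s apart).  The
statistical structure mirrors what the analysis assumes:

* **Step timing.** Heel-strike intervals are i.i.d. Gaussian around a
  per-side mean (a fixed 20 ms left–right asymmetry gives the per-side
  demeaning in step-time variability something real to remove).  The
  distributional form is an assumption — measured step-time distributions
  are only approximately Gaussian.
* **Lateral foot placement.** Placements follow a linear control law
  exactly by construction: the ML position of the landing calcaneus relative
  to the stance calcaneus equals `b·(CoM position rel. stance heel) +
  c·(lab-frame CoM velocity)` at the preceding midstance, plus residual
  noise.  Gains b = 1.2 (–) and c = 0.30 s are in the range reported for
  human ML foot-placement regressions.  The generator draws the *placement*
  first (giving the configured step-width SD) and solves for a consistent
  midstance CoM state, splitting the signal between position and velocity
  (55/45) and adding an independent state component (SD 4 mm) so the two
  regressors are not collinear.  Consequence: the configured step-width SD,
  placement residual SD and law coefficients are exact ground truth that the
  pipeline must recover.
* **Continuous signals.** The lateral CoM trajectory is a cubic Hermite
  spline through the midstance states (so sampling it at midstance returns
  the ground-truth state exactly); pelvis markers are the CoM plus
  offsets symmetric about zero, so their centroid is the CoM.  The C7 marker
  adds a stride-periodic component and a chaotic component — a time-scaled
  Lorenz trajectory whose largest exponent (0.9056 per unit time) is scaled
  to the condition's divergence-rate ground truth.  Foot markers follow
  stance (belt-fixed) / swing (smoothstep with a 13 cm apex) trajectories.
* **Forces.** Per-belt vertical GRF is a smoothstep-ramped plateau at
  ~1.02 bodyweight.  The resultant CoP runs along the stance foot at
  constant slope (belt speed minus heel-to-toe progression) and transfers to
  the new foot through a logistic of time constant 30 ms centred 90 ms after
  footfall.
* **Perturbation response.** Each pulse adds a smooth CoM excursion
  (smoothstep rise over the 300 ms pulse, exponential recovery with a 0.8 s
  time constant; 5 cm per 7.5 %BW), which feeds through the midstance states
  into the placement law, so the feet chase the displaced CoM and recover
  over about three steps.  The response gain is condition-independent —
  which is why, as in the evaluation this package supports, CoM displacement
  carries no impairment signal in the synthetic cohort.
* **Impairments.** Multiplicative inflations of step-width SD, step-time
  SD, placement residual SD and divergence rate.  The defaults average ~1.5,
  consistent with the ~53–54 % variability inflation the artificial
  impairments produced; the per-condition split (braces 1.45, eyes-blocked
  1.5, jets 1.65 on width, etc.) is invented and tunable.
* **Inter-subject spread.** Baseline means and SDs are drawn once per
  subject (Gaussian for means, lognormal for SDs so they stay positive) and
  shared across that subject's conditions — the mechanism that makes
  subject-specific thresholds matter.

All magnitudes that the protocol does not fix (baseline means and SDs,
marker geometry, GRF shape, impulse gains) are invented, physiologically
plausible, and collected in `SyntheticCohortConfig` or module constants.

### Two deliberate calibrations

Two generator constants are calibrated against the *definition* of the
event detectors, not against any measured data:

1. The CoP weight-transfer centre (90 ms) and time constant (30 ms) are
   chosen so that the fore-aft CoP-velocity zero crossing of the 6 Hz
   zero-lag-filtered signal lands at the nominal footfall instant (measured
   residual ≈ −1 ± 0.4 ms).  A zero-phase filter is symmetric in time, so
   any transfer shape implies some fixed offset between "the foot lands" and
   "the filtered velocity crosses zero"; the constant fixes that offset at
   zero so the generator's ground-truth timestamps and the detector's
   convention coincide.
2. The GRF unloading ramp is shifted by 22 ms so the falling 100 N crossing
   lands at the nominal toe-off, for the same reason.  Without it, detected
   midstances are systematically ~13 ms early and the sampled CoM states
   inflate the placement-model residual by a few percent.

The CoP track design also decouples the transfer-jump amplitude and the
local CoP velocity from the individual step time (a mean-reverting
recursion of the per-stance track start).  With a naive design the filtered
crossing time shifts with the step duration, which anti-correlates detected
step times with true ones and shrinks estimated step-time variability by
~9 % — a measurement artifact the real detector would also produce on
signals whose transfer amplitude tracks step length.

### What it does not emulate

No musculoskeletal dynamics, EMG, marker noise/gaps or soft-tissue
artifact; no belt-speed fluctuations; step *length* geometry is
deterministic; the perturbation response has a fixed shape; stutter steps
occur only when injected for validation (labelled).  Passing tests on this
generator therefore demonstrates the correctness of the measurement chain
and the statistical machinery under the assumed structure — not robustness
to real-world artifacts.

## Filtering and preprocessing

All filters are zero-lag Butterworth (forward–backward `sosfiltfilt`); the
stated order is the design order, so the cascaded gain at the cutoff is 0.5.
CoP: 4th order, 6 Hz.  GRF: 2nd order, 60 Hz.  Markers: within the
customary 8–25 Hz range, 10 Hz for foot markers feeding step geometry and
25 Hz for the CoM/C7 chain.  CoM = centroid of the pelvis markers; velocity
by central finite differences (one-sided at edges) before the final 25 Hz
stage.  Marker values at event times are linearly interpolated; force-derived
event times stay on the force clock.

## Event detection

Heel-strike candidates: upward crossings of 0 m s⁻¹ by fore-aft CoP
velocity, or of 0.7 m s⁻¹ by ML CoP speed; candidates within a pairing
window (150 ms perturbed, 200 ms steady) collapse to the earliest; a 100 ms
refractory guard suppresses filter ringing (inactive in practice since the
window is longer).  Side is assigned from the direction of ML CoP transfer.
Stutter exclusion invalidates a candidate when the front foot at the
candidate instant is the same foot as the previous valid heel strike, or
when the candidate foot's calcaneus is ≥ 0.2 m above the surface.
Midstance is defined as the temporal midpoint of heel strike and
ipsilateral toe-off — the simplest reproducible reading of an operationally
ambiguous term (alternatives: CoM-over-foot, or the 32.5 % gait-cycle point
used by perturbation controllers).  The first footfall of a trial has no
preceding weight transfer and is undetectable from CoP by construction; it
is excluded from oracle comparisons the way an experimenter discards the
incomplete first step.

## Metrics: numerical choices

* SDs use the n−1 denominator throughout (including regression residuals).
* Budget trimming takes the chronologically first 570 qualifying steps (144
  strides for λ); shortfalls raise an error naming the subject/condition —
  metrics are never silently computed on fewer.
* The λ estimator embeds forward (state at t concatenated with t+T …
  t+4T), searches nearest neighbours excluding the same stride and any
  zero-distance candidate, truncates divergence records at segment ends,
  averages log distances over available records per normalized timestep,
  and fits OLS over the first 100 timesteps.  Units: 1/normalized-timestep
  (multiply by 100 for per-stride).
* Steady-regime λ uses 8 sections × 9 strides from each of the two
  unperturbed trials (16 contiguous segments); the perturbed regime takes 9
  strides per pulse with the onset in the fifth.
* Margin of stability: pendulum length ℓ = ‖ankle − CoM‖ at heel strike,
  ω₀ = √(9.81/ℓ); the value is the axis distance from the extrapolated CoM
  to the leading foot's 5th-metatarsal marker, sign-flipped between sides so
  left and right steps pool coherently; higher = worse, following the
  convention of prior margin-of-stability work.  The anterior axis is
  available behind the same function but is not part of the headline six.
* CoM displacement is projected on the perturbation direction (rightward =
  −y); wording in the field permits signed or absolute versions, the
  direction-projected form is implemented.

## Detection evaluation

Subject-specific: strict inequality against the same subject's unimpaired
score (ties → unimpaired; conservative).  Cohort: scalar-feature logistic
regression, `class_weight="balanced"` (inverse class frequency — the unique
weighting that makes a constant classifier score exactly 50 %), effectively
unregularized (C = 10⁶), features standardized per training fold for
conditioning (an affine map, so the decision rule is unchanged),
leave-one-subject-out, fold accuracy = the same inverse-frequency weighting
(balanced accuracy), folds averaged.  Degenerate single-class training
folds are skipped with a warning.

Bootstrap: the resampling unit is the step (or stride) — 400 of 570, 99 of
144, with replacement, per subject × condition; models are refitted inside
each draw.  (70 % of 570 is 399; the conventional printed size of 400 is
used.)  For λ, resampling a stride multiset cannot preserve contiguity, so
the draw restricts which strides contribute reference points and neighbour
candidates while forward tracking stays on the original recording;
duplicated strides are inert because zero-distance neighbours are excluded.
Default sample counts: 1000 (100 for λ, which is ~100× costlier).

## Statistics

Wilcoxon signed-rank for paired distributions (exact p for n ≤ 25, normal
approximation with continuity correction above), Kruskal–Wallis omnibus
across metrics, rank-sum contrast of the variability group (step-width,
step-time, placement predictability) against the rest, all at the
Bonferroni-corrected α = 0.0071 (0.05/7, as conventionally printed).
Learning effects: the metric on 200-step windows sliding by 100, OLS of
value against window mid-time (units per minute), first-vs-last 200-step
values, signed-rank of slopes against zero.

When the subject-specific vs cohort comparison is run across "metric
variants", the intended grouping is the five steady-capable metrics × two
data regimes (steady, steady-plus-perturbation) plus CoM displacement
(perturbation data only) — 11 accuracy distributions.  The grouping is a
configuration choice of the caller, not hard-coded.

## Validation experiments (shared by tests and `scripts/acceptance.py`)

* **Parameter recovery.** One subject's two steady trials per seed; the
  570-step estimates of step-width SD, step-time SD and placement residual
  SD must fall inside the two-sided 99 % χ² band of the true σ (df = n −
  #fitted location parameters: 1, 2 and 3 respectively) in ≥ 98/100 runs.
* **Detector oracle equivalence.** Recall/precision ≥ 0.99 and ≤ 10 ms
  timing error against ground truth on steady walking over 20 seeds;
  injected stutters all excluded with no proper step lost.
* **Divergence validity.** The estimator is checked on a construction with
  an exactly prescribed rate: a uniformly expanding fold map (|slope| =
  e^λ, continuous triangle reflection, golden-ratio shift) observed
  linearly.  Between rare fold events every record's log distance is
  exactly linear in time; fold losses scale as 1/λ, so the check runs at
  λ = 0.03/timestep (3.0/stride, upper end of the physiological range),
  where the estimate is within ~3 % across seeds; the generic positive bias
  of smooth chaotic flows (e.g. ~+5 % on a time-scaled Lorenz signal, from
  the early alignment transient the fixed first-stride fit window includes)
  is a property of the estimator, not of this implementation.  Near-periodic
  strides (constant per-segment offsets) must give λ ≈ 0.
* **Threshold comparison.** Two prescribed regimes: inter-subject spread of
  each variability parameter at 2× the impairment effect (multipliers 1.25)
  — subject-specific must beat cohort for every variability metric; and a
  dominant effect (multipliers 2.0, ~5 % spread) — both must reach ≥ 95 %.
  Bootstrap size 200 here; generation is restricted to the two steady
  trials per group, which is all the steady regime consumes, keeping the
  experiment a few minutes on one CPU.

## Known limitations

Gaussian step statistics and an exactly linear placement law are
assumptions, not findings; the generator cannot probe violations of them.
The λ ground truth is injected via signal amplitude/time-scale, so only
ordinal recovery (monotonicity in the divergence multiplier) is tested on
gait-like signals; calibrated recovery is tested on the prescribed-rate
construction.  The headline detection-accuracy percentages of any real
cohort depend on effect sizes and spreads that are free parameters here;
the package validates machinery and qualitative orderings, not those
numbers.
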