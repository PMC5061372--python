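# Methods

## The measurement model

A subject copies an Archimedean spiral, drawing from the center outward
inside a 10×10 cm square; the pen trace is recorded as (t, x, y, pressure)
samples at roughly 100 Hz. The analysis re-expresses the trace in polar
form about the drawing origin: for an ideal spiral r = a + bθ, radius is a
straight line in unwrapped angle, so every departure of the drawn r(θ)
from its own least-squares line carries shape information ("unraveling"
the spiral). Six indices summarize a trace:

| index | definition | units | interpretation |
|---|---|---|---|
| mSp | total path length / total drawing time | cm/s | bradykinesia |
| T | turns drawn / maximal radius | loops/cm | micrographia (tighter = higher) |
| 2ndSm | ln mean[(Δ²ρ/Δθ²)²] of the detrended residual ρ | — | curvature irregularity |
| 1stZC | sign changes of Δρ per revolution | /rev | small frequent fluctuations |
| SWVI | CV of per-angle median loop-to-loop widths, tremor removed | — | erratic/ataxic spacing |
| DoS | 4·logistic(w₀ + w·z), z = (RMS(ρ)/r_max, 2ndSm, CV of speed) | 0–4 | overall execution severity |

Per subject, each hand's ten trials are aggregated by the mean (median for
SWVI, which is strongly right-skewed), and hand asymmetry is summarized as
the absolute dominant-minus-non-dominant difference of each aggregate,
yielding 18 features.

### Pipeline details and numerical choices

* **Center.** The centroid of the first K = 5 pen-down samples (subjects
  start at the center; acquisitions begin with the pen resting there).
* **Jitter zone.** Near the center, positional noise dominates the sample
  angle, and unwrapping through it can wind up spurious revolutions. The
  pen-rest jitter scale is estimated from the spread of the first K
  samples about their centroid; leading samples with radius below 6× that
  spread (capped at 30 % of the maximal radius) are skipped. A noise-free
  trace has zero spread and loses nothing.
* **Unwrap and direction.** The angle is unwrapped, sign-normalized so it
  is predominantly increasing (mirror-image spirals become identical), and
  shifted to start at zero. Samples where the angle retreats by more than
  0.05 rad from its running maximum are dropped (hand jitter).
* **Angle grid.** Radius and time are resampled onto a uniform grid of 360
  bins per revolution. Radius uses a shape-preserving cubic (PCHIP):
  piecewise-linear interpolation leaves slope kinks at every pen sample
  whose size scales with drawing speed, which would bias the curvature
  index by sampling density rather than drawn shape, while an ordinary
  spline rings where the angular sample spacing is uneven near the center.
  Samples closer in angle than half a grid step are thinned first.
* **Detrending.** One ordinary least-squares line r = a + bθ is fit on the
  grid and shared by 2ndSm, 1stZC and DoS, all defined relative to the
  ideal linear transform.
* **Tightness.** The angular span is extended to the line's r = 0
  intercept (capped at half a revolution) so the turns skipped inside the
  jitter zone are counted; without this the index is biased low by ~4 %.
* **Zero crossings.** Residual first differences below 10⁻⁹ cm are treated
  as exact zeros (zeros inherit the preceding sign), so float round-off on
  a perfect spiral cannot register crossings.
* **Tremor removal for SWVI.** The radius residual (trend removed first —
  the raw radius sweeps through time too quickly near the center for a
  time-domain filter) is low-passed at 2 Hz with a zero-phase 4th-order
  Butterworth before widths are computed; parkinsonian action tremor lives
  at 4–6 Hz. The cutoff is configurable; a cutoff of 0 disables filtering.
* **2ndSm floor.** ln of the mean squared second difference is floored at
  ln(10⁻¹²) so numerically perfect spirals have a finite value.
* **DoS weights.** The composite is a documented calibration, not a
  published formula: weights (w₀ = 0.21, w_rms = 8.0, w_sm = 0.9,
  w_cv = 1.5) live in `spiralkit.config.DosWeights` and were set once so
  that a noise-free spiral scores ≈ 0 ("normal", < 1), the generator's
  maximal-degradation preset scores > 3 ("severe"), and the default
  synthetic groups land near the 0.7–1.5 band of the clinical scale.
  All slope weights are positive, so DoS is monotone in each component.

## Statistical machinery

* **Welch t-test** from group summaries (mean, SD, n) with
  Welch–Satterthwaite degrees of freedom. The unequal-variance form is the
  package's dialect because recomputing the published demographic and
  index comparisons from their printed summaries reproduces the printed
  p-values (0.55 for age, 0.018 for speed) only under Welch.
* **Pearson chi-square** on 2×2 tables, df = 1, no continuity correction
  (again the variant that reproduces the printed values).
* **Mann-Whitney U** with midranks; exact enumeration of all label
  assignments for pooled n ≤ 20 (valid under ties), tie-corrected normal
  approximation otherwise. Used for SWVI and all hand-difference rows,
  which are skewed. IQR is reported as a single width (Q3 − Q1) with
  linearly interpolated quartiles.
* **Linear mixed models** per index on per-trial dominant-hand
  observations: value ~ group + age + sex + handedness with a random
  intercept per subject, REML (statsmodels MixedLM). The group effect is
  tested against a t reference with between-subject degrees of freedom
  (subjects − fixed-effect columns); the default Wald z is anticonservative
  at cohort sizes in the tens, inflating type-I error to ≈ 0.06 where the
  t reference restores ≈ 0.04–0.05. Optimizer falls back from L-BFGS to
  Powell/CG if the REML surface degenerates (near-zero between-subject
  variance).
* **No multiplicity adjustment** by default (12 unadjusted comparisons,
  matching the reporting style of the study design); Holm is available
  behind a flag.
* **Classifier.** Main-effects logistic regression on the 18 features,
  standardized with training-set statistics only. The MLE is computed by
  L-BFGS on the exact negative log-likelihood with analytic gradient; under
  (quasi-)separation — where the MLE is undefined — a weak ridge penalty
  (10⁻⁴, intercept unpenalized) is applied and a warning issued.
* **ROC/AUC.** Empirical ROC over all distinct thresholds, trapezoidal
  AUC; the tie convention makes AUC ≡ Mann-Whitney U/(n₁n₂) exactly. The
  Youden cut maximizes sensitivity + specificity − 1, ties broken toward
  higher specificity.
* **Cross-validation.** Three label-stratified random folds (stratification
  prevents single-class validation folds at cohort scale); per-fold AUC of
  a model trained on the other two folds, and their mean. Stratification
  and fold seeds are explicit everywhere.
* **Early-PD analysis.** PD records filtered to disease duration ≤ 5 years
  (all controls retained), then the same cross-validation.

## The synthetic cohort generator

No raw traces are distributed with the study design this package targets,
so the generator is a first-class component providing data with known
ground truth. One trace is an ideal Archimedean trajectory traversed at
constant tangential speed (after a 50 ms pen-rest dwell and a 250 ms
quadratic acceleration ramp; cruise speed is solved analytically so total
path / total time equals the nominal speed exactly), perturbed by three
radial noise processes chosen to steer different indices quasi-
independently:

1. **Irregularity field** — Gaussian knots every 0.7 rad of unwrapped
   angle, cubic-spline interpolated. Defining roughness in the angle
   domain makes its per-revolution structure intrinsic to the drawn shape
   rather than to drawing speed or sampling rate; it drives 2ndSm, 1stZC
   and DoS. Its zero-crossing rate is amplitude-independent, which is what
   keeps 1stZC near-null between groups even when amplitudes differ.
2. **Tremor** — a sinusoid at 4–6 Hz in time. Preset amplitudes are small
   and equal across groups: subjects in the emulated protocol draw in the
   treated ("on") state, where action tremor is largely suppressed — and
   the zero-crossing and tremor-band content of the two groups' published
   indices are indistinguishable.
3. **Loop-spacing drift** — a slow sinusoid in θ/2 modulating the spacing
   between successive loops; drives SWVI. Its amplitude is capped at 60 %
   of the loop spacing so loops cannot cross.

Subject-level parameters are drawn from truncated-normal group presets;
one hand (random side) is degraded by a multiplicative asymmetry factor on
the impairment parameters and loop spacing (not speed: slowing appears
bilaterally, so between-hand speed differences stay null, matching the
published difference table); trials add 6 % lognormal jitter. Covariates
emulate the study cohort: age ≈ 64/65 ± 10–14 years, 61 % vs 46 % female,
86 % right-handed, disease duration drawn so that exactly the requested
number of PD subjects fall at ≤ 5 years.

Preset levels were calibrated once (scripts preserved under `scratch/`)
against the published group means and the qualitative pattern — PD spirals
tighter, slower, more irregular, more asymmetric; zero-crossing rate
near-null — with the constraint that the cross-validated AUC of the
combined-index classifier lands in the study's 0.75–0.90 regime rather
than at an unrealistic 1.0. They were then frozen.

### What the generator does and does not emulate

It reproduces sampling rate, spatial extent, trial structure, effect
directions and discriminability regime. It does not model biomechanics
(no arm dynamics, no pressure dynamics — the pressure channel is carried
as constant 128 ± noise and unused), drawing-direction preference,
learning/fatigue across trials, pen lifts, or the absolute scale of the
published smoothness/zero-crossing values, which depend on the original
proprietary implementation's internal smoothing. Passing tests therefore
demonstrate that the measurement and inference machinery recovers known
ground truth and published-summary statistics — not that real tablet data
would yield the published AUC.

## Problem sizes

Unit tests run on reduced cohorts (20–24 subjects per group, 2–3 trials
per hand); statistical calibration uses 500 null replicates for the Welch
and mixed-model type-I checks, a 24 + 24 null cohort for the chance-level
cross-validation band, and 100 label permutations. The acceptance script
and the end-to-end acceptance tests run the full study-sized cohort
(138 PD / 150 controls, 50 early PD, 10 trials per hand, ≈ 5,760 traces).

## Known limitations

* DoS is a documented stand-in composite; its absolute values are
  calibrated to the generator, not validated against clinical ratings.
* The exact 2ndSm/1stZC scales are resolution-dependent (grid and
  interpolant choices); comparisons are internally consistent but not
  numerically transferable to other implementations.
* The mixed model uses a between-subject-df t approximation rather than
  Satterthwaite/Kenward-Roger degrees of freedom.
* Sensitivity/specificity at the Youden cut are high-variance functionals
  of one point on the ROC; seed-to-seed variation of a few points is
  expected at n = 288.
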