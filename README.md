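# spiralkit

Kinematic and spatial analysis of digitized spiral drawings as a
quantitative motor biomarker for Parkinson's disease (PD).

Handwriting is impaired early in PD. When a subject copies an Archimedean
spiral on a digitizing tablet, the pen trace (t, x, y, pressure at
~100 Hz) can be "unraveled" by the radius–angle transform: an ideal spiral
r = a + bθ becomes a straight line in unwrapped angle θ, and departures
from that line quantify tremor, micrographia and trajectory irregularity.
`spiralkit` implements this pipeline end to end for researchers in
movement-disorder biomarkers:

* six per-spiral indices — overall degree of severity (**DoS**, 0–4
  clinical scale), second-order smoothness (**2ndSm**), first-order
  zero-crossing rate (**1stZC**), tightness (**T**, loops/cm), mean
  drawing speed (**mSp**, cm/s), and the spiral-width variability index
  (**SWVI**, a coefficient of variation of loop-to-loop widths with
  tremor filtered out);
* per-subject aggregation over 10 trials per hand plus the absolute
  dominant/non-dominant difference of each index (PD is asymmetric);
* group statistics: Welch t-tests (computable directly from published
  summary tables), Pearson chi-square, exact/tie-corrected Mann-Whitney,
  and covariate-adjusted linear mixed models (random intercept per
  subject; age, sex, handedness);
* discriminative validity: an 18-feature logistic classifier, ROC/AUC,
  the Youden-optimal cut, three-fold stratified cross-validation, and an
  early-PD (disease duration ≤ 5 years) subset analysis;
* a synthetic cohort generator with known ground truth that emulates the
  acquisition protocol (10×10 cm square, ~100 Hz, 10 trials/hand,
  138 PD / 150 controls with 50 early PD), used by the test suite and the
  bundled analyses.

The scientific background, model assumptions and numerical choices are
documented in [docs/methods.md](docs/methods.md).

## Worked example

```python
import spiralkit as sk

# one noise-free spiral: 5 turns, 0.9 cm loop spacing, 20 cm/s
trace = sk.simulate_trace(sk.DrawingParams(), seed=1)
print(sk.compute_index_set(trace))
```

```
IndexSet(DoS=1.1178159420654164e-10, SecondSm=-27.631021115928547,
         FirstZC=0.0, T=1.1111111111111112, mSp=19.995772402721066,
         SWVI=3.4384499185558423e-16)
```

A perfect spiral scores DoS ≈ 0 ("normal" is below 1 on the 0–4 clinical
scale), smoothness at its numerical floor, no residual zero crossings,
tightness 5 turns / 4.5 cm = 1.111 loops/cm, mean speed equal to the
generator's 20 cm/s, and no width variability.

A full cohort analysis:

```python
metas, traces, truth = sk.generate_cohort(n_pd=138, n_control=150,
                                          n_early_pd=50, seed=20161012)
records = sk.subject_records(metas, sk.index_table(traces))
print(sk.comparison_table(records)[["block", "index", "control_center",
                                    "pd_center", "p_value"]].head(6))
feats = sk.feature_table(records)
disc = sk.analyze_features(feats, seed=20161012)
print(disc.cv.fold_aucs, disc.cv.mean_auc)
```

```
      block     index  control_center  pd_center       p_value
0  dominant       DoS        0.916635   1.283896  6.490937e-08
1  dominant  SecondSm       -2.665231  -2.244878  2.466018e-05
2  dominant   FirstZC        3.035185   3.478703  4.737825e-02
3  dominant         T        1.244362   1.472272  2.629918e-11
4  dominant       mSp       21.584341  19.947863  6.250084e-02
5  dominant      SWVI        0.252363   0.323288  3.591976e-04
[0.7621739130434783, 0.8056521739130434, 0.782608695652174] 0.7834782608695652
```

PD-preset spirals are more severe, less smooth, tighter, slower and more
variable in width, while the zero-crossing rate stays near-null — and the
combined-index classifier cross-validates in the high-0.7/low-0.8 AUC
range at this cohort size.

The same steps are packaged as numbered drivers under `analysis/`
(simulate → indices → group comparison → discrimination → published-table
checks), writing their tables under `results/`, and as a CLI:

```bash
spiralkit simulate --n-pd 138 --n-control 150 --n-early 50 --seed 1 --out scratch/cohort
spiralkit indices  --traces scratch/cohort/traces --out results/trial_indices.csv
spiralkit analyze  --cohort scratch/cohort/cohort.csv \
                   --indices results/trial_indices.csv --seed 1 --out results/analysis.json
spiralkit report   --seed 1 --out results/report
```

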