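# fogstep

Step-level detection and prediction of **freezing of gait (FOG)** in
Parkinson's disease from shank-mounted gyroscopes.

FOG is an episodic inability to progress the feet despite the intention to
walk — trembling legs, shuffling, or complete akinesia. Because
spatial–temporal gait parameters degrade progressively in the seconds before
an episode, a classifier operating on *individual steps* can both detect
ongoing freezes and predict imminent ones, enabling preventive cueing.
`fogstep` implements that analysis for researchers in wearable movement
analysis: it takes per-trial recordings of the x-axis angular velocity
ω<sub>x</sub> of each shin (60 Hz, one timed-up-and-go test per trial) and
runs the full chain from raw signal to subject-independent performance
reports. A seeded synthetic two-shin gait simulator generates annotated
cohorts with the same statistical structure, so every stage is testable
without patient data.

## Method

1. **Normalization** — per trial and per leg,
   ω′<sub>x</sub> = (ω<sub>x</sub> − mean ω<sub>x</sub>) / (max ω<sub>x</sub> − min ω<sub>x</sub>),
   giving zero-mean, unit-range signals so all later thresholds are relative.
2. **Synchronization** — the two devices start recording independently while
   the subject sits; the large sit-to-stand transient appears in both traces
   and superimposing those peaks recovers the inter-device delay.
3. **Step segmentation** — local maxima of ω′<sub>x</sub> mark mid-swing.
   Peaks ≥ 20% of the per-leg maximum and ≥ 350 ms apart anchor two slices
   per step: *Type I* (previous peak → current peak, the stride) and
   *Type II* (the positive lobe around the peak, the swing).
4. **Features** — 16 per step: stride std/range/RMS; angular jerk
   ½∫ω̈²<sub>x</sub> dt and its time-normalized variant; DTW cost against the
   previous stride; step and stride times; swing peak height and half-power
   width; and from the stride spectrum *P* (normalized squared FFT
   magnitude): spectral entropy −Σ P ln(P + ε) with ε = 0.001, principal
   harmonic frequency/amplitude/width, amplitude × frequency, and the
   fraction of power below 2 Hz.
5. **Labeling** — a step is *FOG* if its peak lies inside an annotated
   episode; *pre-FOG* if it lies within a window (2–5 s) before an onset;
   *gait* otherwise. Detection is gait vs FOG; prediction is gait vs pre-FOG
   with gait-initiation episodes excluded.
6. **Models and validation** — a Gini decision tree (≤ 15 splits) ranks
   features by first-split depth; a wrapper grid over (top-*f* features ×
   SVM cost *c* ∈ 1..20) is tuned by 10-fold CV; protocols are 10-fold CV,
   20× stratified 70/30 splits, and leave-one-subject-out (LOSO). The
   pre-FOG task additionally sweeps the window length against four model
   families (SVM, kNN, LDA, logistic regression) with seeded random-search
   hyperparameter tuning, tunes a false-negative cost (positive-class
   weight, 1–10), OR-combines SVM and LDA, and transfers models across
   levodopa on/off therapy states.
7. **Evaluation** — sensitivity, specificity, accuracy, PPV, NPV, F-score
   and Youden index (percent), ROC/AUC, Spearman feature–label correlations
   for features selected in ≥ 80% of LOSO folds, and detection latency in
   steps before each freeze onset.

## Worked example

```python
from fogstep import (DegradationProfile, FogEpisodeSpec, GaitProfile,
                     LabelingConfig, generate_trial, label_steps,
                     trial_feature_table)
from fogstep.pipeline import recording_from_synthetic

episode = FogEpisodeSpec(onset_s=20.0, duration_s=4.0,
                         phenotype="trembling", tremble_hz=5.0)
trial = generate_trial(
    GaitProfile(cadence_hz=1.0, noise_sd=0.03),
    episodes=[episode],
    degradation=DegradationProfile(window_s=2.0, amp_decay=0.5,
                                   steptime_shrink=0.7),
    duration_s=30.0, seed=0, sync_offset_s=0.5,
)
rec = recording_from_synthetic(trial)
print(f"estimated inter-device delay: {rec.sync_delay_s:.3f} s "
      f"(injected {trial.truth.sync_offset_s:.3f} s)")
steps = trial_feature_table(rec)
print(f"steps extracted: {len(steps)}")
ds = label_steps(steps, {rec.trial_id: rec.episodes},
                 LabelingConfig(prefog_window_s=2.0, task="prediction"))
print(ds.data.groupby("step_class")[["peak_height", "stride_time_s",
                                     "low_power_frequency"]].mean().round(3))
```

Output:

```
estimated inter-device delay: 0.483 s (injected 0.500 s)
steps extracted: 38
            peak_height  stride_time_s  low_power_frequency
step_class
gait              0.231          1.041                0.827
prefog            0.221          0.975                0.812
```

The stand-up peaks recover the half-second device offset to within one
sample (1/60 s). Of the 38 detected steps, the four labeled pre-FOG show the
expected degradation direction: lower mid-swing amplitude, a shorter stride
period, and less power in the 0–2 Hz locomotor band.

## Command line

```bash
fogstep simulate --out cohort/ --seed 1            # synthetic cohort
fogstep features --cohort cohort/ --out steps.csv  # per-step feature matrix
fogstep run --cohort cohort/ --out results/ --seed 1
```

`run` writes `summary.json` with every validation report, the window ×
family accuracy grid, the cost curve, correlation tables and latency
summaries.

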