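# Methods

This note documents the models, numerical conventions and design choices
behind `fogstep`, and what the synthetic benchmark does and does not show.

## Signal model and preprocessing

The analysis operates on a single gyroscope channel per shin: the angular
velocity around the sensor's x axis, which lies in the frontal plane when
the subject stands, so ω<sub>x</sub> captures the principal sagittal shank
rotation. Sampling is 60 Hz throughout (configurable; all window lengths are
specified in seconds and converted at run time).

Normalization is the affine map ω′ = (ω − mean ω)/(max ω − min ω), computed
once per trial and per leg over the full trace, including the sitting and
stand-up prefix. Computing the statistics over the full trace is the only
scope that lets segmentation thresholds be subject-independent; a
configuration flag allows normalizing after prefix removal instead, but all
shipped defaults and tests use the full trace. A constant trace has no
defined normalization and raises an error rather than producing NaN.

Two-device synchronization uses the sit-to-stand transient: the global
maximum of |ω′| within the first 10 s of each recording. The later-starting
device's trace is shifted so the two transients coincide; the estimated
delay is the peak-index difference in seconds. A recording is rejected as
"no stand-up present" when its early-window maximum does not exceed 1.3×
the largest |amplitude| in the remainder of the trace. We chose this
dominance test over a median-amplitude multiple because a smooth gait trace
has a high median |amplitude|: the ratio of the stand-up peak to the median
(~5) is indistinguishable from the same ratio in pure noise (~4.9), whereas
the stand-up transient — twice the largest swing by construction — cleanly
dominates the remainder. Samples up to 3.5 s after the stand-up peak are
flagged non-gait (the subject is still settling) and excluded from step
detection.

## Segmentation

Mid-swing is the instant of maximal shank angular velocity, so peaks of ω′
anchor steps. A candidate is a strict local maximum (plateaus contribute
their first sample); candidates are kept when their height is ≥ 20% of the
largest candidate of the same leg in the same trial and they are ≥ 350 ms
apart. Separation is enforced greedily by descending height with ties to
the earlier peak — deterministic and duplicate-free. Peak positions snap to
the sample grid, so recovered peak times are exact to half a sample period
(±8.3 ms at 60 Hz) and stride intervals to one sample.

Each peak with a same-leg predecessor yields a step with two slices: Type I
runs from the previous peak (exclusive) to the current peak (inclusive), so
consecutive Type I slices tile the inter-peak region with no gap or
overlap; Type II is the positive lobe containing the peak, found by walking
outward to the nearest zero crossings and including one boundary sample on
each side. Akinetic freeze intervals produce no peaks above threshold and
therefore no steps; trembling intervals do produce peaks (the oscillation
exceeds the 20% threshold), which become FOG-class steps for the detection
task.

## Features

Sixteen features per step; conventions that are not forced by the
definitions:

- **Angular jerk** ½∫ω̈² dt: ω̈ by central second differences scaled by the
  squared sampling rate, integral by trapezoid; normalized jerk divides by
  the slice duration (the literal "normalized by time" reading — the
  dimensionless-jerk alternative with duration⁵/amplitude² scaling is not
  used).
- **Stride similarity**: dynamic time warping with absolute-difference local
  cost and the standard match/insert/delete step pattern, no window
  constraint, operands unresampled (DTW absorbs length mismatch). The DP is
  implemented in-package (~30 lines); tests check it against an independent
  recursive oracle.
- **Spectra**: mean-removed Type I slice, rectangular window, zero-padded to
  512 points, one-sided squared magnitude normalized to unit sum. At 60 Hz a
  ~1 s stride gives Δf ≈ 0.12 Hz, enough to localize the principal harmonic.
- **Spectral entropy** −Σ P ln(P + ε), ε = 0.001, natural log (any base is a
  monotone rescaling absorbed by the classifiers). The DC bin is ≈ 0 after
  mean removal and contributes nothing.
- **Half-power widths**: amplitude/√2 threshold for the time-domain swing
  lobe (an amplitude quantity), power/2 for the spectral line (already a
  power quantity); crossings are linearly interpolated.
- **Step time** is the current peak minus the previous contralateral peak;
  **stride time** the previous same-leg peak. Both are computed from peak
  times — the only computable definition for a peak-anchored segmentation.
- **Missing data**: steps lacking a previous same-leg stride or a previous
  contralateral peak (the first one or two steps of each leg per trial) are
  dropped, not imputed. The resulting feature matrix contains no undefined
  values.

## Labeling

Class membership is decided by the anchor peak time alone, so a segment
straddling an episode boundary has exactly one label. Pre-FOG windows never
override FOG membership, which implicitly truncates a window that reaches
back into a preceding episode. For the prediction task, episodes flagged as
occurring during gait initiation define no pre-FOG window (no steady gait
precedes them), but their FOG steps remain FOG and are dropped with the
rest; the detection task uses every episode. Steps that would be pre-FOG
count as gait in the detection task (two classes only; configurable).

## Models

- **Feature ranking**: Gini decision tree, minimum leaf size 1, at most 15
  splits (`max_leaf_nodes = 16`). Features are ordered by the shallowest
  depth at which they first split, ties broken by total impurity decrease,
  then original column order; unused features follow in column order.
- **Wrapper tuning**: exhaustive grid over f ∈ 1..16 top-ranked features ×
  SVM cost c ∈ 1..20, scored by stratified 10-fold CV misclassification
  error; arg-min ties prefer fewer features, then smaller cost. Linear SVMs
  use the liblinear primal squared-hinge solver (an order of magnitude
  faster than libsvm here with equivalent boundaries); kernel SVMs use
  libsvm with `max_iter = 20000` — extreme corners of the admissible
  (kernel scale, box constraint) ranges otherwise iterate near-indefinitely
  during random search, and capped fits simply score poorly and are not
  selected.
- **Families and hyperparameter ranges**: SVM (linear/quadratic/gaussian,
  kernel scale 0.001–100 mapped to γ = scale⁻², box constraint 0.01–100),
  kNN (k 1–50, euclidean/manhattan, equal/inverse/squared-inverse weights),
  LDA (shrinkage γ 0.01–1 and a coefficient-elimination threshold δ
  0.01–100, realized as a post-fit soft-threshold zeroing small
  coefficients), logistic regression (L2 strength λ 0.01–100). Scale-like
  parameters are sampled log-uniformly by a seeded random search with a
  default budget of 30 evaluations per (window, family) cell — a budgeted
  seeded stand-in for Bayesian optimization with the same contract.
- **Cost-sensitive training**: the false-negative cost is a class-weight
  multiplier on the positive class (priors scaling for LDA, posterior
  thresholding for kNN, which has no training weights). Cost 1 is neutral by
  construction; the sweep covers 1–10 and the chosen cost maximizes CV
  sensitivity subject to the F-score staying within 5 points of the
  unweighted model.
- **Protocols**: stratified k-fold, repeated stratified 70/30 splits
  (splits drawn per repetition from a spawned seed stream, not
  subject-grouped — subject independence is LOSO's job), and LOSO. Ranking,
  wrapper tuning and cost tuning always see training rows only; every
  protocol asserts row/subject/condition disjointness at run time and
  records the audit in its report. All protocols are pure functions of
  (data, configuration, seed).
- **Aggregation**: per-fold metrics are averaged NaN-skipping (small LOSO
  folds can lack a class; undefined metrics are flagged, never coerced to 0
  or 100); pooled metrics over all held-out predictions are also reported
  and are what the acceptance summary quotes.

## Evaluation

Confusion metrics are exact formula evaluations in percent. ROC curves
sweep unique score thresholds (ties collapse) with trapezoidal AUC, which
equals the normalized Mann–Whitney U on tie-free data. Spearman
correlations use average ranks and the large-sample t approximation;
negative ρ means the feature decreases on steps approaching a freeze.
Detection latency counts the consecutive run of pre-FOG predictions
immediately preceding each onset (strictest reading); a looser
first-positive-onwards variant is available behind a flag. Episodes with no
pre-onset steps are excluded from latency aggregates but counted in a
coverage report.

## Synthetic cohort

The generator emulates the structure the analysis depends on, not
biomechanics. Per leg it places raised-cosine swing lobes at the subject's
cadence (0.85–1.15 Hz across subjects) with an inter-swing negative trough;
lobe width defaults to ~0.68 of the stride cycle because the shank rotation
this sensor records is smooth and near-sinusoidal — this keeps ≥ 80% of a
steady stride's spectral power below 2 Hz, the premise behind the low-power
frequency feature (a narrow 0.35 s pulse would leak half its power above
2 Hz). A biphasic stand-up pulse of twice the swing amplitude precedes
walking; the right device starts recording 0.1–1 s late so synchronization
is non-trivial. Episodes are trembling (4–7 Hz oscillation at ~25% swing
amplitude) or akinetic (noise only), non-overlapping, ~3 per 50 s trial.

Pre-freeze degradation ramps linearly over a 2 s window before each onset
(quadratic optionally): at onset the swing amplitude is multiplied by 0.5,
the step period and swing duration by 0.7, and a 6 Hz component carrying a
0.3 power fraction is superimposed — a moderate, plausible motor breakdown;
these effect sizes are free simulator parameters, not claims about
Parkinsonian physiology. The off-therapy state scales the degradation depth
by 1.5 (levodopa partially corrects the pre-freeze pattern, so its
withdrawal deepens it). White noise (σ = 0.03 of nominal swing amplitude)
is added throughout; all draws flow from one seeded generator per call and
identical seeds give bit-identical trials.

Problem sizes: the study-scale benchmark is 10 subjects × 2 trials (one per
therapy state) of 50 s each, ≈ 1 500 analyzable steps of which ≈ 250 are
pre-FOG at the 2 s window; segmentation-recovery checks use a 4-subject
noise-free cohort; the window-length comparison contrasts 2 s vs 5 s.

**What passing tests show — and do not.** The benchmark demonstrates that
the pipeline recovers a planted, subject-consistent degradation signature
without information leakage, that its protocols, tie-breaks and metrics
behave as specified, and that the window/cost/ensemble machinery responds
in the expected directions. It does not demonstrate clinical performance:
real pre-freeze dynamics are heterogeneous across patients and episodes,
degradation need not be monotone or confined to a fixed window, annotation
boundaries are uncertain, and real signals contain turning, hesitation and
artifacts the simulator omits. Synthetic accuracies are accordingly higher
than anything expected on patient data.

## Known limitations

- Akinetic intervals yield no steps, so purely akinetic freezes are
  invisible to the detection task's step-level classifier.
- The LDA δ threshold acts on standardized coefficients after fitting; it
  reproduces predictor elimination but not a jointly regularized fit.
- The latency statistic assumes annotated onsets are exact; a systematic
  annotation lag shifts it directly.
- The CLI's `run` command aborts per stage on malformed cohorts; partial
  results are not resumed.
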