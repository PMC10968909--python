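# Methods

## Scope and model

`plistack` implements a window-level functional-connectivity classification
pipeline for three-group (HC / GAD / DD) resting-state EEG. The unit of
classification is a non-overlapping time window, not a subject: each
window contributes one 480-dimensional Phase Lag Index (PLI) feature
vector, and all metrics are window-level unless a subject-grouped split is
requested explicitly (see *Cross-validation* below).

## Synthetic cohort generator

Real clinical recordings for this problem are not publicly available, so
the generator is a first-class component that emulates their relevant
structure:

- **Montage / acquisition** — 16 channels of the 10–20 system (Fp1…O2),
  250 Hz, default 600 s per subject, amplitudes in µV.
- **Background activity** — per channel and rhythm band, an independent
  band-limited Gaussian process (4th-order Butterworth-filtered white
  noise), with eyes-closed-like default amplitudes (alpha dominant, beta
  weakest: theta 4, alpha1 6, alpha2 5, beta 3 µV), plus per-channel
  1/f-shaped (pink) broadband noise (`noise_sd`, default 2 µV).
- **Planted coupling** — a `CouplingEdge(channel_a, channel_b, band, lag,
  strength, jitter_sd)` injects one *shared* oscillator into two channels.
  The shared oscillator is a bounded-envelope narrowband random-FM
  process: its instantaneous frequency wanders slowly inside the band
  around the band center (low-pass-filtered Gaussian frequency noise,
  deviation width/6), and its envelope is modulated but clipped away from
  zero. Channel B receives the analytic signal rotated by
  `exp(i(jitter(t) − lag))`, i.e. a constant phase lag plus slowly varying
  Gaussian phase jitter (marginal sd `jitter_sd`, 0.5 Hz bandwidth).
  `strength` mixes the shared oscillator against the channel's independent
  band background with power normalization (weight √(1−Σstrength²)).

  A filtered-Gaussian shared oscillator was rejected for this role: its
  Rayleigh envelope fades to zero, where windowed analytic-signal phase
  estimates break down, so a planted lag would not survive extraction
  exactly. With the bounded-envelope FM process, a jitter-free edge of any
  lag ∉ {0, π} yields PLI exactly 1 on trimmed windows, and mean PLI under
  jitter matches a direct Monte-Carlo simulation of sign(wrap(lag − j)),
  j ~ N(0, jitter_sd²), to within sampling error. Note the wrapping: for
  lags near π a heavy jitter tail wraps past π and flips sign, so measured
  PLI falls below the naive un-wrapped prediction — the simulation oracle
  must wrap too.
- **Group templates** — HC carries a baseline edge set (occipital/parietal
  alpha, frontal theta, weak frontal/central beta). GAD strengthens
  frontal beta (F3–F4 to 0.8) and adds frontal beta edges (Fp1–F7,
  Fp2–F8), weakening occipital alpha1; DD adds distinct frontal beta edges
  (Fp1–F3, F7–F8) and weakens parietal alpha2.
  Group sizes default to 38/45/42. Effect sizes are qualitative choices
  (no quantitative group effect sizes exist to copy); they are strong
  enough that desk-scale cohorts are learnable but far from trivially
  separable at the window level.

**What the generator does not emulate:** ocular/muscle artifacts, volume
conduction (zero-lag cross-channel leakage), inter-subject variability in
spectral peaks, nonstationarity across the recording, electrode noise
correlations. Passing tests on synthetic cohorts therefore demonstrate
correctness of the computational pipeline and recoverability of planted
structure — not clinical-grade performance on real EEG.

## Preprocessing

Fixed stage order: band-pass 4–30 Hz → baseline correction → down-sample
to 125 Hz → segment into non-overlapping windows → per-window rhythm-band
extraction. All filters are 4th-order Butterworth applied
forward–backward (`sosfiltfilt`), hence zero-phase — mandatory here, since
any filter-induced phase shift would masquerade as connectivity lag.
Baseline correction is linear detrend + mean removal (deterministic;
the drift-correction method is otherwise unconstrained). Down-sampling
uses `scipy.signal.decimate` (zero-phase anti-alias). A trailing window
remainder is dropped. An artifact-removal hook (identity by default) marks
where an ICA-based cleaner would sit for real data; synthetic data is
artifact-free and manual artifact rejection is irreproducible, so no ICA
is reimplemented.

A zero-phase 4th-order band-pass is −6 dB at its corners, so ~3% of
broadband white-noise power survives just outside the nominal band edges;
the tests assert the spectrally integrated behavior of this actual filter
(stopband far from the corners < 0.5%).

## PLI

The analytic signal is computed per window without padding (windows are
≥ 250 samples; edge effects are confined to the window ends). Phase
differences are taken as arg(Z₁Z₂*) and wrapped to (−π, π]; sign(0)
contributes 0, so self-PLI is 0 and exact zero-lag coupling is discounted.
The vectorized matrix builder uses sign(Im(Z₁Z₂*)), identical to the
sign of the wrapped angle except on the measure-zero boundary. An optional
`edge_trim` fraction (default 0) drops samples at each window end before
averaging; the first/last sample of a finite window is systematically
unreliable, and trimming ≥ 1 sample recovers planted lags exactly.
The absolute-value form |⟨sign Δφ⟩| is used throughout (the only reading
under which larger values mean stronger phase synchronization); the signed
mean is exposed as `pli_signed` for diagnostics.

Feature ordering is band-major (theta, alpha1, alpha2, beta), pairs
upper-triangle row-major by montage index — an artifact convention,
documented and stable, with `decode_feature` as its exact inverse.

## Models and tuning

Base learners: LightGBM, XGBoost, and sklearn's
`GradientBoostingClassifier` ("gboost") as the third gradient-boosting
family, configured with `max_features="sqrt"` (random feature subspacing,
which also keeps 480-feature fits tractable). All are single-threaded and
fully seeded; LightGBM runs with `deterministic=True`.

Search spaces: LightGBM `num_leaves` ∈ int[16,96], `min_data_in_leaf` ∈
int[2,60], `feature_fraction` ∈ [0.75,1], lr ∈ log[5e-3,0.1]; XGBoost
depth ∈ int[3,10], `min_child_weight` ∈ int[1,5], `colsample_bytree` ∈
[0.5,1], lr ∈ log[5e-3,0.1]; gboost depth ∈ int[5,8], `min_samples_leaf` ∈
int[1,5], lr ∈ log[5e-3,0.1]. The tuner is an in-package
tree-structured-Parzen-style sequential optimizer (10 random startup
trials, then per-dimension good/bad Gaussian KDEs at the 25% quantile,
candidates drawn from the good density and scored by density ratio),
maximizing F1-macro on a stratified 10% validation split; 30 trials by
default. It is deterministic given the seed.

Stacking is exactly two layers. A stratified 10% validation split is
carved off first (early stopping with 50-round patience where the library
supports an eval set; gboost uses its internal validation fraction,
enabled only when the training portion can afford it). Layer-1 models
produce out-of-fold probabilities via internal 5-fold stratified
splitting — layer-2 models never see layer-1 predictions made on data
those bases were fitted on. Layer-2 inputs are [raw features ⊕ 3×3
out-of-fold probabilities]. Final aggregation weights come from greedy
forward ensemble selection with replacement (15 rounds) on the validation
split, so they are convex by construction. Out-of-fold (rather than
refit-on-full) layer-1 predictions are the leakage-safe choice where the
original procedure is silent.

A fitted `StackedEnsemble` persists via `save`/`load`: each model in its
library's native format (LightGBM booster text, XGBoost JSON, joblib for
the sklearn learner) plus a JSON manifest of classes, weights and feature
width; a reloaded ensemble reproduces the original probabilities exactly.

## Feature selection

Ranking: per model family, p repeats of stratified k-fold (study scale
p=100, k=5); per (repeat, fold), the model trains on k−1 folds (minus the
10% validation split) and emits the descending permutation of its native
gain importances, normalized to sum 1, ties broken by ascending feature
id. The three matrices concatenate to a (3·p·k) × 480 index with
(model, repeat, fold) provenance per row.

Subset construction for size n counts, per feature, its appearances within
the first n columns over all rows and keeps the n most frequent; ties
break by better mean rank position, then ascending id. Note subsets are
not necessarily nested across n (counts depend on n). The frequency
reading (count over top-n columns of all rows) is implemented; a
rank-weighted variant would be a natural alternative but is not.

Subset evaluation uses repeated stratified k-fold (study scale p=5, k=5)
of the stacked ensemble; the best subset maximizes mean ensemble accuracy,
ties to the smaller n. The candidate grid defaults to every n ∈ [1, 480]
with an optional stride as the practical escape hatch; hyperparameters are
tuned once per configuration, not re-tuned inside every subset evaluation.

## Cross-validation and leakage

Splits are stratified by class (three unbalanced groups); class imbalance
is otherwise left alone (no reweighting). By default, folds are drawn at
the *window* level, so windows of one subject can appear in both train and
test folds — this matches the original experimental design but inflates
absolute accuracies through within-subject correlation. A subject-grouped
mode (`sklearn.model_selection.GroupKFold` on `subject_id` over the
feature table's metadata columns) is the leakage-safe alternative for any
claim about generalization to new subjects.

## Metrics

Accuracy, F1-macro (per-class F1 averaged unweighted; a class with no true
and no predicted positives contributes 0), Gmean-macro
(mean of √(precisionᵢ·recallᵢ)), and kappa in two variants: Cohen
(Pe from marginal products — the default) and a "printed" variant with
Pe = accuracy². The printed variant is non-standard; note that under
*either* variant kappa ≤ accuracy whenever accuracy < 1 (for Cohen this is
an algebraic identity, proven in a property test), so reported kappa
values exceeding accuracy cannot arise from these formulas — the package
flags this rather than silently "fixing" it. Model comparison: one-way
ANOVA across the four models' repeat-level metric samples, then Tukey-HSD
contrasts against the ensemble with 0.05/0.01/0.001 star tiers.

## Network report

Selected feature ids decode to (rhythm, channel pair) edges; counts per
rhythm partition the subset. Region strength averages each selected
edge's group-mean PLI into the regions of both endpoints (once, if both
endpoints share a region): frontal {Fp1,Fp2,F3,F4,F7,F8}, central
{C3,C4}, temporal {T3,T4,T5,T6}, parietal {P3,P4}, occipital {O1,O2} —
a declared default (the exact clinical montage is unspecified), fully
configurable via a JSON region map. Regions without a contributing edge
are reported as absent, not zero. Region means are convex combinations of
edge means.

## Numerical and degenerate-input choices

- sign(0) → 0; an all-zero channel has undefined phase: flagged with a
  warning, PLI set to 0 for its pairs.
- Probability ties in prediction break to the lowest class index
  (np.argmax); class labels sort alphabetically (DD, GAD, HC).
- Validation splits are at least one sample per class even when 10% of a
  tiny fold would be smaller.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; per-subject streams are keyed on
  (seed, group, subject index) so any subject is regenerable in isolation.

## Problem sizes in tests and the acceptance script

The package defaults mirror the study scale (600 s recordings, 38/45/42
subjects, windows 2–16 s, p=100/k=5 ranking, p=5/k=5 evaluation, 30 tuning
trials). The test suite and `scripts/acceptance.py` run the same code at
desk scale as the package's own verification conditions: 6–10 subjects
per group, 60–120 s recordings, p=2/k=3 ranking, p=1/k=3 evaluation,
5 tuning trials, 40–60 boosting rounds, candidate-size grids of 2–4
points. These sizes keep every planted effect recoverable while the whole
suite runs on one CPU.

## Known limitations

- Window-level CV (the default, matching the original design) overstates
  subject-level generalization; use the grouped mode for that question.
- The generator's group differences are qualitative mimics; absolute
  accuracies on synthetic cohorts are not comparable to clinical results.
- PLI is blind to zero-lag coupling by design; a true zero-lag
  interaction would be invisible to the whole pipeline.
- The "printed" kappa variant is provided for comparability only and is
  not a recommended statistic.
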