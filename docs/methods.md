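# Methods

This note documents the models and procedures implemented in `gaitdnd`,
the parameter defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the package's numerical and
design choices.

## Signal model and preprocessing

A walking VGRF trace per foot alternates between a loaded state (stance)
and a near-zero unloaded state (swing); turn-backs at the ends of a
walking hallway inject brief force spikes. Conditioning follows the
standard recipe for continuous hallway walks:

- **Edge trim** — 15 s (default `trim_s`) removed from each end, where
  gait initiation/termination artifacts live.
- **Despiking** — running median, kernel 5 samples (default
  `median_kernel`; ≈17 ms at 300 Hz). This is the smallest odd kernel that
  removes 1–2-sample sensor glitches without flattening stance peaks; the
  edge windows shrink instead of padding, so output length equals input
  length and kernel 1 is the identity. No kernel value is prescribed by
  the underlying method description; 5 is this package's documented
  default.
- **Windowing** — non-overlapping 30-s windows (default `window_s`),
  trailing remainder discarded; each window is an independent sample.
- **Window rejection** — visual screening of noisy windows is not
  reproducible, so the package substitutes a thresholded rule: a window is
  dropped when more than `max_spike_fraction` (default 0.05) of its
  samples on either foot exceed 3× the window's upper state level, or
  when its id appears on an explicit exclude list. The upper state level
  used here is estimated with the top `2 × max_spike_fraction` amplitude
  quantile excluded (capped at the top half), because a long saturated
  artifact would otherwise become the upper histogram mode and inflate
  its own rejection threshold.

## Bilevel state-level estimation and event detection

Per window and foot, the amplitude histogram uses range
`A_R = A_max − A_min`, Scott's normal-reference bin width
`3.49 σ̂ n^{−1/3}` (σ̂ the sample standard deviation), and
`M = ⌈A_R / width⌉ ≥ 2` equal bins. Rounding up keeps the bins covering
the full range. The occupied bin range `[i_low, i_high]` is split at the
midpoint index `i_low + ⌊(i_high − i_low)/2⌋` (midpoint bin assigned to
the lower part); each state level is the center of the most populated bin
of its sub-histogram, with ties broken toward the lowest index so the
estimate is deterministic. Constant signals, or signals collapsing into a
single occupied bin, have no bilevel structure and are rejected.

Events are crossings of the reference level `S_L + 0.10 (S_U − S_L)`:
upward = heel strike, downward = toe-off. Crossing times are refined by
linear interpolation between the straddling samples, giving duration
resolution finer than the 1/300-s sampling grid. Two debounce rules
stabilize the sequence against noise chatter around the reference:

- an opposite-kind candidate closer than `min_phase_s` (default 0.1 s,
  shorter than any physiological stance or swing at normal pace) to the
  last accepted event is discarded;
- a same-kind candidate *supersedes* the previous one — chatter emits
  runs of same-direction crossings, and the last crossing before the
  state actually switches is the genuine event.

The sequence is trimmed to start at a heel strike. Stance, swing and
stride derive from the alternating events; `stride = stance + swing` is
an arithmetic identity of that construction. State levels are estimated
per 30-s window, not per record, consistent with windows being
independent samples.

## Feature descriptors

Per channel: RMS, variance, skewness, kurtosis. The moment conventions
are deliberate and slightly unusual: variance uses the unbiased 1/(N−1)
divisor, while skewness and kurtosis put 1/N central moments over powers
of that *sample* variance,

    Sk = (1/N) Σ (x−μ)³ / Var^{3/2},   Ku = (1/N) Σ (x−μ)⁴ / Var²,

kurtosis in non-excess form (Gaussian → 3). Library defaults
(`scipy.stats.skew/kurtosis`) normalize by the 1/N variance instead and
would silently differ by O(1/N) factors, so the composition is
implemented directly. A duration series needs at least 4 cycles for the
full descriptor set (kurtosis precondition); shorter series drop the
window for that signal family only, with a log entry. The 8-vector is
channel-major (left block, right block); tree learners are insensitive to
within-vector ordering, so this choice is cosmetic but fixed.

## Group statistics

Feature-wise comparisons use tie-corrected Kruskal–Wallis H (chi-square
reference, k−1 df) on balanced per-class subsamples (default: the
smallest class size; the interface also accepts an explicit n, e.g. 130).
Pairwise post-hoc comparisons are Dunn z-tests on pooled mid-ranks with
the tie term `Σ(t³−t)/(12(N−1))`, adjusted with the Šidák family-wise
correction `p_adj = 1 − (1−p)^m` over the m = 6 pairs. Dunn's test was
chosen as the pairwise statistic because it is the standard post-hoc
companion of Kruskal–Wallis; the alternative (Šidák over pairwise
Mann–Whitney) is not implemented. A one-sample Kolmogorov–Smirnov screen
against a fitted normal is available for reporting; it never gates the
pipeline. Because parameters are estimated from the data, that screen is
conservative (the Lilliefors situation) — it is informational only.

## Classifiers

- **CART** — Gini impurity, greedy best-first growth, thresholds at
  midpoints of sorted feature values, capped at `max_splits` internal
  nodes and `min_leaf_size` samples per leaf. Backed by
  `sklearn.tree.DecisionTreeClassifier` with
  `max_leaf_nodes = max_splits + 1`, with a pinned `random_state` so
  feature-tie permutation cannot break run reproducibility.
- **Bagging** — trees on bootstrap resamples of size n, unweighted
  probability averaging.
- **AdaBoost.M1** (binary) — learner weight `α_t = ½ ln((1−ε_t)/ε_t)`
  shrunk by the learning rate; a perfect round gets a capped finite α
  (ε clipped at 1e−12, α ≤ 12); a round with ε ≥ ½ is discarded and
  weights reset to uniform (logged). Multiclass boosting is deliberately
  *not* SAMME: each boosted learner is a strictly binary machine inside
  the one-vs-all scheme.
- **RUSBoost** — AdaBoost.M1 where each round first randomly undersamples
  the majority class down to the minority count (weights renormalized on
  the resample, updates computed on the full set). This targets the ≈1:3
  positive:rest imbalance of one-vs-all subproblems; the other learners
  are left unweighted, matching the framework's plain binary
  realizations.
- **Random subspace** — trees on random feature subsets of size
  `round(fraction × p)`; the published parameter table lists a "learning
  rate" for this method, which has no learning rate — it is interpreted
  here as the subspace sampling fraction (0.5 → 4 of 8 features).

**ECOC one-vs-all** trains one binary learner per class; prediction is
argmax of positive-class scores with ties resolved toward the lowest
index in the fixed order CON, ALS, PD, HD.

**Cross-validation** uses equi-stratified folds: per-class seeded
shuffle, then round-robin assignment with a running offset, giving fold
sizes equal ±1 and per-fold class proportions within one sample of the
overall proportions. Reported numbers are per-fold macro metrics averaged
over folds. Base trees inside ensembles default to `max_splits = 20`,
`min_leaf_size = 1` (the published table specifies tree caps only for the
standalone CART).

**Hyperparameter tuning** is a budgeted, seeded random search (a
documented fallback for sequential model-based optimization) over
min_leaf_size 1–50, max_splits 1–100, n_cycles 10–500, learning_rate
0.1–1.0, subspace_fraction 0.25–1.0, minimizing 5-fold CV
misclassification on a stratified 10% subset. The published parameter
table is available verbatim as the `paper_params` presets. The tuning
subset is not excluded from the final cross-validation — this mirrors the
original evaluation protocol and implies mild optimism; budget-capped
ensemble sizes (`cycle_cap`) bound tuning runtime.

**Metrics.** Binary one-vs-rest accuracy, sensitivity, specificity, F1
and Cohen's κ with `P_e = [(TP+FP)(TP+FN)+(TN+FN)(TN+FP)]/N²`; 0/0 ratios
fall back to 0 with a log entry. The overall summary is the unweighted
macro mean over the four one-vs-rest views — the aggregation under which
overall accuracy can sit far above overall sensitivity when classes are
imbalanced (each class view contributes many true negatives). A
micro-averaged variant is provided for comparison. Percentages are on the
0–100 scale; κ is a coefficient in [−1, 1] at the API level and scaled to
percent in reports.

## Synthetic cohorts

`simulate_record` builds each foot's trace cycle by cycle: stride
durations are independent Gaussians (an optional AR(1) knob exists,
default off), stance occupies a per-cycle fraction of the stride, and the
stance burst is an M-shaped profile — raised-cosine attack and release
ramps over 4% of the stance multiplied by a cosine core with two peaks
and a mid-stance valley, C0-continuous and zero at the burst edges.
Amplitude is `peak_force` with multiplicative jitter; Gaussian sensor
noise and Poisson-placed rectangular spikes (3.5× peak, default 5 ms,
configurable up to turn-back-like 0.2 s) are added. The right foot
repeats the left cycle train phase-shifted by half a stride with
independent jitter and noise. Ground-truth heel-strike/toe-off times are
the analytic instants where the noiseless burst crosses 10% of that
cycle's amplitude — the same convention the detector applies — so with
zero noise detection matches truth within a sample, and truth-derived
durations satisfy stride = stance + swing exactly.

Condition presets encode the published group profile qualitatively:
control walks fastest and most regularly (stride 1.05 ± 0.02 s, stance
fraction 0.62), PD slowest (1.30 ± 0.10 s, 0.68), ALS and HD intermediate
(1.25 ± 0.08 s / 1.12 ± 0.06 s) with elevated stride variability and
amplitude jitter; peak forces roughly track group body weight. The
presets reproduce the speed ordering CON > HD > ALS > PD and
disease-elevated variability; they are *not* clinically calibrated VGRF
morphology. In particular the simulated classes differ in scale and
timing simultaneously, which makes the duration-series features more
discriminative than they are on real recordings — passing tests
demonstrate the machinery recovers constructed truth and separates
separable classes, not clinical effect sizes. Real-data phenomena not
emulated: sensor drift, asymmetric left/right pathology, fatigue trends
within a walk, double-support structure, and the 8-sensor layout summed
per foot.

`gaussian_feature_cohort` bypasses the waveform stage entirely: four
unit-variance Gaussian clusters in feature space with mean separation
1.9, the overlap at which a single CART's cross-validated macro accuracy
sits near 85% — the regime used to demonstrate the ensemble-over-base
advantage with headroom on both sides.

## Problem sizes and numerical choices

Validation and the acceptance script run on scaled-down cohorts chosen as
reasonable desk-scale defaults: 10 simulated records per class at 5 min
(→ 80 windows per class), 60 learning cycles for the benchmark ensembles
(the published table's largest value is 485), 100 seeds × 3-fold CV at 20
cycles for the ensemble-vs-base comparison, 100 windows for event
recovery, and 1000 replicates for the family-wise-error calibration. All
randomness flows from one master seed through `numpy` seed sequences;
per-stage and per-fold seeds are derived, never reused, so pipeline runs
are reproducible byte for byte (reports carry no timestamps; the run log
does and is excluded from comparisons).

Degenerate inputs are contracts, not crashes: constant signals are
rejected by the bilevel estimator, windows without events yield empty
sequences plus warnings, single-class training data yields a trivial
one-leaf tree with a warning, and 0/0 metric ratios fall back to 0 with a
log entry.

## Known limitations

- The window-rejection rule is a reproducible surrogate, not a
  reconstruction of visual screening; on real data an explicit exclude
  list may still be needed.
- Real-archive headline numbers depend on an external accession and a
  manual screening step and are not reproduced here; on the simulator the
  duration-signal classifiers perform closer to the VGRF classifier than
  they do on real recordings (see above).
- The WFDB reader supports the header + format-16 subset sufficient for
  two-channel gait records, not the full format family.
- Bayesian optimization is replaced by budgeted seeded random search; with
  small budgets the selected parameters are coarse.
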