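# Methods

This package re-implements, over synthetic data, a target-detection analysis
for rapid serial visual presentation (RSVP) EEG under five graded
weak-contrast stimulus conditions. This note records the models, the
parameter choices that matter, and the places where the design was genuinely
open.

## Paradigm and design

A trial shows a fixation plus for 1 s, a 0.5 s gap, then the ten digits 0–9
for 200 ms each with no inter-stimulus interval; exactly one digit is the
pre-instructed target. A session interleaves 150 trials, 30 per contrast
condition, in random order; the full design is 10 sessions per subject,
giving 300 target and 2700 non-target stimulus epochs per condition. The
five conditions C1–C5 are equal-RGB gray levels 255/127/63/31/15 on black;
the contrast ratio of a condition is its gray value over 255 (1, 0.498,
0.247, 0.122, 0.059). The inter-trial interval is not part of the stimulus
stream; it defaults to 1 s and is configurable (the noiseless recovery tests
raise it to 4 s, see *Numerical choices*).

## Synthetic EEG generator

The generator emulates a 62-channel 10-10 recording at 1000 Hz.

**Signal.** Each target stimulus adds a P300: a positive Hann-shaped lobe
(`cos²` bump, half-width 250 ms, so ~500 ms support) peaking at the
condition's latency, scaled across the scalp by a parietal-maximal Gaussian
topography centered on Pz (spatial scale 0.07 m). Non-target stimuli add
nothing. Two smaller target-locked subcomponents distribute signal beyond
the parietal focus, qualitatively mirroring where selection concentrates on
real data: an occipital lobe (focus Oz, 3 μV, 350 ms) scaling with the
contrast ratio — the conspicuous benchmark drives visual re-processing —
and a right-temporal lobe (focus T8, 2.5 μV, 450 ms) scaling with 1 −
ratio, i.e. with recognition effort under weak contrast. Both can be
disabled (`secondary=()`).

**Calibration.** Injected P300 parameters per condition are the cohort
grand averages: amplitudes 8.92/8.55/8.51/8.72/7.84 μV and latencies
582/572/576/595/644 ms for C1..C5, with standard errors (over 18 subjects)
of ~1.2–1.4 μV and ~21–26 ms. Three variability scales derive from them:

- *between subjects*: condition means are offset per subject by
  N(0, SE·√18) — the spread those SEs measure;
- *between trials, amplitude*: N(0, SE·√18), truncated at 0 (a generator
  choice: single-trial ERP amplitude scatter is of the order of the
  between-subject spread);
- *between trials, latency*: N(0, 40 ms). Single-trial P300 latency jitter
  within a subject is far smaller than the between-subject spread; a
  between-subject-sized per-trial jitter (~106 ms) would smear the
  300-trial average peak by ~28% and make the calibration unrecoverable,
  so the two scales are kept distinct.

**Measurement-gain compensation.** Published P300 amplitudes are measured
*after* band-pass filtering, and a 0.3 Hz zero-phase high-pass alone
removes ~15% of the peak of a monophasic half-second lobe (nearly
independent of filter order); latency jitter smears another ~6% off the
grand average. The generator therefore scales injected amplitudes up by the
deterministic attenuation of the destination chain — the filtered-template
peak ratio times the jitter-convolution peak ratio — so that the measured
grand average reproduces the calibration table. Both factors are computed,
not fitted, and the compensation can be disabled (`calibrate_to_band=None`).

**Noise.** Background activity is 1/f^α noise (α = 1 by default, the
textbook EEG spectral slope), RMS 15 μV per channel — a typical ongoing-EEG
amplitude below 20 Hz. Channels are mixed by a distance kernel
(exp(−d²/2λ²), λ = 5 cm, Cholesky-normalized to unit channel variance) to
mimic volume conduction. What the noise model does *not* contain: alpha
peaks, eye blinks, muscle artifacts, electrode drift, non-stationarity.
Passing tests therefore show that the estimators recover what was planted
under realistic amplitude ratios — not that they are robust to real-world
artifacts.

## Preprocessing

Continuous recordings are band-pass filtered 0.3–20 Hz per channel with a
4th-order Butterworth applied forward–backward (zero phase — the latency
statistic depends on it), then cut into epochs from stimulus onset to
1000 ms, then decimated by 8 to 125 Hz (plain sample picking; the 20 Hz
cutoff sits far below the 62.5 Hz post-decimation Nyquist, so no second
anti-alias stage). Filtering happens on continuous data before epoching to
avoid edge transients inside the 1 s windows. No baseline correction and no
artifact rejection are applied.

## P300 statistics

The P300 is quantified on the across-epoch target average at one channel:
amplitude = maximum of the average waveform in 200–900 ms (endpoints
inclusive), latency = time of that maximum, ties to the earliest sample. A
per-epoch mode (average of single-epoch maxima) exists for sensitivity
analyses. Condition contrasts against the C1 benchmark use two-sided paired
t-tests across subjects, reported uncorrected (four planned contrasts) with
the usual star codes. The measurement channel is an argument everywhere; the
analysis drivers use the simulator's topography peak (Pz). For external
recordings the conventional frontal-central site (the signature default,
Fz) may be more appropriate — the choice is the user's.

## Channel selection

Six channel sets are compared: (1) all 62; (2) a standard 32-channel cap;
(3) a 16-channel set; (4) the 8 midline electrodes; (5) a classic 8-channel
ERP set; (6) six channels selected per subject and condition by sequential
floating forward selection (SFFS). The subset objective is a Fisher
separability score: epoch features (channels × 125 samples, concatenated)
are compressed by PCA to the smallest dimension P covering >99% of
variance — recomputed inside every candidate evaluation — and the score is
trace(S_w⁻¹ S_b) on the compressed features, S_w diagonal-loaded by
10⁻⁶ × its mean diagonal.

Because P varies between candidate subsets, the raw score (a scaled
Hotelling T²) inflates by ≈ P/n and would reward channels that merely add
independent-noise dimensions. SFFS therefore maximizes the standard
small-sample bias-corrected form, ((ν − P − 1)·J − P)/ν with ν = n − 2, by
default; the raw form remains available (`corrected=False`). SFFS grows the
subset by the best single addition, then repeatedly removes any channel
(except the newest) whose exclusion strictly improves on the best score
recorded at the smaller size; it overshoots the target size by 3 and
returns the best recorded size-6 subset, channels in inclusion order. Ties
prefer the lexicographically smallest label, making selection
deterministic. Selection runs on a balanced subsample (default 200 epochs
per class) — the criterion is quadratic in sample count and the non-target
surplus adds little.

## Decoding

Features are the PCA-compressed (>99% variance, basis fit on training folds
only) channel × time values. Two classifiers:

- **LDA**: y = wᵀx with w = Σ̂_w⁻¹(μ̂₊ − μ̂₋). Σ̂_w uses analytic
  Ledoit–Wolf shrinkage by default — with P of the order of the training
  count, lightly regularized scatter inversion makes *more* channels decode
  *worse*, inverting the expected channel-set ordering; shrinkage LDA is
  the standard remedy in single-trial ERP work. Diagonal loading is
  available via `reg`. The threshold ξ is set on the training-score ROC at
  the Youden optimum (max sensitivity + specificity − 1), placed midway
  between adjacent training scores; `y > ξ` ⇒ target.
- **SVM**: soft-margin RBF machine y = Σᵢ wᵢ exp(−g‖xᵢ − x‖²) + b (libsvm
  backend), g defaulting to 1/(dim × feature variance), cost 1 — no
  hyperparameter search by default, recorded in the run manifest.

Evaluation is 10 repetitions of stratified 6-fold cross-validation
(repetition r seeds as base + r). Epochs are 1:9 target:non-target, so raw
accuracy is dominated by the majority class; by default training folds are
subsampled to 1:1 and test folds scored by *balanced accuracy* (mean of
sensitivity and specificity, chance = 50%). Raw-accuracy scoring and
unbalanced training are available as flags. Accuracies are reported as
mean ± SE over the 60 fold scores.

**ITR.** Accuracy P over N commands issued every T seconds converts to
bits/min as 60/T·[log₂N + P log₂P + (1−P) log₂((1−P)/(N−1))], zero-probability
terms contributing zero. Defaults N = 10 (ten digit commands) and T = 2 s
(one ten-digit stream); both are uncertain conventions, exposed in config.
Below-chance P yields a negative value, clamped to 0 with a warning by
default.

## Numerical choices

- Epoch grid: decimation leaves 125 samples; latencies are read off an
  8 ms grid.
- The noiseless recovery tests use a 4 s inter-trial interval: the
  zero-phase high-pass spreads each bump's compensatory undershoot over
  ±3 s, and at the default 1 s interval neighboring trials leak ~0.5% into
  each other's epochs.
- Scales used by the tests and the acceptance script, chosen to keep a
  desk-top run in minutes: one fully simulated subject (10 sessions, 62
  channels) for calibration-recovery and decoding checks; 8-channel
  instances for the exhaustive-search comparisons (the exhaustive oracle is
  exponential in channels); the analysis drivers default to 6 subjects × 2
  sessions with flags for the full 18 × 10 design.
- Seeds: every stochastic step takes an explicit seed; per-subject seeds
  derive from the base seed by hashing, kept below 2³¹.

## Known limitations

- The noise model omits rhythmic and artifactual structure of real EEG
  (see *Noise* above); absolute accuracies on synthetic data should not be
  read as forecasts for recorded data.
- The planted signal is a sum of three smooth lobes with a shared
  per-trial latency shift; real single-trial ERPs vary in shape, not just
  amplitude and latency.
- Selection and decoding share the same epochs (selection is not nested
  inside the cross-validation folds), matching the analysis being
  reproduced; nested selection would give slightly more conservative
  set-6 accuracies.
- The two-way repeated-measures interaction analysis (condition × channel
  set) is out of scope.
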