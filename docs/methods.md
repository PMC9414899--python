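# Methods

`sleepwear` implements an end-to-end pipeline for classifying sleep stages
from a chest + finger wearable sensor pair, evaluated the way small clinical
feasibility studies evaluate such systems: per-epoch features, personal and
population cross-validation frameworks, and pooled chance-corrected
agreement. Because no public recordings accompany the study design it
follows, the package ships a first-class synthetic-data generator whose
ground truth (hypnogram, R-peak times, injected clock offsets, desaturation
events) makes every downstream stage testable.

## Synthetic data model

**Hypnogram.** A first-order Markov chain over {Wake, N1, N2, N3, REM} at
30-s resolution, started in Wake. A Markov chain is the minimal generative
structure that produces realistic stage bouts; real hypnograms additionally
show ultradian cycling that a first-order chain does not capture. The
default transition matrix was chosen once for plausible bout lengths
(wake bouts ≈ 2–3 min, N2 dominant) and a stationary distribution of
roughly 16 % Wake, 11 % N1, 43 % N2, 14 % N3, 17 % REM — a fragmented,
hospital-style night. `stationary_distribution()` exposes the
eigen-decomposition oracle used by the tests.

**ECG / heart rhythm.** R-peak times are drawn from a stage-dependent
renewal process: mean interval 60000 / HR(stage) ms, with variability from
(a) two sinusoidal modulations at 0.10 Hz (LF) and 0.30 Hz (HF) whose
amplitude mix is the per-stage HF fraction, and (b) white jitter. Amplitudes
are scaled so the interval SD matches the per-stage SDNN target (80 % of the
variance in the two bands, 20 % white). Intervals are clipped to
[350, 1800] ms. The ECG trace is a fixed stylized PQRST template placed at
each (sample-quantized) R-time; morphology realism is deliberately out of
scope — only R-time geometry feeds the features. Defaults (Wake 78,
N1 70, N2 64, N3 57, REM 74 bpm; SDNN 25–60 ms; HF fraction 0.25–0.75)
give clean stage separation at zero heterogeneity and respect the
HR > 40 bpm validity floor.

**SpO2.** 97 % baseline at 5 Hz with trapezoidal desaturation events
(default 5/h, 4 %-points deep, 30 s: equal ramp-down / plateau / ramp-up
thirds) from an exponential inter-arrival process, plus Gaussian noise,
clipped to [0, 100]. Trapezoids make event counts (ODI) and time-below
(TSA) known by construction.

**Movement.** Quiet gravity baseline on three axes plus 1–3 s burst windows
of high-variance noise, Poisson per epoch with stage-dependent rates
(Wake 60/h ≫ sleep stages ≤ 6/h). Movement is the dominant wake cue, as in
actigraphy.

**Temperature.** Chest at 35.5 °C; limb at 33.5 °C plus a distal rise of
1.5 °C during sleep (distal vasodilation), smoothed over ~2 min, so the
distal-to-proximal gradient (DPG) carries sleep information.

**Heterogeneity.** Two mechanisms, both scaled by one knob: (a) per-subject
additive baseline offsets on HR (SD 8 bpm × scale), SpO2 (1.5 % × scale)
and temperature (0.8 °C × scale), drawn once per subject; (b) in cohorts,
per-stage physiology (stage HR means, SDNN, HF fraction, movement rates,
DPG shift, desaturation rate) is jittered around the shared defaults.
Additive offsets alone would be removed by within-subject z-scoring; the
contrast jitter is what makes the stage→feature mapping subject-specific,
which is the regime in which personal models beat population models.
At heterogeneity 0 all subjects share the defaults exactly.

**What the generator does not emulate:** real QRS morphology and ectopy,
PPG waveforms (SpO2 is synthesized directly), respiration, ultradian
hypnogram structure, sensor detachment and motion artifact of real
wearables. Passing tests therefore demonstrate the pipeline recovers
*constructed* stage structure, not clinical performance on patients.

## Preprocessing

Channels are resampled to nominal rates by polyphase band-limited
interpolation (mean-removed so constants are exact). Accelerometer and ECG
streams are highpass filtered with a fifth-order Butterworth at 1 Hz,
applied forward–backward: the analysis is offline, and zero-phase
filtering preserves R-peak timing. Streams are time-aligned by normalized
cross-correlation of the two ECG channels at a 128 Hz common rate
(adequate for QRS alignment at low cost) within a ±300 s search window;
positive lag means the target stream starts later.

Per-epoch physiological validity: an epoch is excluded iff its minimum
SpO2 < 50 % or minimum heart rate < 40 bpm (strict inequalities), or if
required inputs are missing. The epoch HR minimum is taken from detected
R-R intervals (60000 / max RR), falling back to the 1 Hz device HR channel
when fewer than two plausible peaks are detected in the epoch.

## R-peak detection

Classic Pan-Tompkins stages: 5–15 Hz Butterworth bandpass (zero-phase),
derivative, squaring, 150 ms moving-window integration, adaptive dual
thresholds (running signal/noise peak estimates with 0.125/0.875 update),
200 ms refractory spacing, and search-back at half threshold when the gap
since the last beat exceeds 1.66× the running RR average. Fiducials are
localized to the raw-signal maximum within ±50 ms. Intervals outside
[300, 2000] ms are treated as implausible (ectopy/artifact) and dropped
before any feature computation.

## Features (73 per epoch)

Epochs are non-overlapping 30-s windows `[30k, 30(k+1))`; a trailing
partial epoch is dropped. R-R intervals are assigned to the epoch holding
their terminating peak.

* **ACC (33):** mean, min, max, range, IQR, SD, kurtosis, RMS, variance per
  axis, plus pairwise Pearson rho and p for (x,y), (x,z), (y,z). The
  416 Hz z-axis is decimated (anti-aliased) to the 52 Hz grid first so the
  per-axis statistics are comparable. Variance/SD use the population (n)
  convention and kurtosis is Pearson (non-excess) — stated so tests can be
  exact. Constant-axis correlations are undefined; they are reported as
  rho = 0, p = 1 and the epoch stays valid.
* **ECG (19):** RR and HR mean/min/max, SDNN, RMSSD, NN20/NN50 (strict
  `>`), PNN20/PNN50 (per successive pair, ×100), and spectral features
  from an FFT periodogram of the 4 Hz-interpolated, mean-removed R-R
  tachogram, zero-padded to 4096 points: band power (rectangular
  integration) and peak frequency in VLF 0.0033–0.04, LF 0.04–0.15,
  HF 0.15–0.4 Hz, plus LF/HF. A 30-s epoch cannot resolve VLF (native
  resolution ≈ 0.033 Hz); the VLF numbers are computed literally and are
  near-degenerate — they are carried for inventory completeness, not
  interpretability. Zero HF power would make the ratio singular, so it is
  computed as LF/(HF + 1e-12). Epochs with fewer than 3 plausible
  intervals are invalidated rather than imputed.
* **TEMP (6):** DPG (= limb − chest) mean/min/max/range plus channel means
  on the shared 1 Hz grid.
* **SpO2 (15):** mean, min, variance, lag-1 autocorrelation ("rho": the
  field lists a correlation feature for SpO2 without a second variable;
  lag-1 self-similarity keeps the inventory at 15 and measures waveform
  smoothness), zero-crossing rate of the mean-removed signal (crossings
  per second), desaturation index (mean |difference| of successive 10-s
  window means), TSA at 95/90/85/80/70 % (seconds below threshold), and
  ODI at 2/3/4/5 points below the previous valid epoch's mean.

**ODI event rule.** An *event* is a maximal excursion at least 2 points
(the shallowest ODI threshold) below the reference; ODIx counts events
whose deepest sample reaches x points below. Counting maximal runs
separately per threshold would break the natural nesting
ODI5 ≤ ODI4 ≤ ODI3 ≤ ODI2 whenever noise fragments a deep excursion, so
events are segmented once and classified by depth. The first epoch of a
night (no reference) reports 0; an invalid previous epoch is skipped in
favor of the most recent valid one.

## Models and cross-validation

Four algorithms with paired imbalance handling: balanced bagging and
balanced random forest (class weights + seeded random undersampling to the
minority count) and gradient boosting / XGBoost (SMOTE: synthetic minority
rows interpolated uniformly between a row and one of its k = 5 same-class
nearest neighbors until all classes match the majority; classes with < 2
members fall back to random oversampling, logged). Rebalancing touches
training splits only.

Frameworks: **population** = leave-one-subject-out outer CV;
**personal** = stratified 10-fold outer CV within one subject (random
stratified, not temporally blocked — contiguous-block folds would be the
stricter alternative for autocorrelated nights and are noted as such).
Features are z-scored within subject over the full night in both
frameworks; this mirrors per-subject normalization as practiced, and for
the personal framework it is a known (mild) leakage of test-fold means and
SDs into training — accepted deliberately and flagged here.

Inside each outer training fold: greedy correlation pruning in fixed
column order (drop the later feature of any pair with |r| > 0.95; the
boundary is strict), then an inner stratified 10-fold loop selects the
hyperparameter grid point and the feature-subset size by mean weighted F1.
The recursive-feature-elimination ranking is computed once per outer fold
on the rebalanced outer-training set (step = half the features per round);
the inner folds score prefix subsets of that ranking at a ladder of sizes
(default: halving from all features down to 8). Computing the ranking once
per outer fold rather than per inner split keeps selection outer-fold-local
(no outer-test leakage) at a fraction of the cost. Ties prefer fewer
features. Default grids: trees ∈ {100, 300}, depth ∈ {3, 6}, learning rate
∈ {0.05, 0.1} (boosting only). `ModelSpec.desk_scale()` is a reduced,
seeded search (one grid point, 60 trees, ladder {73, 16}, inner 5-fold)
used for the demonstration cohorts below.

All randomness (fold shuffling, rebalancing, estimators) derives from one
integer seed; a fixed seed reproduces the entire `CVResult` bit-for-bit.

## Evaluation

Pooled Cohen's kappa is computed from one confusion matrix aggregated over
all test folds (pooling, not averaging, keeps the chance-agreement
denominator consistent); agreement bands: < 0 worse-than-chance, 0–0.20
slight, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80 substantial,
0.81–1 near-perfect, with boundaries assigned to the lower band.
Per-class one-vs-rest specificity, precision, sensitivity and F1
(harmonic mean; an empty predicted class reports precision 0 with a flag),
balanced accuracy (mean recall), and per-fold mean ± SEM are reported
alongside. Sleep architecture: total sleep time = 0.5 min per non-Wake
epoch; stage percentages are of total recording time; an awakening is a
maximal Wake run strictly inside the sleep period (after the first and
before the last non-Wake epoch). tSNE uses perplexity 40 and 300
iterations (shrunk with a warning if rows < 3× perplexity), seeded.

## Problem sizes used in the shipped checks

The demonstration cohorts are 5 subjects × 2 h at heterogeneity 0 and 2.0
(≈ 1200 epochs each), with `desk_scale` model specs; the signal-level
checks use a half-hour clean night (~2100 beats) and a seven-point offset
sweep over ±120 s at SNR 10. These sizes were chosen as the smallest at
which the qualitative contrasts of interest (stage separability, the
personal-vs-population ordering) are stable across seeds.

## Known limitations

* Synthetic physiology is stylized; absolute kappas on it say nothing
  about clinical accuracy (the qualitative contrasts are the testable
  claims).
* VLF features are near-degenerate on 30-s epochs (above).
* Personal 10-fold stratification ignores temporal autocorrelation of
  adjacent epochs; with one night per subject this mirrors the common
  single-night protocol, but multi-night train/test splits are the honest
  deployment test.
* The population framework here has 5–9 subjects; leave-one-subject-out
  estimates at that size have high variance by nature.
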