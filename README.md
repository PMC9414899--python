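# sleepwear

Sleep-stage classification from multimodal wearable sensors — a tested,
fully synthetic-data-backed pipeline for the question: *how well can a
chest + finger wearable pair (ECG, triaxial acceleration, SpO2, skin
temperature) recover the polysomnography hypnogram, and does a model
trained on one person transfer to another?*

The package is aimed at sleep / biomedical-signal researchers prototyping
wearable staging algorithms. It provides:

* **Synthetic overnight recordings** with known ground truth: a first-order
  Markov hypnogram over {Wake, N1, N2, N3, REM} at 30-s epochs drives
  stage-dependent heart rhythm (per-stage HR and SDNN with LF/HF
  oscillatory structure), wake-concentrated movement bursts, trapezoidal
  SpO2 desaturations, and a sleep-related distal temperature rise; cohort
  generation adds subject-specific baselines and physiology jitter.
* **Preprocessing**: polyphase resampling, zero-phase 5th-order Butterworth
  highpass (1 Hz), ECG cross-correlation time synchronization, and the
  per-epoch validity screen (min SpO2 < 50 % or min HR < 40 bpm excludes
  the epoch).
* **Pan-Tompkins R-peak detection** (bandpass, derivative, squaring,
  150 ms integration, adaptive dual thresholds with search-back).
* **73 features per 30-s epoch**: 33 accelerometer, 19 ECG/HRV
  (NN20/NN50, PNN20/PNN50, SDNN, RMSSD, VLF/LF/HF band powers and peaks,
  …), 6 temperature (distal-to-proximal gradient), 15 oximetry
  (TSA thresholds, ODI event counts, desaturation index, …).
* **Personal vs. population models**: stratified 10-fold CV within a
  subject vs. leave-one-subject-out CV across subjects, with correlation
  pruning (|r| > 0.95), within-subject z-scoring, nested
  RFE + grid-search selection by weighted F1, and algorithm-paired
  imbalance handling (class weights + undersampling for bagging/forest,
  SMOTE for boosting/XGBoost).
* **Evaluation**: pooled Cohen's kappa
  κ = (p_o − p_e)/(1 − p_e) on the fold-aggregated confusion matrix,
  per-class specificity/precision/sensitivity/F1, balanced accuracy
  (mean recall), sleep-architecture summaries (TST, stage percentages,
  awakenings), tSNE feature-space maps, and report bundles.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from sleepwear import SleepStageModel, build_feature_table, generate_cohort
from sleepwear.modeling import ModelSpec

cohort = generate_cohort(n_subjects=3, heterogeneity=1.0, seed=42, duration_h=2.0)
table = build_feature_table(cohort)          # 73 features x 720 epochs
spec = ModelSpec.desk_scale("balanced_random_forest", seed=42)
res = SleepStageModel(table, framework="personal", resolution=4,
                      spec=spec, subject="S1").fit()
print(res.summary())
```

```
Sleep-stage classification results
========================================================
framework:          personal
resolution:         4-stage
algorithm:          balanced_random_forest
epochs (pooled):    240
folds:              10
pooled kappa:       0.978 (near-perfect)
balanced accuracy:  0.991

Per-class (pooled):
       specificity  precision  sensitivity     f1
Wake         0.990      0.957        0.978  0.967
Light        1.000      1.000        0.986  0.993
Deep         1.000      1.000        1.000  1.000
REM          0.996      0.938        1.000  0.968
```

The pooled kappa is chance-corrected agreement over all ten test folds of
subject S1's night (240 epochs); 0.978 lands in the near-perfect band
because the synthetic stages are separable by construction — on real
patients the interesting result is the *contrast* between frameworks, not
the absolute value. `res.sleep_architecture()` summarizes the predicted
night (here: TST 97.0 min, 7 awakenings), and
`res.report("out/")` writes metrics JSON, confusion matrices and a
predicted-vs-truth hypnogram plot.

The same fit on the **population** framework (train on other subjects,
test on the held-out one) degrades as cohort heterogeneity grows — the
core qualitative finding this pipeline exists to measure.

There is also a CLI for the full chain:

```bash
sleepwear simulate -n 5 --hours 2 --heterogeneity 1 --seed 7 --out data/
sleepwear extract --data data/ --out features.csv
sleepwear train --features features.csv --framework personal \
    --algorithm xgb --stages 4 --subject S1 --seed 7 --out run1/
sleepwear run --seed 7 --out demo/          # all-in-one
```

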