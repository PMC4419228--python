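# eegsampling

Multicategory EEG detection by survey sampling and statistical features.

Long EEG recordings are nonstationary and expensive to summarise point by
point. This package implements a detection pipeline that treats each class
recording as a finite population: it partitions every channel into *k*
contiguous time segments, selects representative time points by one of two
survey-sampling designs, condenses each channel's selected amplitudes into
11 statistical features, and classifies the resulting feature vectors with
k-nearest neighbours, multinomial logistic regression with a ridge
estimator, or a one-vs-one RBF support vector machine, all evaluated under
a repeated, stratified cross-validated protocol. It targets researchers in
biomedical signal processing who need a reproducible, fully specified
baseline for multiclass EEG detection (e.g. the five-class
healthy/interictal/ictal problem).

## The method

**Sample-size design.** The required sample size for a finite population of
size `Popu` follows the confidence-interval formula with finite-population
correction:

    SS = z² · p · (1 − p) / e²,      n = ⌈ SS / (1 + (SS − 1)/Popu) ⌉

with `z` the standard normal variate of the desired confidence level, `p`
the assumed population proportion and `e` the margin of error. Defaults
(z = 2.58, p = 0.5, e = 0.01) give n = 965 for a 1024-point segment,
966 for a 1025-point segment, and 3288 for a whole 4097-point recording.

**Random sampling (RS)** treats each segment as its own population and
draws its n points uniformly without replacement. **Optimum allocation
sampling (OS)** computes one class-level budget m for the whole recording
and divides it across segments by

    nᵢ = m · Nᵢ √(Σⱼ s²ᵢⱼ) / Σᵢ Nᵢ √(Σⱼ s²ᵢⱼ)

where `Nᵢ` is segment i's length and `s²ᵢⱼ` the variance of channel j
inside segment i, so longer and more variable segments contribute more
points (integerised by largest-remainder rounding, which conserves m).

**Features.** Each channel's sampled values are summarised by mean, median,
mode, Q1, Q3, IQR, SD, skewness, excess kurtosis, minimum and maximum — a
500 × 11 feature matrix for a 5-class × 100-channel corpus.

**Classifiers and protocol.** k-NN (Euclidean, automatic k in 1..30 by
cross-validated error), MLR fitted by quasi-Newton minimisation of the
ridge-penalised negative multinomial log-likelihood, and one-vs-one RBF SVM
voting over all K(K−1)/2 class pairs. Stratified 10-fold cross-validation is
pooled into one confusion matrix per repetition; the sampling is repeated
(20× by default) and the metric panel — TPR, FAR, precision, recall,
F-measure, accuracy, kappa, MAE, ROC area — is reported as mean ± standard
error.

## Worked example

The package ships a synthetic corpus generator that emulates the
corpus layout (one ASCII file per channel, one amplitude per line, grouped
in class directories) with controllable class separation:

```bash
eegsampling generate --classes 5 --channels 20 --samples 1024 \
    --separation 6 --seed 7 --out demo_corpus
eegsampling run --corpus demo_corpus --out demo_report \
    --scheme rs --classifier knn --repetitions 3 --folds 5 --seed 7
```

prints

```
realized per-segment sample sizes:
  Class F	253	253	253	253	1012
  Class N	253	253	253	253	1012
  Class O	253	253	253	253	1012
  Class S	253	253	253	253	1012
  Class Z	253	253	253	253	1012
overall metric panel (mean over repetitions):
  TPR: 100
  FAR: 0
  Precision: 100
  Recall: 100
  F: 100
  Acc: 100
  kappa: 1
  MAE: 0
  ROC_area: 1
```

Each 1024-sample channel splits into four 256-point segments; the design
formula asks 253 representative points of each (the finite-population
correction at e = 0.01 takes nearly the whole segment at this length), and
the five widely separated synthetic classes are recovered perfectly: 100%
macro accuracy, zero false alarms, kappa 1. `demo_report/` contains
`report.json`, `report.csv` and per-repetition confusion matrices. The same
pipeline is available as a library (`generate_benchmark`,
`build_sample_set`, `build_feature_matrix`, `run_experiment`) — see
`docs/methods.md` for the modelling details and conventions.

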