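# Methods

## Model and procedure

The pipeline treats a multichannel, per-class EEG corpus as a collection of
finite populations of time points. One experiment run is:

1. **Segmentation.** Each channel of length L is partitioned into k
   contiguous, nonoverlapping segments. The first k−1 segments have size
   ⌊L/k⌋; the remainder is appended to the last segment, so a 4097-point
   recording split four ways gives (1024, 1024, 1024, 1025).
2. **Sample-size design.** The required sample size for a population of
   size Popu is SS = z²p(1−p)/e² shrunk by the finite-population correction
   n = ⌈SS/(1 + (SS−1)/Popu)⌉, clamped to [1, Popu]. The rounding is UP:
   a fractional requirement always costs one more observation.
3. **Selection.** Under RS each segment is its own population and its n
   points are drawn uniformly without replacement. Under OS one class-level
   budget m (Popu = L) is split across segments proportionally to
   wᵢ = Nᵢ·√(Σⱼ s²ᵢⱼ), the segment length times the root of its summed
   per-channel variances. One set of time indices per segment is shared by
   all channels of the class, preserving cross-channel time alignment (the
   allocation formula produces one nᵢ per segment, not per channel).
4. **Features.** The concatenated per-channel samples are summarised by the
   11 statistics listed below, one feature row per (class, channel).
5. **Classification and evaluation.** Stratified n-fold cross-validation of
   the configured classifier; per-fold test predictions are pooled into a
   single confusion matrix per repetition; the whole sampling→features→CV
   chain is repeated (seeds base, base+1, …) and the metric panel is
   reported as mean and standard error across repetitions.

## Numerical conventions

Several estimators are named but not pinned down by convention alone; the
package fixes them as follows.

* **Quantiles** interpolate linearly between order statistics at rank
  h = (n−1)q (the numpy `linear` rule).
* **Standard deviation** uses the n−1 denominator (0 for n = 1).
* **Skewness and kurtosis** are the biased central-moment ratios
  g1 = m₃/m₂^{3/2} and g2 = m₄/m₂² − 3 with mᵣ = (1/n)Σ(x−x̄)ʳ; kurtosis is
  reported as *excess*, so a normal distribution scores 0. A constant
  series short-circuits to g1 = g2 = 0 (and SD = 0) before any moment is
  formed — this also sidesteps catastrophic cancellation when all values
  are equal but large. The mean is clamped into [min, max], where pairwise
  summation can otherwise land a ulp outside.
* **Mode** is the midpoint of the fullest of ⌈√n⌉ equal-width bins over
  [min, max]; ties take the lowest bin; a degenerate range returns the
  common value.
* **Allocation integerisation** uses largest-remainder (Hamilton) rounding,
  ties on fractional parts going to the lower segment index; a share capped
  at its segment size releases its surplus for re-apportionment among the
  uncapped segments by the same rule, iterated to feasibility. The
  pre-rounding shares match the allocation formula exactly, and Σnᵢ = m
  always holds.
* **Sample-size design defaults** z = 2.58 (99% confidence), p = 0.5 (the
  variance-maximising proportion), e = 0.01. These reproduce the reference
  per-segment sizes 965/966 and class budget 3288; all three are
  configurable.
* **MLR** parameterises the first K−1 classes against the last (softmax
  with reference class): P_j = exp(xB_j)/(1 + Σ_l exp(xB_l)). The objective
  is the negative multinomial log-likelihood plus λ·‖B‖² over non-intercept
  entries (intercept unpenalised, so λ→∞ recovers the class priors);
  default λ = 1e−8. Minimisation uses scipy's L-BFGS-B quasi-Newton method
  with the analytic gradient (verified against central finite differences);
  log-sum-exp keeps the likelihood stable. A convergence warning carries
  the final gradient norm if the projected-gradient tolerance (default
  1e−6) is not met within max_iter (default 500) — common and benign on
  (near-)separable data at tiny λ, where the optimum is at infinity.
* **k-NN** works on normalized features with Euclidean distance. Tie rules
  are fully deterministic: distance ties prefer the lower training-row
  index; vote ties go to the tied class whose nearest representative comes
  earliest in the neighbour ordering. Automatic k selection scans 1..k_max
  (default 30) by stratified-CV error on the training matrix, ties to the
  smallest k. The selection runs once per repetition on the full feature
  matrix and the chosen k is reused in every fold; a nested per-fold
  selection would multiply cost without changing the tie-to-1 behaviour on
  separable data.
* **SVM** uses the one-vs-one decomposition: K(K−1)/2 binary soft-margin
  RBF machines (delegated to scikit-learn's SVC), votes summed per class,
  argmax ties to the earliest label in sorted order; scores are vote shares
  votes/(K−1). Defaults C = 1, γ = 1/n_features.
* **Normalization** (default `minmax`) rescales each feature to [0, 1]
  using training-fold bounds only; transformed test values are clipped to
  the guard range [−0.5, 1.5] so a wild out-of-range value cannot dominate
  a distance. `zscore` and `none` are available.
* **Metrics.** Per class (one-vs-rest): TPR = TP/(TP+FN) (= recall =
  sensitivity), FAR = FP/(FP+TN), precision (0 when undefined), F-measure
  (0 when precision and recall are both 0), and a per-class accuracy equal
  to that class's recall. Overall values are unweighted macro averages —
  this reproduces, e.g., an overall TPR that is the arithmetic mean of the
  per-class TPRs. Kappa = (p_o − p_e)/(1 − p_e) with p_e from the marginal
  products, on the [−1, 1] scale. MAE is the mean over instances and
  classes of |score − one-hot truth| (uniform scores over K classes give
  exactly 2(K−1)/K²). ROC area per class is the rank statistic
  P(score₊ > score₋) + ½·P(tie), computed from average ranks; a class with
  no positives or no negatives yields NaN and is excluded from the macro
  mean.
* **Seeds.** Repetition r uses seed base+r for sampling and for the CV
  shuffle; each class's draw is additionally keyed by its corpus index, so
  classes sample independently but reproducibly. Reports are bitwise
  reproducible from (corpus, config).

## Synthetic corpus generator

`generate_class_signal` produces AR(1) channels x_t = φx_{t−1} + ε_t driven
by standardized skew-normal innovations whose SD is σ·multiplier[i] inside
segment i. It emulates the features of the real corpus the pipeline
exploits: the directory/file layout, between-class differences in amplitude
scale and distributional asymmetry, and within-recording variance changes
(which make optimum allocation nontrivial). `generate_benchmark` spaces
classes by a single `separation` knob acting on amplitude scale and
skewness; separation 0 yields identically distributed classes (a null
corpus), and the five-class benchmark gives the last class a several-fold
faster amplitude growth, mimicking the visibly larger voltage swings of
ictal activity. The skew-normal shape parameter orders sample skewness
monotonically but saturates near |a| ≈ 5, so the middle classes of a
five-class benchmark are distinguished mostly by scale; the end-to-end
recovery tests use separation 6 as their "well-separated" condition.

What the generator does **not** emulate: spectral structure (alpha peaks,
spike-wave complexes), artifacts, inter-channel correlation, or heavy
non-Gaussian tails. Passing tests on synthetic corpora therefore establish
that the pipeline is implemented correctly and recovers separable classes
under its own model; they say nothing about detection accuracy on real
recordings, which must be assessed on real data.

## Problem sizes in the test suite

Structural checks that mirror the reference geometry run at full size
(5 classes × 100 channels × 4097 samples). The end-to-end classification
tests use scaled-down corpora — 5 classes × 20 channels × 1024 samples,
5 folds, 3 repetitions — which keeps the whole suite under a minute while
leaving every per-class fold nonempty; the 20-repetition, 10-fold defaults
remain the package's production configuration.

## Known limitations

* The OS scheme estimates per-segment variances from the same data it then
  samples; no design-based variance correction is applied.
* Automatic k selection on the full matrix slightly optimistically biases
  the reported CV error for k-NN; pin `knn_k` to avoid it.
* MAE compares scores to one-hot truth, so vote-share scores (SVM) have a
  nonzero floor even for perfect classification whenever K > 2.
* Feature normalization bounds come from the training fold only; constant
  features map to 0 rather than being dropped.
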