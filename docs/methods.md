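# Methods

## Problem and model

Single-lead ECG beats are classified into eight classes — one normal and
seven arrhythmic (LBBB, RBBB, PVC, PAC, VESC, VFLT, PACE) — directly from
amplitude samples. Class frequencies are extremely skewed (the reference
eight-class selection runs from ~68 % NORM down to ~0.1 % VESC), so the
method optimizes a class-balanced objective: the unweighted mean of the
per-class one-vs-rest Matthews correlation coefficients. MCC is the Pearson
correlation between binary truth and prediction indicators; unlike accuracy
it cannot be saturated by the majority class, so a feature subset only
scores well if the rare classes are recognized too.

The classifier is a probabilistic neural network: a Parzen-window density
estimator per class with an isotropic Gaussian kernel, deciding by the
maximum class-averaged kernel response. Training is pattern storage;
evaluation is O(n_train · n_eval · ns). The Gaussian normalization constant
is class-independent and is omitted from the scores — it cancels under the
argmax. Class priors are equal: the only class weighting is the 1/n_k
averaging, which is what makes the model usable under heavy imbalance.

The feature optimizer is a binary differential evolution over 0/1 masks of
the nf per-beat positions: 1-point crossover between two distinct random
individuals with probability CR, independent bit-flip mutation with
probability MR (applied to every trial, whether or not crossover fired),
and greedy pairwise replacement requiring strict fitness improvement. The
last individual of the initial population is the all-ones mask, so the
final answer is never worse than using every feature. Termination is
`max_gen` generations or a best fitness unchanged (|Δ| ≤ 1e-12) for
`stagnation_window` consecutive generations.

## Parameters

| parameter | default | units / scale | rationale |
|---|---|---|---|
| band-pass corners | 0.5–40 Hz | Hz | baseline/powerline removal, QRS band retained |
| filter order | 6 | — | one-way Butterworth order; applied bidirectionally (zero phase, squared magnitude) |
| fiducial lead | 90 | ms before R | isoelectric PR-segment proxy for the baseline spline |
| beat window | 250 / 450 | ms before/after R | covers P through T; 253 samples at 360 Hz |
| PNN spread σ | 0.1 | Z-score units | kernel width; see below |
| np | 50 | individuals | population size |
| max_gen / stagnation | 200 / 20 | generations | termination |
| CR / MR | 0.8 / 0.2 | probability | crossover / bit-flip rates |
| init_p1 | 0.8 | probability | P(bit = 1) at initialization; biases the search to start near full feature sets |
| split | 0.5, stratified | fraction | per-class halves; odd counts give the extra beat to train (configurable) |

**Choosing σ.** The spread is the one free classifier parameter and must be
matched to the pattern dimension: squared distances between independent
Z-scored ns-dimensional beats grow like 2·ns, so a spread far below √ns
drives every kernel to zero (scores then underflow and fall back to a
logged uniform). The library default of 0.1 suits low-dimensional or
near-duplicate patterns; for full 253-sample beats the package's own study
runs use σ = 1.0, which keeps same-class kernels well inside floating-point
range while preserving contrast between classes. All structural properties
(score ordering oracles, optimizer behaviour) hold for any σ > 0.

## Evaluation

Confusion matrix rows are true classes, columns predictions. Each class in
turn is "positive"; TP/TN/FP/FN derive from the matrix, then Acc, Sen, Spe,
F1 (percent), MCC, and trapezoidal one-vs-rest AUC over the normalized PNN
scores. Macro averages are unweighted class means; the mean per-class MCC is
the DE fitness (reported on the [−1, 1] scale, not percent). Conventions:
0/0 rates report 0 with a warning; an MCC with any zero denominator factor
is 0; tied decision scores go to the lowest class code; tied ROC thresholds
are grouped, making the trapezoidal AUC equal to the Mann–Whitney
probability with ties counted ½.

By default the DE fitness is computed on the final test subset, replicating
the method's original protocol; by modern standards that leaks test
information into feature selection, so `holdout: true` scores candidate
masks on a validation split carved from the training half instead (the
final report is always on the untouched test half).

## Numerical and design choices

- ms→samples conversions round half away from zero (90 ms at 360 Hz → 32
  samples), fixed for cross-platform reproducibility.
- Z-scoring uses the population SD (divisor n). Rows whose SD is below
  1e-12 of their amplitude scale are treated as constant and map to zeros
  (a strict `sd == 0` test misses constant rows whose mean carries an
  O(eps) round-off).
- The Butterworth filter is realized as second-order sections;
  bidirectional application uses odd-reflection padding of 3 × order
  samples. The 0.5 Hz corner rings for seconds, so steady-state gain
  comparisons exclude record edges.
- The baseline spline is not-a-knot, extrapolated with the boundary
  polynomial; it reproduces polynomial trends up to degree 3 exactly.
  Fiducials falling before the record start are dropped with a warning.
- Crossover cuts are uniform on [1, nf−1] so both parents contribute at
  least one bit; an all-zero mask (after initialization or mutation) is
  repaired by switching one uniformly chosen bit on, so an empty feature
  set is never evaluated.
- Fitness values are cached by mask bits; identical masks recur often and
  the cache changes nothing but runtime.
- When several individuals tie at the best fitness the reported mask is the
  sparsest (parsimony — reduction is the point of the search); replacement
  during evolution still requires strict improvement.
- Kernel exponents below −700 are flushed to zero before `exp`.
- End-to-end runs thread one master seed through generator, splitter and
  optimizer; artifacts are stamped with a config hash and are
  byte-reproducible under a fixed seed.

## Synthetic data

The generator emulates the statistical structure the method assumes, not
physiology. Each class is a sum of Gaussian-shaped waves on the beat window
with stylized class signatures (widened QRS for PVC/VESC-like beats, an
rSR'-like double peak for RBBB, a narrow pacing spike for PACE, no discrete
P/T for flutter), plus white noise; records add sinusoidal baseline wander
and 60 Hz interference at exactly known R-peak positions. Default class
proportions follow the reference eight-class imbalance; `ensure_all_classes`
floors rare classes at `min_per_class` samples so stratified splits are
feasible at small n. A separate benchmark mode plants class signal in a
stated feature subset of otherwise pure-noise features (class means at ±
hypercube corners), giving feature-selection tests a known ground truth.

Because morphologies are stylized and beats are i.i.d. (no inter-beat
context, no patient structure, no electrode artifacts), passing tests show
the pipeline's computations and contracts are correct — they do not certify
clinical performance on recorded ECG. The split is beat-wise, as in the
original protocol; patient-wise (inter-patient) evaluation is out of scope
and would give lower numbers on real data.

## Study conditions at desk scale

The full-scale reference experiment (≈108 k beats, 50 × 200 fitness
evaluations, each a PNN pass quadratic in ~54 k stored patterns) is far
beyond a single-CPU test budget. The package's own study conditions scale
it down: the acceptance run uses 1200 synthetic beats (noise SD 0.35, all
classes floored at 4 samples), np = 10, max_gen = 15, stagnation 5,
σ = 1.0; the optimizer-correctness benchmark uses nf = 8 with a planted
informative pair, where exhaustive search over all 255 masks is the oracle.
Under these conditions the DE search reproducibly improves the mean
per-class MCC over the all-features baseline while discarding roughly half
the features.

## Known limitations

- R-peak positions are trusted annotations; no QRS detector is included.
- PNN inference cost grows linearly with stored patterns — the full-scale
  reference run is supported through the CLI but is not desk-scale.
- The printed-report rounding (2 decimals, half away from zero) matches
  common practice but can differ from values averaged before rounding by
  up to half a cent per class.
- WFDB input requires the optional `wfdb` dependency; the CSV dialect is
  the first-class interchange format.
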