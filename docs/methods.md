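# Methods

## Problem and pipeline

Fidgety movements (FMs) are an age-specific pattern of spontaneous infant
motility whose absence around 9–20 weeks post-term is a strong early marker
of neurodevelopmental risk. `matmotion` implements a screening pipeline
that classifies 5-second pressure-mat recordings ("snippets": 500 frames at
100 Hz, each a 32×32 grid of 8-bit pressure values) as FM-present (`FMplus`)
or FM-absent (`FMminus`):

1. **Motion encoding.** Each frame is cropped to the active area — rows
   1–29, columns 4–29 (1-based inclusive), 29×26 = 754 sensors — and split
   head-to-feet into a 12×26 top area (shoulders/head contact) and a 17×26
   bottom area (hips). Per area and frame the centre of pressure (CoP) and
   mean pressure are first spatial moments:

   x = Σᵢ i·p(i,j) / Σᵢⱼ p(i,j),  y = Σⱼ j·p(i,j) / Σᵢⱼ p(i,j),
   p = Σᵢⱼ p(i,j) / (m·n),

   with 1-based area indices i = 1..m, j = 1..n. The six signals
   (x_t, y_t, p_t, x_b, y_b, p_b) are smoothed with a centred 5-frame
   moving average and min-max normalised to [0, 1]: the four position
   signals share one denominator (the largest of their four ranges), the
   two pressure signals another. Sharing denominators preserves relative
   amplitude between body parts while dividing out infant size and weight.
   A snippet is thus reduced from 500×32×32 to 500×6.
2. **Features.** For the kernel and feed-forward models each snippet is
   summarised by mean and population SD of the six signals (12 features),
   optionally plus the same statistics of their time derivatives (24).
3. **Classifiers.** Four families, named by declarative variant specs:
   SVMs (RBF / polynomial kernels, degrees 1–3) and feed-forward networks
   on the features; 1-D CNNs (filters slide along time over 6 channels,
   average pooling after the conv stack, then FC layers) and LSTMs on the
   raw 500×6 signals. All network heads are a single sigmoid unit.
4. **Evaluation.** Infant-grouped 5-fold cross-validation: folds partition
   the infants (45 infants → 9 test infants per fold; the 36 training
   infants split 30 fit / 6 validation). Reported per fold: sensitivity
   TPR = TP/(TP+FN), specificity TNR = TN/(TN+FP), balanced accuracy
   BA = (TPR+TNR)/2; across folds: mean, t-based 95% CI, and pairwise
   pooled-variance two-sample t-tests (Welch behind a flag).

## Training protocol

Networks train with Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-7), binary
cross-entropy, batch size 4, and a validation stop: training halts when
the validation loss has not improved for 10 consecutive epochs (patience
10, epoch cap 500) and the best-validation-loss weights are restored. Per
fold the network is trained from several random initialisations ("restarts")
and the restart with the lowest validation loss is selected; the SVM is
instead selected from the full 25-point grid C ∈ {0.1, 1, 10, 100, 1000} ×
γ ∈ {0.01, 0.1, 1, 10, 100} by plain validation accuracy, ties broken
toward the smallest C, then the smallest γ (prefer the least complex
model). Model selection only ever sees the validation subset; each fold's
test subset is evaluated exactly once, by the selected model.

The network engine is a compact NumPy implementation (`matmotion.nn`):
Glorot-uniform initialisation, im2col-based valid convolutions,
non-overlapping average pooling (remainder steps dropped), full
backpropagation through time for the LSTM (gate order i, f, g, o,
forget-gate bias 1), and a logit-parameterised loss (softplus form) for
float32 stability. Every layer's gradients are verified against central
finite differences in the test suite (float64, relative error < 1e-6).
All parameters live in one flat buffer so the Adam update is a single
vectorised pass; training is deterministic given the seed (initialisation
and batch shuffling both derive from it).

Numerical choices worth knowing:

- **Validation-stop threshold.** An epoch counts as an improvement only if
  the validation loss drops by at least `min_delta = 1e-4` (configurable).
  On easily separable data the loss otherwise keeps creeping down by
  vanishing amounts and patience never fires; 1e-4 on the BCE scale is
  far below any practically meaningful difference between restarts.
- **Moving-average edges.** Centred window, truncated (shrinking) at the
  boundaries: length-preserving, no phase shift, no invented padding
  values. Whether the original protocol used a centred or trailing window
  is unknowable from its description; centred is the unbiased choice.
- **Zero-pressure frames.** An all-zero area has no CoP; it is mapped to
  the area's geometric centre ((m+1)/2, (n+1)/2) with p = 0 and a logged
  warning rather than an exception, keeping signals defined.
- **Zero-range normalisation.** If a signal group's shared denominator is
  0 (all signals constant) the group normalises to all-zero — a constant
  signal carries no motion information.
- **Derivatives.** Central differences scaled by the 0.01 s sampling
  interval, one-sided at the ends; computed from the filtered, normalised
  signals. Population (divide-by-N) SD throughout — immaterial at N = 500
  but fixed for reproducibility.
- **Feature scaling.** Features are z-scored with training-set statistics
  inside the SVM pipeline; without it the fixed γ grid is meaningless.

## Synthetic cohort generator

There is no public forward model from infant movement to mat pressure, so
the generator (`matmotion.synth`) is deliberately minimal: two isotropic
Gaussian pressure blobs (shoulders/head top, hips bottom) on the 32×32
grid, quantised to 8 bits, zero outside the active area. Each blob's
centre moves as a sum of 2–4 random-phase sinusoids plus a slow baseline
drift (0.08 Hz), and its peak pressure is modulated at the same
frequencies. The two classes differ only in their motion law:

| parameter | FM− (absent) | FM+ (present) |
|---|---|---|
| frequency band | 0.3–1.0 Hz | 1.5–4.0 Hz |
| displacement amplitude | 3.0 cells (×0.7–1.3 per snippet) | 1.0 cells (×0.7–1.3) |
| pressure modulation | 0.20 | 0.08 |

i.e. FM-absent movement is slow and large, FM-present is faster and
smaller, and the bands are disjoint — so a trivial spectral-peak
classifier on the ground-truth trajectories is 100% correct, guaranteeing
the downstream learning problem is solvable (a property test asserts
this). Body geometry (blob centres, spreads, weight scale) is sampled once
per infant and reused across that infant's snippets, which is what makes
infant-grouped cross-validation meaningfully harder than snippet-level
splits. Additive Gaussian sensor noise defaults to 2 counts SD on the
8-bit scale — the mat's true noise figure is unpublished; 2 counts (<1% of
typical peak pressure) is a realistic sensor-grade default. Labels are
drawn i.i.d. with positive fraction 948/1776 ≈ 0.534, emulating the study
cohort's mild class imbalance; the default cohort shape is 45 infants ×
40 snippets.

Every snippet carries the exact trajectories used for rendering, so the
encoder can be validated end to end: for noise-free snippets with blobs
well inside their areas the extracted CoP follows the ground-truth track
within 0.5 cells at every step. Near the 12/17 split boundary the CoP is
biased toward the area interior because the Gaussian tail is truncated —
a property any split-based CoP shares, synthetic or real.

What the generator does **not** emulate: limb-resolved contact patterns,
postural shifts and rolling, non-stationary movement bouts, sensor
calibration drift, or the "not assessable" behavioural states. Passing
tests therefore demonstrate that the pipeline recovers class structure
that is genuinely present in the signals, not that the real recordings
are this easy: published accuracies on real infants are far below the
near-perfect values reached here.

## Problem sizes used in the shipped analyses

The analysis drivers and the acceptance script run a 45-infant × 20-snippet
cohort with 5 network restarts per fold, and cross-validate one tractable
representative per family (S1.RBF, S2.P1, F1.3, C3F2). These sizes keep a
full run to minutes on a single CPU while preserving the study's fold
geometry (9/30/6 infants); the full 40-snippet, 20-restart protocol is a
config change (`CohortConfig`, `TrainingConfig`). LSTM variants are
implemented and gradient-checked but excluded from the shipped full-scale
comparison: backpropagation through 500 time steps in NumPy is an order of
magnitude slower than the convolutional models, and the model tests cover
the family at smaller scale.

## Known limitations

- The per-variant layer tables beyond the three explicitly described CNN
  variants (4@7, 16@13, 64@21) are reconstructed by convention: deeper
  conv stacks repeat the 7-wide filter with doubling counts (4→8→16),
  pooling window 4, FFN/LSTM widths 100/200/32. All are overridable via
  `ModelSpec`.
- Whether reported confidence intervals use t or normal quantiles is
  ambiguous in this literature; t-based intervals are implemented.
- The adapter for externally deposited recordings validates shapes and
  label vocabulary only; it has not been run against any real deposit.
- The pooled-variance t-test treats per-fold accuracies as independent
  samples, as is conventional for k-fold comparisons, although folds share
  training data.
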