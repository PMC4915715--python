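# Methods

`odormap` predicts the odor impression of a monomolecular odorant — a
profile of applicability values over 144 verbal descriptors ("floral",
"sweet", …) in [0, 1] — from its 70 eV electron-ionization mass spectrum,
binned to 212 integer m/z channels (51–262).  This note documents the model,
the training recipe, the numerical choices, the synthetic data the package
is validated on, and the known limitations.

## Model

The predictor is a nine-layer fully-connected sigmoid network with unit
counts

    212 – 85 – 45 – 50 – 55 – 50 – 30 – 65 – 144

assembled from three separately trained parts:

1. a **spectrum autoencoder** 212–85–45–85–212, whose encoder half
   (212–85–45) compresses a spectrum to a 45-dimensional code;
2. a **mapper** 45–50–55–50–30, a multilayer perceptron from the spectrum
   code space to the sensory code space;
3. a **sensory autoencoder** 144–65–30–65–144, whose decoder half
   (30–65–144) expands a 30-dimensional sensory code to the descriptor
   profile.

All units except the input layer apply the logistic function to an affine
map, so every intermediate and final activation lies strictly in (0, 1) —
matched to max-normalized intensities and applicabilities.  Assembly is pure
rewiring: at assembly time `predict(x)` is bit-identical to
`decode(map(encode(x)))` (a tested invariant).

## Training recipe

Every part is trained by per-sample stochastic gradient descent on the
squared-error loss plus an L1 (lasso) penalty on all weights and biases,
with the update

    w <- w - eta * dE/dw + alpha * (w - w_prev) + noise

* `eta = eta0 * decay^t`, eta0 = 0.4, decay = 0.99, `t` the epoch index
  (one sweep over the training set in freshly shuffled order); constant
  within an epoch.  Per-update decay would shrink eta to ~0 within a few
  epochs and freeze learning.
* `lambda_l1` = 4e-7; the subgradient of |w| at 0 is taken as 0.
* momentum `alpha` = 0.025 on the previously realized step.
* 200 epochs per training stage by default.
* initialization: uniform on [-0.03, 0.03] for the autoencoders (see
  below for the mapper).

**Greedy pretraining.**  Deep sigmoid autoencoders trained cold suffer
vanishing gradients, so the five-layer autoencoders are initialized by
copying: stage 1 trains a three-layer autoencoder M–K–M on the data; stage 2
trains K–D–K on the stage-1 hidden codes (sigmoid outputs in (0, 1), used
without rescaling); the outer and inner weight pairs are copied into the
M–K–D–K–M stack, which is then fine-tuned end to end (flag-controlled, on
by default).  Copying is exact: immediately after assembly the stack's
encoder output is bit-identical to the stage-1 encoder.

**Mapper initialization.**  The mapper has three hidden sigmoid layers and
no pretraining stage of its own.  With a fixed ±0.03 uniform init its
hidden activations start indistinguishable from 0.5 and backpropagated
signal through three near-zero weight layers is vanishingly small; in our
experiments the mapper then stalls at predicting the target mean (training
R ≈ 0.5) regardless of epoch budget or schedule.  The mapper therefore
defaults to fan-scaled (Glorot) uniform initialization,
±sqrt(6/(fan_in+fan_out)) with zero biases, the standard remedy for exactly
this pathology; `train_mapper(init=0.03)` restores the narrow init.

**Whole-model fine-tuning.**  After assembly the nine-layer stack is
fine-tuned end to end for 5 passes with the same rule.  The learning-rate
schedule continues from the budget already spent building the parts
(3 × `epochs`, i.e. t = 600 at defaults, eta ≈ 1e-3).  This choice is
load-bearing: per-sample end-to-end updates through eight stacked weight
layers diverge at eta above roughly 1e-2 (gradients are amplified by
products of trained weight matrices of magnitude 1–5), and a fine-tune at
the initial rate reliably destroys an assembled solution.  A
`lr_reset=True` flag restarts the schedule for comparison.

**Noise injection.**  The update rule supports adding i.i.d. Gaussian noise
of standard deviation `noise_coeff * sqrt(2*eta)` (noise_coeff = 0.5) to
every weight update, intended to shake weights out of poor local minima.
It is implemented and tested but **disabled by default**: with sd
proportional to sqrt(eta), the noise–gradient balance is that of a Langevin
sampler at constant temperature T = noise_coeff² = 0.25 (the sqrt(2·eta)
factor exactly cancels the eta in the drift), and by equipartition the
stationary distribution carries ~T/2 excess loss per parameter — thousands
of loss units for networks with 10⁴–10⁵ parameters, far beyond the entire
attainable loss range.  In pilot runs training under the default-scale
noise never progressed; annealing enters only through sqrt(eta) and is far
too weak.  A temperature low enough to help (noise_coeff ≲ 0.01) is a
different regime than the published constant, so rather than silently
rescale we expose the mechanism (`TrainConfig.noise_enabled`) and default
to plain SGD with momentum.

## Evaluation protocol

Repeated k-fold cross-validation: the paired matrices are randomly split
into 6 folds (sizes 21/20/…/20 at n = 121), each fold is held out once per
repetition, and the split is redrawn 10 times — 60 fits.  For each fit the
**entire** pipeline (both autoencoders, mapper, assembly, fine-tuning) is
retrained from scratch on the 5 training folds.

* **Pooled Pearson R** — one correlation over all descriptor × sample
  points of the held-out fold (e.g. 144 × 21 = 3024 points), the headline
  metric.  Note this pools between-descriptor and within-descriptor
  variance; a model that only reproduced per-descriptor means would already
  score R ≈ 0.3–0.8 depending on the data, which is why leakage tests use
  within-descriptor correlations instead.
* **Generalization error** — the summed per-sample loss over the held-out
  fold.
* **Reconstruction error** — the absolute-sum criterion
  `sum_nm |x_nm - y_nm|` for the autoencoders, also used in the
  K/D dimension sweeps and in the PCA comparison.
* **Medians across fits** — stochastic fits occasionally diverge;
  non-finite fits are excluded and counted, and medians (not means)
  summarize the 60 fits.
* **Per-sample error analysis** — mean absolute held-out error per sample
  and per descriptor; the top 5% of samples (6 of 121, rounding 6.05 to
  the nearest integer) are flagged as hard cases.

Baselines: PCA reconstruction at matched component count (centering + SVD,
fitted on training folds) and two-block PLS regression under the identical
CV rule, with its latent-variable count selected by minimum median held-out
error over a grid.

## Synthetic data

Real paired data (a Dravnieks-style sensory atlas × a spectral library) are
not redistributable, so the `synthetic` module generates datasets of the
same shape and character from a known low-dimensional ground truth.  A
latent vector z ~ N(0, I₃) drives both sides:

* **Spectra**: 40 fragment channels at fixed random m/z positions; channel
  intensities are log-linear in z (exp(1.5·z·w + b)) with multiplicative
  lognormal noise, scaled per spectrum to base peak 999 (the relative-
  abundance convention of EI libraries), then max-normalized per dataset.
  This yields sparse nonnegative patterns with a handful of dominant peaks
  per sample.  Defaults: 121 samples, 212 bins, ~10 dominant peaks.
* **Sensory profiles**: the default `sigmoid-mixture` link passes z through
  8 steep sigmoid ridge functions (steepness 6) and mixes them per
  descriptor with a squashed output (scale 1.5, offsets N(-0.8, 0.5)) so
  values concentrate in the low-to-mid range like panel applicability
  data; Gaussian noise (sd 0.05) is added, values are clipped to [0, 1]
  and max-normalized.  The steep ridges make the spectrum→sensory relation
  genuinely nonlinear, so a linear baseline is measurably handicapped — the
  regime the nine-layer model is designed for.  A `linear` tag (exactly
  linear, useful as a PLS sanity case: with zero noise PLS reaches
  R ≥ 0.999) and an `rbf` tag are also provided, as is an outlier-injection
  flag that moves 5% of samples far from the latent centroid.

What the generator does **not** emulate: chemically realistic fragmentation
(isotope clusters, neutral losses, shared fragments between homologues),
correlated panel noise, or descriptor semantics.  Passing benchmarks on
this data shows the pipeline recovers a smooth nonlinear latent link at
n ≈ 121 better than linear baselines; it does not certify performance on
real sensory atlases.

## Benchmark problem sizes

The distribution-level checks are sized to run comfortably on one CPU:

* nonlinear-advantage benchmark: 10 seeds, full default data shape
  (121 × 212 → 121 × 144), stage epochs reduced to 50, one held-out fold
  (of a 6-fold split) per seed, PLS latent count selected per seed by the
  CV rule over {2, 3, 5, 8, 12, 20, 30, 45}.
* autoencoder-vs-PCA: curved 1-D manifold (¾ circle arc rotated into 20
  dimensions), 100 train / 20 test, code dimension 1, 200 epochs per
  stage, 10 seeds.
* gradient checks: central finite differences at step 1e-6 on 100 random
  networks of up to 4 weight layers and 10 units, plus an 8-weight-layer
  shrunken shape; relative-error tolerance 1e-5 in the l2 norm.

## Degenerate inputs and numerical details

Sigmoid evaluation uses `scipy.special.expit` (saturates, never NaN).
All-zero matrices cannot be max-normalized (error); negative intensities
are rejected; fractional m/z are rounded to nominal mass with a warning;
duplicate sample ids are errors at alignment.  All randomness flows through
explicit `numpy.random.Generator` objects; every fit in a CV campaign
derives its generator from (plan seed, repetition, fold) so campaigns are
reproducible and folds independent.  Models serialize to a versioned JSON
archive (layer sizes + flat arrays).

## Known limitations

* The noise-injection constant is exposed but unusable at its published
  scale (analysis above); enabling noise requires choosing a much smaller
  coefficient.
* End-to-end fine-tuning at aggressive rates is unstable; the default
  corrects gently and large improvements must come from the pretrained
  parts.
* The pooled-R headline metric rewards reproducing descriptor means;
  per-descriptor correlations are reported alongside for a stricter view.
* Training is plain NumPy on one core; a full 60-fit campaign at the
  default 200-epoch budget takes a few hours, which is why the shipped
  benchmarks use reduced epochs.
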