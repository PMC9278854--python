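# Methods

`neuroiface` implements the *direct interface* test of correspondence
between neural recordings and layers of a convolutional image classifier:
instead of asking how much variance a brain region shares with a model
layer, it asks whether the recorded activity, translated linearly into that
layer's activation space, can *drive the network to the correct behavior*.
This note documents the models, the synthetic study conditions, the
numerical choices, and the places where the design was genuinely open.

## The interfacing model

Let `f` be a trained classifier mapping an image stack `X` (n × H × W × C)
to class probabilities `P = f(X)` (n × m).  For any named layer `q` the
forward pass decomposes as `f = g'_q ∘ g_q`, where `g_q(X)` are the layer-q
activations and `g'_q` resumes the computation.  Given a neural data matrix
`R` (n × d; electrodes or voxels, row-aligned with the images), a linear
translation `W` (d × u) is fitted on training rows so that

    g_q(X) ≈ preprocess(R) · W

and the brain-driven predictions are `P_r = g'_q(preprocess(R) · W)`.
Correspondence between the recorded region and layer q is scored on
held-out rows by

* **multiclass AUC** (Hand–Till): for each unordered class pair, the two
  directed two-class AUCs under the respective class scores — each computed
  through the Mann–Whitney U statistic with ties counted ½ — are averaged,
  and the result is averaged over all pairs.  Chance is 0.5 regardless of
  the number of classes.
* **KL divergence** per row between image-driven and brain-driven output
  distributions, `D(P_i ‖ P_r)` in nats; lower is better.  The phrase "KL
  divergence of P_r from P_i" is read as divergence *of the approximation
  from the reference*; the opposite direction is available by flag
  (`kl_rows(..., reverse=True)`) and all internal comparisons use one
  direction consistently.  Rows are clipped at 1e-9 and renormalized before
  logs so one-hot rows cannot produce infinities.

### Cross-validation

All classifier-based scores use stratified k-fold cross-validation (default
k = 8): every stratum is dealt round-robin into folds after a seeded
shuffle, which (i) gives the exact 1/k-per-class allocation whenever counts
divide k and (ii) handles strata smaller than k (two examples per class is
a *supported regime*, not an error).  Stratification can be keyed on object
identity instead of class label.  The reported AUC is computed **once over
the pooled held-out predictions** — every row is predicted by the fold that
held it out — with per-fold values retained only as dispersion diagnostics.
Zero-shot generalization uses leave-one-class-out: one fold per class,
containing the entirety of that class, so every evaluation row belongs to a
class the translation never saw.

### Translation modes and fitting

`W` is bias-free and has no nonlinearity.  The neural data are centered and
column-normalized using **training-fold statistics only**; "column-
normalized" is ambiguous between unit SD and unit norm, and the package
defaults to z-scoring (unit SD) with unit-norm selectable — the two differ
only by a per-column constant, which a ridge-type penalty treats
equivalently.  Zero-variance columns (dead channels) get scale 1 and are
zeroed by the centering, never an error.

One genuine deviation from the naive reading: a bias-free `W` applied to
*centered* inputs provably cannot reproduce the nonzero mean of post-ReLU
activations (on centered X, the OLS fit of any constant target component is
exactly zero).  The map is therefore fitted against mean-centered targets
and the training-target mean is stored with the map and restored at
application.  `W` itself remains linear and bias-free; the stored mean is
preprocessing metadata of the same standing as the neural-side centering
statistics.  Without this, held-out activation predictions carry a constant
offset equal to the training-mean activation vector, and exact recovery on
noise-free fixtures is impossible.

Three training modes:

* **mse** — minimize mean squared error to the layer activations.  The
  reference optimizer is mini-batch SGD (batch 64, momentum 0.9, l2 3e-4,
  initial learning rate 0.1, halved when validation loss stalls for 4
  epochs; stop at 400 epochs or 20 stale epochs).  A closed-form ridge
  solver — the minimizer of `(1/(n·u))‖XW−Y‖² + (λ/u)‖W‖²` — is offered as
  a fast path and agrees with the converged SGD solution on
  well-conditioned problems (tested).  The two are *not* interchangeable on
  noisy, ill-posed problems: early stopping gives SGD an implicit
  regularization the tiny explicit λ does not replicate, so the sparse
  noisy regimes below use the SGD reference mode.  An Adadelta variant
  (batch 128, rate multiplier 0.04) is the trial-level option; it converges
  slowly and is intended for the temporal analyses that mirror it.
* **end_to_end** — `W` is the only free parameter of the composed model
  `g'_q(W·x)`, trained by backpropagating categorical cross-entropy from
  the softmax output with every network weight frozen (verified
  bit-identical before/after).
* **pca_target** — targets are first reduced to the leading r principal
  components of layer-q activations, with axes fitted on an *independent*
  activation sample; `W` maps into the latent space and application
  reconstructs the full activation width through the stored axes.

### The classifier

The classifier is a miniature VGG-style network implemented directly in
NumPy (im2col-free shifted-matmul 3×3 convolutions, spatial batch
normalization, ReLU, 2×2 max pooling, dense layers, softmax), trained with
mini-batch SGD with Nesterov momentum 0.90561, initial learning rate 1e-3,
batch 64, Glorot-normal init, l2 weight decay 5e-4, dropout 0.4 on dense
layers, and flip/translate (optionally rescale) augmentation; the learning
rate halves after 4 epochs without validation improvement and training
stops after 10.  The default architecture is 4 blocks (16-32-64-64, one
conv per block) on 32×32×3 input with one 64-unit dense layer — small
enough to train in well under a minute on one CPU while preserving the
early/late layer contrast.

Injection points sit at the output of a full block
(convolution → batch-norm → ReLU), i.e. **post-nonlinearity**, which makes
the decomposition identity exact (max abs error ≤ 1e-5 is asserted;
observed error is 0 because resuming re-executes the identical float32
ops).  Pre- versus post-ReLU injection is a genuine design choice;
post-ReLU is the only one under which
"replace the activations" is unambiguous, and the alternative remains an
expert option by adding explicit checkpoints.  Flattening is row-major
over (h, w, c) and translation maps use the same order.  Evaluation-mode
forward passes are pure: dropout off, normalization statistics frozen.

## Synthetic study conditions

The method's natural habitat is real cortical recordings paired with an
ImageNet-scale classifier; neither is reproducible at desk scale.  The
synthetic_data module therefore generates data with the statistical
structure the analyses *assume*, so that every pipeline stage is testable
against ground truth:

* **Images** — m classes of geometric archetypes (disc, square, cross,
  bars, gratings, ring, triangle, checker, ...) crossed with hue and a
  texture factor, with position/scale jitter and light pixel noise.
  Classes are procedurally separable (a linear pixel readout already
  exceeds 90% on held-out data), which concentrates class evidence in later
  layers of a trained net — the regime the method targets.
* **Static recordings** — `R = g_q(X)·A + η`, with `A` a fixed random
  projection (standard-normal entries scaled by 1/√u, full rank almost
  surely) and `η` i.i.d. Gaussian measurement noise with SD equal to
  `noise_sd` × each feature's signal SD.  Noise is applied after the
  projection (measurement noise), not before (neural noise); one knob
  suffices for the test surface.  The real datasets' noise structure is
  uncharacterized; Gaussian is a stand-in.
* **Two-region dynamics** — paired V4-like and IT-like temporal recordings
  (10-ms bins, onsets −20…270 ms) in which (i) a stimulus drive with
  trial-level fluctuations reaches the V4-like region first and the
  IT-like region `feedforward_lag` bins later *carrying the same
  fluctuations*, so raw rates are Granger-causal V4→IT; (ii) an
  object-class code (a random projection of a late layer's activations)
  enters the IT-like region under a stimulus-locked envelope with its own
  amplitude fluctuations, and the V4-like region receives the class signal
  and its fluctuations `feedback_lag` bins later, so class information is
  Granger-causal IT→V4; (iii) a weak third-order loop returns the fed-back
  V4 class signal to IT.  Rates are rectified after additive noise.
  Defaults: 45 bins of 10 ms (onsets −20…420 ms), stimulus on bins 2–12,
  feedforward lag 2, feedback lag 3, feedback gain 0.8, noise SD 0.3.  The
  recorded window extends well past stimulus offset deliberately: per-trial
  standardization (below) couples a trial's late bins into its early ones
  at order 1/T, and a longer window keeps that smear below the detection
  threshold of the causal tests.

## Temporal analysis

Bin-wise interfacing treats each 10-ms bin as an independent decoding
problem at the individual-trial level under the shared fold plan, giving a
trials × bins KL series per region; the same container carries mean-rate
series.  Stationarization of the KL series is two-step: per-trial temporal
standardization, then per-bin standardization across trials (every bin
ends with mean 0, SD 1 across trials).  The description "subtracting the
temporal mean and SD" is read as subtract-mean-then-divide-by-SD, since
subtracting an SD is not a standardization.  Re-applying the operator to
an already-stationarized series is the identity.  One intrinsic artifact
deserves note: the per-trial mean couples a trial's future into every bin
at order 1/T, which can smear genuinely late cross-region dependence
slightly backward in time — hence the extended simulation window above and
T = 60 series in the calibration fixtures.  Raw **rate** series are
standardized per bin only (`stationarize(..., per_trial=False)`): the
two-step form exists to remove trial-level scale from the relative-entropy
readout, the simulator's rates carry no trial-level gain drift for the
per-trial step to remove, and skipping it avoids injecting the late
feedback epoch into the early feedforward epoch of the same trial.

Each direction of a Granger comparison is an OLS lag regression pooled
across trials with lags never crossing trial boundaries (per-trial fitting
with summed likelihoods is available by flag).  The lag order p is chosen
by an information criterion (BIC default) **on the causal model**, for two
reasons: selection on the null (own-lags) model is blind to cross-series
dependence (a lag-2-only coupling leaves the target white, the null BIC
picks p = 1, and the dependence is never tested), and order selection is
performed on every other trial so the subsequent test is not biased by
choosing the best-fitting order on the same sample.  The decision is a
likelihood-ratio test, χ² with p degrees of freedom at α = 0.05
(configurable).  Time-resolved decisions use an expanding window from
stimulus onset (step 1 bin), so each decision uses all post-onset
evidence available at that step.

Under these choices, white-noise calibration gives a type-I rate within
three Monte-Carlo SDs of α, and a lag-2 coupling of 0.8 is detected in
essentially every run with the reverse direction at the nominal false-alarm
level.

## Perturbation analysis

Gaussian noise with per-unit SD γσ (σ estimated from the clean activations
of the evaluation images themselves; γ default 4.0) is injected at a layer
and propagated to a downstream reference layer; deviation is the mean
absolute difference normalized by the reference units' SD (MSE and cosine
distance are selectable alternatives), averaged over 8 noise draws by
default.

How well the attenuation finding survives miniaturization splits cleanly
in two.

**Interior attenuation is robust.**  Noise injected two or more pooling
stages upstream of the reference consistently produces *less* deviation
there than noise injected at the no-pool adjacent layer, across every
architecture and training instance examined.  Two structural properties
carry this: the compared adjacent pair must not have a pooling stage
between them (in the full architecture the final conv block contains
several convolutions, so the "immediately preceding" layer feeds the
reference directly; a one-conv-per-block miniature inserts a pool there
and destroys the contrast), and wide early layers let independent noise
cancel through fan-in.  `NetSpec.vgg_miniature()` — five blocks,
64-channel early layers, multi-conv final block — preserves both, and the
interior ordering is asserted by the test suite.

**The ordering relative to the very first conv layer is not a desk-scale
property.**  A γσ perturbation at the first layer destroys the network's
entire stimulus representation, and whether the downstream cascade absorbs
or amplifies that depends on details of the trained weights: across ~16
training instances (4–5 blocks, 16–64 channels, 32²/64² inputs, flat and
textured stimuli, 6–40 epochs, saturating and non-saturating tasks) the
earliest-vs-preceding margin is approximately zero-mean with spread of
about half a σ-unit, flipping sign from one training seed to the next.
Training on a hard, non-saturating task (the 144-class set) reduces but
does not eliminate the instance dependence.  At full scale the first
convolutional block is enormously overcomplete for its input (64 channels
of 3×3×3 filters at 224²), a redundancy no desk-scale miniature in this
package's budget reproduces; we report this as a finding about the
phenomenon's prerequisites.  The corresponding earliest-layer assertion in
the acceptance suite is expected to fail on the canonical fixture and is
left in place deliberately rather than pinned to a luckily-initialized
training seed.  The compact net remains the default for analyses where
architecture is not the object of study.

## Baselines

* **MVPA** — multinomial logistic regression (lbfgs, 1e3 iterations),
  single nearest neighbor (Euclidean), and a one-vs-rest linear SVM
  (C = 1e-3, 1e4 iterations, uncalibrated decision-function scores),
  each fitted per fold on fold-normalized recordings and scored with the
  same pooled Hand–Till AUC as the interfacing run, on the identical fold
  plan.
* **Neural predictivity** (shared variance) — per fold, PCA of the probed
  layer's activations on training images, partial-least-squares regression
  (defaults scaled to the small net: 200 PCs, 10 PLS components) from the
  reduced activations to each recording feature, Pearson correlation per
  feature on pooled held-out predictions, summarized by the median feature.
  The mapping direction is model→brain, the reverse of interfacing.
* **Pixel interfacing** — flattened images reduced to the leading principal
  components (axes fitted on a held-aside image pool) substitute for
  recordings in the standard grid.  With ample samples this attains its
  best AUC at the earliest conv layer, the complementary control showing
  the substitution approach carries no intrinsic late-layer bias.

In the many-class sparse regime (144 classes × 2 examples, late-layer
readout with measurement noise at 4× signal SD), all three MVPA baselines
sit near chance while late-layer interfacing stays well above it — the
desk-scale analogue of decoding failing where interfacing succeeds.  This
dissociation needs many classes (it does not appear at 10 classes, where
one example per class suffices for prototype classifiers) and the SGD
reference mode for the translation (whose early stopping regularizes the
fit in this ill-posed regime).

## Reproducibility

Every pipeline stage draws from a named substream of one master seed
(SeedSequence keyed by a CRC of the stage name), so re-running one stage
never perturbs another, and identical seeds give bit-identical artifacts
on a fixed platform (single-threaded BLAS).  Scenario runs write a config
echo, its content hash, and all seeds beside the results.

## Problem sizes

Analyses are sized for a single CPU: 10 classes × 200 images for the main
grid (train ≈ half a minute), 144 classes × 40 for the many-class net,
200 trials × 45 bins for the temporal simulator, 200/100 Monte-Carlo runs
for Granger calibration/power, 20 seeded runs for the recurrence
dissociation.  These sizes are choices of the package's study conditions;
every threshold quoted above is asserted by the test suite at exactly these
sizes.

## Limitations

* The synthetic recordings instantiate the linear-readout structure the
  translation assumes; passing tests demonstrates the machinery recovers
  planted structure, not that real cortical data satisfies the assumptions
  (no hemodynamics, no biophysical spiking, Gaussian noise only).
* The Hand–Till AUC uses the symmetric average of the two directed pairwise
  AUCs; asymmetric variants would differ only through class imbalance.
* The Granger machinery is bivariate; spectral or conditional variants and
  more than two regions are out of scope.
* Inherited hyperparameter conventions (SVM C, logistic iteration caps,
  the Adadelta rate) are defaults, not claims of optimality.
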