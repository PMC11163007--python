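# Methods

## The problem

High-throughput screening of hydrogel libraries (e.g. thermogelling
Pluronic F-127 or supramolecular α-cyclodextrin/PEG systems) produces one
impedance phase-angle spectrum per well: a 1-D curve with a resonance-like
dip whose position, width and depth shift at the sol–gel transition.
Classifying each spectrum as *solution* or *gel* is a supervised problem,
but the training data are almost always class-imbalanced — a concentration
sweep yields many more wells of one phase — and a CNN trained by plain
cross-entropy on such data collapses toward the majority class (in our
experiments the unaugmented baseline frequently predicts *solution* for
every test well).

`phasegan` addresses this with generative data augmentation: a
class-conditional generator, a Wasserstein critic with gradient penalty,
and the classifier itself are trained jointly. Adversarial learning makes
generated spectra realistic; cooperative learning (the classifier's
cross-entropy on generated samples, added to the generator objective)
makes them class-distinguishable; and every classifier batch is balanced
by filling minority deficits with generated spectra.

## Model and training procedure

Spectra are min–max normalized to [-1, 1] (constants fitted on the
training split only) and reshaped onto a most-square 2-D grid
(800 → 25×32, 128 → 8×16) so that the 2-D convolutional architecture
applies: 4 blocks of [Conv2D(4×4, stride 2, same), LeakyReLU(0.2)] for the
critic and classifier, 4 blocks of [ConvTranspose2D, LeakyReLU, BatchNorm]
with a final tanh for the generator, random-normal(σ=0.02) initialization,
Adam(lr 2·10⁻⁴, β₁=0.5, β₂=0.9), gradient-penalty coefficient λ=10,
kernel counts (64,128,128,256) / (128,128,64,1) / (32,32,128,256),
150 epochs after 100 reconstruction pre-training epochs. Transposed
convolutions are implemented as the exact adjoint of the downsampling
convolution between each pair of grid shapes, so odd grid sizes mirror
exactly.

Published accounts of this model family leave the exact player objectives
to supplementary material; this package adopts

* critic: `mean D(x̃, y) − mean D(x, y) + λ·mean((‖∇x̂ D(x̂, y)‖₂ − 1)²)`
  with x̂ a per-sample uniform interpolate of real and generated batches,
* generator: `− mean D(x̃, y) + w_coop · CE(C(x̃), y) + w_fm · Σ_c ‖mean φ(x̃_c) − mean φ(x_c)‖²/K`,
* classifier: cross-entropy on the balanced batch (real + generated fill),

with `w_coop = 1`, `w_fm = 1` and φ the critic trunk (per-class feature
matching). Update order is critic → generator → classifier, one step each.

### Pre-training and the latent prior

An encoder sharing the critic trunk maps spectra to the latent space and
the generator decodes them conditioned on the true label; both are trained
by mean-squared reconstruction. Afterwards the class-conditional latent
prior N(μ_y, σ²) is fitted from the encoder outputs: per-class means with a
**pooled** within-class spread. A minority class of a handful of samples
cannot support its own spread estimate; the pooled spread transfers the
majority class's within-class variation (e.g. peak-position jitter) through
the shared decoder — precisely the mechanism that lets generative
augmentation out-diversify interpolation of the few minority samples.

### Desk-scale stabilizers

Joint adversarial training with a minority class of 2–10 samples is
delicate; the following choices, all active by default, were required for
stable behaviour and are part of the package's design:

* **Class-balanced critic batches.** The critic's real batches are drawn
  class-balanced (minority resampled with replacement). Fed the raw
  imbalanced stream instead, the critic sees the minority region populated
  almost exclusively by generated samples, learns "minority-looking ⇒
  fake", and actively pushes the generator out of the minority class.
* **Multi-class-output critic.** D(x, y) selects class y's column of an
  n-class linear head over the trunk features. A single score with weak
  additive/projection label coupling degenerates at tiny minority counts
  into an unconditional critic whose transport field points from the
  minority region toward the majority mass; per-class scores keep each
  class's real-vs-generated comparison self-contained.
* **Critic warm-up** (default 10 epochs): critic-only updates before the
  generator moves, so the first generator steps follow an informative
  score rather than noise (Adam's per-coordinate normalization otherwise
  amplifies meaningless early gradients into full-size steps).
* **EMA serving generator** (decay 0.995): an exponential moving average
  of the generator weights serves all generated samples consumed by the
  classifier and by `generate_minority`, insulating the classifier from
  transient adversarial excursions. Over long runs the EMA converges to
  the live generator.
* **Explicit measurement noise.** The generator models the smooth
  class-conditional signal; white measurement noise with σ estimated from
  pooled within-class training residuals is added to generated samples
  wherever they are compared with or substituted for real ones. Without
  this the classifier (or critic) can separate real from generated by
  noise level alone and never learns the class structure.
* **Per-class feature matching** on the critic trunk restrains adversarial
  overshoot (the generator exaggerating a class signature beyond the real
  data).

### Determinism

All randomness flows from one seeded root `numpy` generator with named
substreams (splitting, initialization, pre-training, training); identical
config + seed reproduces the training log bit-for-bit. Classifier
probability ties break to the lowest class index.

## Baselines and evaluation protocol

SMOTE and Borderline-SMOTE (variant 1, DANGER membership with the
inclusive m/2 lower bound) are implemented from their defining rules with
round-robin parent selection for guaranteed coverage; distances are
Euclidean on the normalized value vectors. The evaluation protocol draws
an imbalanced training split (simple stratified random sampling; the split
is shared across methods within a repetition so paired one-sided t-tests
apply), trains the method, and scores per-class and macro precision,
recall and F = 2PR/(P+R) on all held-out spectra, with the
zero-denominator convention P, R, F = 0. Repetition counts, seeds and
aggregation (mean ± sd) follow one base seed. The interpolation baselines
clamp k to the largest feasible neighbor count when the minority class is
smaller than k+1.

## The synthetic data generator

Real spectra are emulated as: linear baseline + Gaussian dip (class-
dependent center/width/depth, in phase-angle degrees), per-spectrum peak
jitter (σ = 0.03 of the axis), additive white Gaussian noise (σ = 1.5°),
and a `similarity` knob blending every class mean toward the across-class
average — at 1.0 the class means coincide while jitter keeps full
strength, emulating the supramolecular case whose solution and gel spectra
are nearly identical. Default length is 200 (800 remains available); the
scaled-down experiments use 128. A plate-scan generator morphs the curve
logistically across 96 wells and returns the true transition well, giving
the labeling procedures a ground truth. What the simulator does **not**
model: autocorrelated instrument noise, multi-peak spectra, baseline
drift between experiments, and any composition–property nonlinearity
beyond the logistic morph — conclusions about real instruments therefore
require real data.

## Phase labeling

Both procedures act on one scalar summary per well (default: value at the
dip position, auto-detected as the argmin of the across-well mean
spectrum; this scalar responds linearly to the sol→gel morph, which the
extremal reducers distort). Sigmoid labeling fits a 4-parameter logistic
by least squares (plateau/steepest-difference initialization, up to 5
jittered restarts) and places the transition at the smallest well index
strictly above the inflection. Two-line labeling fits OLS lines to both
sides of every admissible breakpoint (≥ 3 points per side), picks the
minimum total RSS (ties to the smallest breakpoint), and takes the ceiling
of the lines' intersection; parallel or out-of-range intersections fall
back to the breakpoint with a warning.

## Problem sizes and expected behaviour

The shipped experiment preset (`ThreePlayerConfig.scaled_down()`) uses
length-128 spectra, kernel counts (16,32,32,64)/(32,32,16,1)/(16,16,32,64),
latent dimension 32, 30 pre-training + 10 warm-up + 40 training epochs —
sizes chosen so a full repeated comparison runs on a single CPU core in
minutes. Under the default simulator conditions (well-separated classes,
majority 150 / minority 4) the three-player classifier lifts macro F from
the collapsed baseline (≈ 0.2–0.4) to ≈ 0.96–1.0 across seeds, on par
with SMOTE. In the high-similarity regime (similarity 0.9) both the
three-player model and its frozen pretrained-generator ablation stay well
below SMOTE: with four minority samples, residual decoder artifacts exceed
the subtle class signature, whereas SMOTE's interpolants lie exactly on
the real-sample manifold and preserve it by construction. This is a known
limitation of from-scratch generative augmentation at very small minority
counts and desk-scale training budgets; the corresponding comparison is
reported as-is by `scripts/acceptance.py`.
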