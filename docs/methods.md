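# Methods

`fundusgru` implements a prognostic model for longitudinal colour-fundus
imaging: given a short sequence of photographs of one eye taken at
uneven intervals, predict whether the eye will have progressed to
advanced disease at a later visit. This note records the model, the
choices made where the design was genuinely open, and what the synthetic
test bed does and does not establish.

## Model

Given images X_0, …, X_N at times t_0 < … < t_N and a prediction
horizon t_{N+1} > t_N, the model computes

1. **Shared-weight CNN features.** One convolutional network (the same
   weights at every visit) maps each image to a feature vector of
   length F. Two backbones are provided: the full InceptionV3 graph
   (F = 2048) and a small three-block CNN (`tiny_cnn`, F configurable,
   default 64) that trains from scratch on a CPU in minutes.
2. **Interval scaling.** Each visit's feature vector is multiplied by
   w_i = 1/(t_{N+1} − t_i). Later visits have smaller gaps to the
   horizon and therefore strictly larger weights. The weights are a
   deterministic function of the recorded times — nothing is learned —
   and enter the network as a non-trainable per-visit input, keeping the
   graph differentiable with respect to images only.
3. **Recurrent fusion.** The scaled vectors, stacked as a T×F matrix,
   are consumed in time order by a single-unit GRU; a sigmoid maps its
   final state to a probability of progression. "Single unit" is the
   reading of a recurrent head that "results in a single value"; the
   CAM-capable variant (below) widens this to 8 units plus a dense
   layer, with the same probabilistic contract.

A terminological note: the interval weighting is sometimes described as
a triangular (smoothing) window, but the defining formula
1/(t_{N+1} − t_i) is reciprocal, not triangular. This package
implements the formula as printed and does not attempt a triangular
variant. Weights are deliberately **not** normalized to sum to one (the
formula has no normalization); `apply_scaling(..., normalize=True)`
exists for ablations only. The formula is unit-dependent; months are
used throughout.

### Neural-network engine

No deep-learning framework is part of the dependency set; the models
run on a small reverse-mode autodiff engine inside the package
(`fundusgru.nn`): tensors over numpy arrays, convolution as shifted
matrix products, max/average pooling, batch normalization, GRU, Adam,
and a numerically stable binary cross-entropy on logits. Every operator
is verified against central finite differences in the test suite.
InceptionV3 is built from these primitives with the standard mixed-block
channel plan (ending at 320+768+768+192 = 2048 channels before global
average pooling); its batch-norm layers are folded away (plain conv +
ReLU), which preserves the graph topology and all shapes. Pretrained
weights can be loaded from an `.npz` checkpoint on disk; nothing is
downloaded, and no test trains the large backbone.

## Preprocessing

- **Crop.** A pixel is foreground when the maximum over channels of its
  absolute difference from the background colour exceeds an offset
  (default 10/255; exposed as a flag). The crop is the tightest box
  containing all foreground pixels; a fully blank image raises.
  "Difference from background" had to be fixed somehow: max-over-channels
  was chosen over mean or luminance because it is the most conservative
  (keeps a pixel if *any* channel deviates).
- **Background colour.** When not supplied it is estimated as the median
  of the four 5×5 corner patches — fundus photographs have dark corners.
- **Intensity and geometry.** 8-bit values are divided by 255 (the input
  dtype is checked, so already-scaled floats are rejected rather than
  divided twice), the crop is resized bilinearly to a square target
  (256 default), and right-eye images are mirrored so the optic disc is
  always on the left. Coordinates are row-major, origin top-left, boxes
  half-open on the max side.
- **Eligibility.** From each eye's per-visit record, the most recent
  window of four consecutive visits whose first three are not
  advanced-stage is selected; the outcome is whether the fourth is
  advanced. Eyes with no qualifying window are dropped. "Most recent"
  is resolved by scanning windows from the latest backwards, so ties
  cannot arise.
- **Split.** Train/validation/test (60/20/20) is assigned at patient
  granularity: patients are shuffled with the seed and packed against
  eye-level targets from largest-remainder apportionment; a patient is
  added to the current split while that keeps the eye count at least as
  close to target as stopping would. Fellow eyes therefore never
  straddle a split.

## Training

`TrainSchedule` defaults mirror a common recipe: Adam at 1e-4, binary
cross-entropy, learning rate multiplied by 2/3 after 10 epochs without
validation improvement (zero min-delta), early stopping, and the
returned model is the checkpoint with minimum *validation* loss. Batch
size (16) and epoch limits are package choices, exposed as config.

The synthetic comparison study trains the small backbone from scratch,
which needs a stronger recipe than fine-tuning would: the study schedule
uses lr 3e-3, batch 8, and a fixed 60 epochs (`min_epochs=max_epochs`,
so stopping is deterministic). Two standard stabilizers are on by
default for the small backbone: batch normalization after each
convolution, and initializing the output bias to the training-set
log-odds so early epochs are spent on discrimination rather than on
matching the ~9% prior. Without these, from-scratch runs frequently
collapsed to the base rate.

## Synthetic data

The generator emulates the *structure* of a longitudinal AMD cohort,
not its appearance: a circular fundus field on a dark background, an
optic-disc blob on the nasal side (so the right-eye flip is
meaningful), and drusen as Gaussian-profile bright ellipses with
randomized eccentricity, count (2–12) and size. Four visits per eye
with gaps uniform on 6–12 months (uneven by construction; the true
inter-visit distribution of such cohorts is not pinned down, so it is
config), ~9.2% progression prevalence, and a second eye per patient
with probability 0.4. Progressing eyes scale drusen area by
(1 + r·Δt months); non-progressing eyes stay flat up to pixel noise
(σ = 0.02). Outcomes are independent Bernoulli draws per eye —
fellow-eye correlation is deliberately out of scope.

The growth rate r = 0.06/month was calibrated once, before any model
training, so that a crude drusen-area statistic at the last input visit
separates progressors at AUC ≈ 0.8 on ~200 eyes — an informative but
imperfect single-visit marker, leaving the visit-to-visit *trend* as
the extra signal a longitudinal model can use.

What passing the synthetic study shows: the pipeline is wired
correctly end to end, the interval-scaled sequence model can recover a
longitudinal signal a single image only partially carries, and the
activation maps land on the lesions that drive the label. What it does
not show: anything about real fundus photographs — no vessels, no media
opacity, no registration error, no label noise, no fellow-eye
correlation, and a far easier image-to-feature problem than real drusen
grading.

## Evaluation

All ROC machinery is implemented from first principles and
cross-checked against brute-force enumeration (and scikit-learn / pROC)
in the tests:

- **AUC** is the Mann–Whitney statistic with midrank tie handling.
- **Youden point** maximizes J = sens + spec − 1 over observed score
  thresholds (rule: positive iff score ≥ threshold). Ties in J break
  toward higher specificity (screening contexts), then lower threshold.
- **De Long CI/test** use the structural-components (placement-value)
  covariance estimator with midranks; normal-approximation intervals
  truncated to [0,1]; the paired test is two-sided. With perfectly
  separated scores the variance is zero and the interval collapses.
- **Bootstrap CIs** for sensitivity/specificity at the Youden point are
  stratified percentile intervals (B = 2000), with the threshold
  re-derived inside each resample by default (`refit_threshold=False`
  freezes it instead). Stratification guarantees both classes in every
  resample. Percentile rather than BCa: the simplest method consistent
  with standard practice.

## Activation maps

The CAM variant adds a dense layer after an 8-unit GRU. Maps are
computed in the classic linear fashion: each visit's spatial feature
maps (taken before the final pooling stage, for twice the spatial
resolution) are combined with the effective weights from pooled
features to the positive logit (GRU candidate-gate input weights
composed with the dense head), rectified, bilinearly upsampled, and
min-max normalized; a constant map is defined as all zeros. Because the
GRU is nonlinear, this linear path is an approximation — the standard
one when a recurrent head sits between pooling and output. Two details
matter in practice. First, a single-output recurrent bottleneck fixes
the feature-to-logit path only up to a global sign (a network can
encode "more drusen" with a feature that *lowers* its internal state
and still predict correctly), so the rectification keeps whichever sign
component carries more mass rather than blindly keeping positives.
Second, a gradient-weighted variant (`method="grad-cam"`) is available
for any head, including the plain single-unit model.

The localization check renders the generator's known drusen masks
through the same crop/resize/flip as the images and asks, for each
correctly classified progressing test eye, whether mean activation
inside the lesion region exceeds that outside at the last input visit;
the study requires this for ≥ 70% of such eyes.

## Study sizes and comparisons

The comparison study uses 280 patients (~400 eyes after second-eye
sampling), images preprocessed to 48×48 for the small backbone, and
three arms sharing cohort, split and seed: the interval-scaled
three-visit model, the same architecture without scaling, and a
single-visit (most recent image) baseline — all with the CAM-capable
head, which leaves predictive behaviour unchanged in form and lets the
localization check reuse the trained model. "The scaled model matches
or exceeds an ablation" is operationalized as: its AUC is numerically
greater or equal, or not significantly below by the package's own
paired De Long test (one-sided, 5%) — with near-ceiling AUCs on an
easy synthetic task, demanding strict numeric ordering would reduce to
a coin flip on ties. Monte-Carlo checks run 500 replicates at n = 1000
(CI coverage at true AUC 0.8) and 500 at n = 200 (type-I error of the
paired test under the null).

## Known limitations

- The engine is CPU-only, float32, and built for clarity over speed;
  InceptionV3 is usable for inference-scale work only.
- Batch-norm statistics make training-mode forward passes depend on
  batch composition; evaluation always uses running averages.
- The Youden threshold on small test sets (a handful of positives) is
  high-variance; the bootstrap CIs make that visible rather than fixing
  it.
- `select_eligible` assumes one image per visit and strictly increasing
  recorded times per eye.
- The generator's outcome-visit image renders a stylized atrophy patch
  for progressors; it is written for manifest completeness and never
  used as model input.
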