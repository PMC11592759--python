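# Methods

`tumorscope` implements a three-stage lung-CT analysis pipeline — lung
segmentation, nodule detection, 3-D tumor reconstruction — as desk-scale,
fully testable code.  Every stage is a statsmodels-style pair of a *Model*
class bound to data and a *Results* object returned by `fit()`; the
functional operation surface (`pixel_reward`, `iou`, `detect`,
`reconstruct`, ...) sits behind those classes and is what the unit tests
exercise directly.

All trainable networks run on a small in-repo reverse-mode automatic
differentiation engine over float64 numpy arrays (`tumorscope.nn`).  This
keeps the numerical stack self-contained and lets gradient correctness be
asserted against central finite differences at tight tolerance; at the
image sizes the package targets (32x32 slices, 16^3 volumes) numpy
convolutions are fast enough for full training runs inside a test suite.

## Synthetic phantoms

Real annotated chest CT (the kind of data the method is aimed at) cannot be
shipped with a package, so all experiments run on generated phantoms with
exact ground truth:

* a torso-like disk containing **two noisy-ellipse lungs** whose pixel share
  is calibrated by bisection into a configured interval strictly inside
  (0, 0.5) — lung tissue is always the minority class, reproducing the
  imbalance that motivates reward shaping;
* **spherical nodules** placed strictly inside lung tissue in 3-D index
  space; the per-slice tumor cross-sections are exact planar sections of the
  ground-truth occupancy volume, so stacking them reproduces the volume
  voxel for voxel;
* per-slice binary lung masks, tight half-open bounding boxes per nodule per
  slice, and additive Gaussian intensity noise clipped to [0, 1].

Defaults: 32x32 slices, 6 slices per case, lung fraction 0.08-0.18
(roughly the share lungs occupy in a mid-thorax CT slice), 1-2 nodules of
radius 1.5-3 px, noise sd 0.03.  What phantoms do **not** emulate: HU
calibration, anatomy beyond two ellipses, textured parenchyma,
radiologist disagreement.  Passing tests therefore demonstrate that the
algorithms are implemented correctly and behave as designed under
controlled imbalance — not that they reach clinical accuracy on real CT.

Preprocessing follows the usual recipe: per-slice min-max normalisation to
[0, 1] (constant slices map to zero by convention), rotation / zoom /
horizontal-flip augmentation applied identically to image and mask (masks
resampled nearest-neighbour to stay binary), bilinear resizing for images.
Coordinates are 0-based row-major (y, x); boxes are half-open
[x_min, x_max) x [y_min, y_max).

## Segmentation: reward-shaped policy gradient

The generator is a 12-layer U-Net-style encoder–decoder emitting a per-pixel
lung probability `pi(a=1|s)`, read as a stochastic per-pixel policy.  The
shaped reward is

    R = +1 / -1   for correct / incorrect minority (lung) pixels
    R = +lam / -lam for correct / incorrect majority pixels,  0 < lam < 1

with tuned default `lam = 0.4`.  Parameters ascend
`alpha * grad sum_t log pi(a_t|s_t) * Rbar` (default `alpha = 0.01`, SGD
with momentum 0.9 and weight decay 1e-4).

Two episode readings are implemented (`reward_aggregation`):

* `"pixel"` (default): each pixel is one step `t` of the episode and its own
  reward weights its log-probability term.  This is the reading under which
  reward-shaped RL for imbalanced classification actually learns.
* `"image"`: the literal collapsed form — the image-mean reward `Rbar`
  weights the whole log-policy sum.  Kept for completeness; at desk scale
  its learning signal is buried in the score-function noise and the
  all-background policy is an absorbing state, so it does not train.

The single-step operation `policy_gradient_step` implements the literal
update (sampled Bernoulli actions, scalar `Rbar` weighting, plain ascent, no
baseline or entropy term) and is verified against central finite differences
of `sum log pi(a|s) * Rbar`.

Training-loop numerical choices, each of which was necessary in practice:

* **Entropy regularisation**, weight annealed 0.5 → 0.02 across epochs.
  Without it any reward-maximising policy saturates toward the majority
  class, where the `p(1-p)` factor of the policy gradient vanishes and
  learning freezes; with it the per-class equilibrium logits
  (`-2 lam / beta` and `+2 / beta`) straddle the decision threshold.
* **Estimator choice** (`estimator`): `"sampled"` (default) averages the
  REINFORCE estimator over `action_samples = 2` action maps per step;
  `"expected"` uses the exact two-point expectation
  `grad p * (R(1) - R(0))` (zero-variance Rao-Blackwellisation).
* **Minority/majority trade-off**: maximising expected shaped reward is a
  weighted-accuracy surrogate, linear in the probability; it is weaker in
  the tails than log loss.  The cross-entropy ablation arm (`use_rl=False`)
  therefore matches or beats the RL arm whenever plain cross-entropy does
  not itself collapse from imbalance — a scale-dependent caveat worth
  keeping in mind when reading the package's ablation outputs.

The Earth-Mover critic scores the slice multiplied pixel-wise by a candidate
mask (generated vs reference); its loss is the difference of mean scores.
Dilated convolutions (rates 1, 2, 4) widen its receptive field.  Lipschitz
control is by weight clipping (bound 0.05) — the engine is first-order, so a
gradient penalty is not expressible.  An optional second input channel
carries the nodule-masked slice, and `critic_feedback` (default off) adds
the critic score to the generator objective.

## Detection: adversarially refined region proposals

A small convolutional backbone (feature stride 2) scores a dense grid of
square anchors (single scale, default 8 px; single aspect ratio) and
regresses normalised box offsets, in the Mask-R-CNN mould at toy scale.
The generator loss is the exact sum `L_G = L_cls + L_box + L_adv`: binary
cross-entropy over sampled anchors (positive fraction 0.33), smooth-L1 (unit
transition) on offsets of positive anchors, and `mean(-log Db(...))` over
RoI-pooled feature patches of predicted boxes.  The box discriminator sees
ground-truth and predicted patches channel-concatenated and trains with the
standard form `mean(-[log Db(real) + log(1 - Db(fake))])`; the printed
source formula applies `Db` twice in its fake term, which we read as a typo
for the standard form.  Probabilities are clamped at 1e-7 before logs.
Detections below the tuned score threshold 0.6 are suppressed, as are
anchors whose image patch is entirely zero — candidates must lie inside
segmented lung tissue, which also guarantees a blank input yields no boxes.

## Reconstruction: slice sequence to volume

Ordered tumor slices are embedded by a VGG-pattern encoder (paired 3x3
convolutions, 2x pooling, dense projection; pluggable against a plain CNN),
aggregated by an LSTM (toy default 64 units x 1 layer, dropout 0.25;
the tuned full-scale configuration is 512 x 3) with additive attention
producing a convex combination of hidden states, and decoded by a volume
generator (dense projection to a coarse grid, two upsample + 3-D convolution
stages, sigmoid).  A 3-D EM critic with dilated convolutions (1, 2, 4)
scores generated against reference volumes.  The generator objective adds a
voxel-wise binary cross-entropy reconstruction term (weight 1.0) to the
adversarial term (weight 0.05): a purely adversarial conditional generator
has no incentive to match the particular case it is conditioned on, so the
content term is what makes per-case validation metrics meaningful.
Optimisation is Adam with the tuned lr 2e-4, beta1 0.5.  Slice order is
ascending `slice_index`; the critic sees volumes only.

## Evaluation metrics

* `iou`: |A∩B|/|A∪B| over non-zero pixel sets; both-empty := 1 (perfect
  agreement), one-sided-empty := 0.
* `hausdorff`: symmetric max-min point-set distance (KD-tree nearest
  neighbours); directed variant exposed; exact agreement with brute-force
  double-loop enumeration is asserted in tests.
* `euclidean3`: the pointwise 3-D distance.
* `surface_metrics`: volumes are binarised at a threshold in (0, 1)
  (default 0.5) and scaled by voxel spacing; `hd` is the Hausdorff distance
  over occupied voxels and `ed` the symmetric mean nearest-neighbour
  distance between boundary voxels, which reduces to the pointwise distance
  for single-voxel volumes.  Per-case values are aggregated by the mean, a
  documented choice (the aggregation is not standardised anywhere we could
  anchor it).
* Training curves score an empty predicted volume as the volume diagonal —
  the worst geometrically possible disagreement — rather than failing.

## Experiments

Stratified partitioning uses nodule presence x lung-fraction tercile as the
stratum key and a single global dealing cursor, keeping per-stratum and
overall fold sizes within one; default 5 folds.  The reward-scale sweep
covers {0.1, ..., 0.9}: the endpoints would erase the minority/majority
asymmetry the reward table requires.  `run_pipeline` trains all three stages
and writes one CSV row per case (`case_id, seg_iou, seg_hd, det_iou, det_hd,
rec_hd, rec_ed`); every number is recomputable from saved artifacts with the
metrics module alone, and identical configuration + seeds reproduce the CSV
byte for byte.  Paired t-tests use the classical n-1-df formula and reject
zero-variance differences.

## Problem sizes used by the test suite

Training-dependent tests run at desk scale, chosen so the whole suite
completes comfortably on one CPU: 10 phantoms of 6 32x32 slices for the
segmentation ablation (40 epochs, batch 8, 5 seeds), 10 ellipsoid tumors of
16^3 voxels for reconstruction (15-25 epochs, 5 seeds), 3-6 cases and 2-8
epochs for smoke and determinism checks.  Table-scale hyperparameters
(batch 64, 512 LSTM units) remain the config defaults; desk-scale runs
override batch size because a 64-image batch exceeds the whole toy training
set and collapses training to one update per epoch.

## Known limitations

* Benchmark-grade accuracies achievable with clinical-scale datasets and
  GPU training budgets (segmentation IoU well above 0.9) are out of reach
  of the phantom scale by design; directional and exactness properties are
  tested instead.
* At desk scale the reward-shaped RL arm does not outperform the plain
  cross-entropy ablation (see the trade-off note above); the package
  reports both arms honestly.
* The detection stage implements head losses only (no RPN loss split) and a
  single anchor scale/ratio.
* The engine is first-order: no gradient-penalty critics, no higher-order
  optimisation.
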