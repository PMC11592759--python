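# tumorscope

Desk-scale toolkit for three connected problems in lung-CT image analysis:

1. **Lung segmentation under class imbalance.**  Lung pixels are a small
   minority of a CT slice, so a plain per-pixel classifier drifts toward
   predicting background everywhere.  The segmentation stage treats the
   U-Net's probability map as a per-pixel stochastic policy and trains it by
   policy gradient with a shaped reward

       R(s, a, y) = +1 / -1      correct / incorrect lung pixel (minority DL)
                    +λ / -λ      correct / incorrect background pixel (DN),

   0 < λ < 1 (default 0.4), via the ascent rule
   θ' = θ + α Σ_t ∇ log π_θ(a_t|s_t) · R̄_t.  An Earth-Mover critic with
   dilated convolutions scores slices multiplied pixel-wise by candidate
   masks, with loss E[D(G(x)∘I)] − E[D(x_real)].

2. **Nodule detection inside segmented lungs.**  An anchor-based
   region-proposal head (Mask-R-CNN style, single scale/ratio) is trained
   with L_G = L_cls + L_box + L_adv, where the adversarial term
   (1/N) Σ −log D_b(G_b(RoI_i)) scores RoI feature patches of predicted
   boxes against a box discriminator that sees real and generated patches
   together.

3. **3-D tumor reconstruction from a 2-D slice sequence.**  A VGG-pattern
   encoder embeds each tumor slice, an LSTM with additive attention collapses
   the sequence into a context vector, and a volume-generating GAN (3-D
   critic with dilated convolutions) decodes it into an occupancy volume.

Evaluation uses IoU = |A∩B|/|A∪B|, the symmetric Hausdorff distance
HD(A,B) = max(h(A,B), h(B,A)) with h(A,B) = max_{a∈A} min_{b∈B} ‖a−b‖,
and the 3-D Euclidean distance, all implemented exactly and tested against
brute-force enumeration oracles.

Because annotated clinical CT cannot ship in a package, everything runs on
**synthetic phantoms** with exact ground truth: two noisy-ellipse lungs
whose pixel share is calibrated into a configured minority interval,
spherical nodules sectioned consistently between per-slice masks/boxes and
the 3-D volume, and Gaussian intensity noise.  Who this is for: anyone who
wants the formulas, training rules and metrics of this pipeline as small,
inspectable, deterministic code — for teaching, for property testing, or as
a reference when scaling the ideas up on real data.

All networks run on an in-repo float64 reverse-mode autodiff engine
(`tumorscope.nn`) — no deep-learning framework required.

## Worked example

```python
from tumorscope import (PhantomConfig, generate_phantom_dataset,
                        LungSegmentationModel, SegTrainConfig, RewardConfig)

cases = generate_phantom_dataset(
    PhantomConfig(image_size=32, n_slices=6,
                  lung_fraction_range=(0.05, 0.15), seed=7),
    n_cases=10, seed=1)
model = LungSegmentationModel(cases,
                              SegTrainConfig(epochs=40, batch_size=8, seed=0),
                              RewardConfig(lam=0.4))
res = model.fit(use_rl=True)
print(res.summary())
```

prints

```
Lung segmentation fit
=====================
training mode:     policy gradient (RL)
lam (majority reward scale): 0.4
epochs:            40
generator params:  21537
final mean reward: +0.4299
final critic loss: -0.0000
final val IoU:     0.7247
final val HD:      2.1999
```

The mean shaped reward has climbed from ~0 (random policy) to 0.43 —
close to the all-correct ceiling (1−f)·λ + f·1 ≈ 0.46 at a lung fraction
f ≈ 0.10 — and the
held-out IoU of 0.72 with a mean boundary Hausdorff distance of 2.2 px says
the policy recovers the lung shapes to within about two pixels at their
worst point.  `res.history` carries the full per-epoch trajectory
(`epoch, mean_reward, critic_loss, val_iou, val_hd`);
`res.segment(slice)` applies the trained policy; the `use_rl=False`
ablation arm trains the same network by plain cross-entropy.

The detection and reconstruction stages follow the same pattern
(`TumorDetectionModel`, `TumorReconstructionModel`), and
`tumorscope.experiments.run_pipeline` chains all three, writing one CSV row
per case with segmentation, detection and reconstruction metrics.

A CLI wraps the library:

```bash
tumorscope phantom --out data/ --n-cases 10 --seed 1
tumorscope train-seg --data data/ --out run/ --seed 0
tumorscope evaluate --pred run_pred/ --truth data/ --out metrics.csv
tumorscope sweep-lambda --data data/ --out sweep/
tumorscope run-all --out results/ --seed 0
```

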