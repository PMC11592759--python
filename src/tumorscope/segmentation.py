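"""Imbalance-aware lung segmentation: a U-Net policy trained by reward shaping.

The generator is a per-pixel stochastic policy: for slice ``I`` it outputs a
probability map ``pi(a=1 | s)`` of each pixel belonging to the lung.  Because
lung pixels are a small minority, plain pixel-wise training is biased toward
the background class.  Training therefore uses a shaped reward

    R(s, a, y) = +1  if a == y and the pixel is lung        (minority, DL)
                 -1  if a != y and the pixel is lung
                 +lam if a == y and the pixel is background (majority, DN)
                 -lam if a != y and the pixel is background

with 0 < lam < 1, so minority-class decisions carry more weight than the
abundant background ones.  Parameters ascend the policy gradient

    theta' = theta + alpha * sum_t grad log pi(a_t | s_t) * Rbar_t

where one episode is one image and all pixels act simultaneously as
independent Bernoulli draws from the probability map.  The single-step
operation :func:`policy_gradient_step` implements the literal form in which
the image-mean reward ``Rbar`` weights the whole log-policy sum; the
training loop defaults to reading each pixel as one step ``t`` carrying its
own reward (``reward_aggregation="pixel"``), the variant under which this
kind of reward shaping learns at small scale — see docs/methods.md.

An Earth-Mover-style critic with dilated convolutions scores the slice
multiplied pixel-wise by the candidate mask (generated vs reference); its
loss is the difference of mean scores, ``E[D(G(x) o I)] - E[D(x_real)]``.
The critic is kept approximately Lipschitz by weight clipping and can
optionally feed an adversarial term back into the generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics
from .datatypes import MaskImage, PhantomCase, SliceImage
from .nn import SGD, Conv2d, Module, Tensor, no_grad

__all__ = [
    "RewardConfig", "PixelDecision", "SegTrainConfig", "UNetPolicy",
    "DilatedCritic", "pixel_reward", "average_reward", "reward_map",
    "policy_gradient_step", "masked_product", "critic_loss",
    "train_segmentation", "segment", "LungSegmentationModel",
    "SegmentationResults",
]


# --------------------------------------------------------------------------
# reward shaping
# --------------------------------------------------------------------------

@dataclass
class RewardConfig:
    """Reward-shaping parameter lam scaling majority-class rewards."""

    lam: float = 0.4

    def __post_init__(self):
        if not (0.0 < self.lam < 1.0):
            raise ValueError("lam must satisfy 0 < lam < 1")


@dataclass
class PixelDecision:
    """One pixel's state: predicted action, ground truth and class."""

    action: int
    truth: int

    def __post_init__(self):
        if self.action not in (0, 1) or self.truth not in (0, 1):
            raise ValueError("action and truth must be binary")

    @property
    def minority(self) -> bool:
        """True when the pixel belongs to the lung class DL (truth == 1)."""
        return self.truth == 1


def pixel_reward(decision: PixelDecision, cfg: RewardConfig) -> float:
    """Shaped reward for one pixel decision (the four-branch table above)."""
    correct = decision.action == decision.truth
    if decision.minority:
        return 1.0 if correct else -1.0
    return cfg.lam if correct else -cfg.lam


def reward_map(actions: np.ndarray, truth: np.ndarray,
               cfg: RewardConfig) -> np.ndarray:
    """Vectorised per-pixel rewards for whole masks."""
    actions = np.asarray(actions)
    truth = np.asarray(truth)
    if actions.shape != truth.shape:
        raise ValueError("action and truth shapes differ")
    if not (np.isin(actions, (0, 1)).all() and np.isin(truth, (0, 1)).all()):
        raise ValueError("actions and truth must be binary")
    correct = actions == truth
    minority = truth == 1
    sign = np.where(correct, 1.0, -1.0)
    magnitude = np.where(minority, 1.0, cfg.lam)
    return sign * magnitude


def average_reward(decisions: list[PixelDecision], cfg: RewardConfig) -> float:
    """Arithmetic mean reward across all pixels of an image."""
    if not decisions:
        raise ValueError("average reward of an empty decision list is undefined")
    return float(np.mean([pixel_reward(d, cfg) for d in decisions]))


# --------------------------------------------------------------------------
# networks
# --------------------------------------------------------------------------

class UNetPolicy(Module):
    """Small encoder-decoder producing a per-pixel lung probability map.

    Two resolution levels with skip connections; 12 convolutional layers at
    the default width, the tuned layer count for the segmentation generator.
    Output is a sigmoid probability strictly inside (0, 1).
    """

    def __init__(self, rng: np.random.Generator, base_channels: int = 8):
        c = base_channels
        self.enc0 = [Conv2d(1, c, 3, rng), Conv2d(c, c, 3, rng)]
        self.enc1 = [Conv2d(c, 2 * c, 3, rng), Conv2d(2 * c, 2 * c, 3, rng)]
        self.mid = [Conv2d(2 * c, 4 * c, 3, rng), Conv2d(4 * c, 2 * c, 3, rng)]
        self.dec1 = [Conv2d(4 * c, 2 * c, 3, rng), Conv2d(2 * c, c, 3, rng)]
        self.dec0 = [Conv2d(2 * c, c, 3, rng), Conv2d(c, c, 3, rng)]
        self.head = [Conv2d(c, c, 3, rng), Conv2d(c, 1, 1, rng)]

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, 1, H, W) -> probability map (N, 1, H, W) in (0, 1)."""
        h0 = self.enc0[1](self.enc0[0](x).relu()).relu()
        h1 = self.enc1[1](self.enc1[0](h0.avg_pool2d(2)).relu()).relu()
        m = self.mid[1](self.mid[0](h1.avg_pool2d(2)).relu()).relu()
        from .nn import concat
        u1 = concat([m.upsample2d(2), h1], axis=1)
        d1 = self.dec1[1](self.dec1[0](u1).relu()).relu()
        u0 = concat([d1.upsample2d(2), h0], axis=1)
        d0 = self.dec0[1](self.dec0[0](u0).relu()).relu()
        return self.head[1](self.head[0](d0).relu()).sigmoid()

    def prob_map(self, pixels: np.ndarray) -> np.ndarray:
        """Inference helper: (H, W) image -> (H, W) probability map."""
        with no_grad():
            out = self.forward(Tensor(pixels[None, None]))
        return out.data[0, 0]


class DilatedCritic(Module):
    """EM-distance critic over mask-multiplied slices.

    Dilated convolutions widen the receptive field without losing
    resolution; the score is an unbounded scalar per image (the critic is a
    regressor approximating the Earth-Mover discrepancy, not a classifier).
    An optional second channel carries the nodule-masked slice.
    """

    def __init__(self, rng: np.random.Generator, channels: int = 8,
                 dilation_rates: tuple[int, ...] = (1, 2, 4),
                 in_channels: int = 1):
        if not any(r > 1 for r in dilation_rates):
            raise ValueError("at least one dilation rate must exceed 1")
        self.convs = []
        c_in = in_channels
        for rate in dilation_rates:
            self.convs.append(Conv2d(c_in, channels, 3, rng, dilation=rate))
            c_in = channels
        self.head = Conv2d(c_in, 1, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, C, H, W) -> scores (N,)."""
        h = x
        for conv in self.convs:
            h = conv(h).leaky_relu(0.2)
        return self.head(h).mean(axis=(1, 2, 3))

    def clip_weights(self, bound: float = 0.05) -> None:
        for p in self.parameters():
            np.clip(p.data, -bound, bound, out=p.data)


# --------------------------------------------------------------------------
# losses and the policy update
# --------------------------------------------------------------------------

def masked_product(x, m):
    """Pixel-wise product of an image and a mask (the 'o' operator)."""
    if isinstance(x, Tensor) or isinstance(m, Tensor):
        xt = x if isinstance(x, Tensor) else Tensor(x)
        mt = m if isinstance(m, Tensor) else Tensor(m)
        if xt.shape != mt.shape:
            raise ValueError("shape mismatch in masked product")
        return xt * mt
    x, m = np.asarray(x, dtype=float), np.asarray(m, dtype=float)
    if x.shape != m.shape:
        raise ValueError("shape mismatch in masked product")
    return x * m


def critic_loss(d_fake_scores, d_real_scores) -> float:
    """EM-style critic objective: mean fake score minus mean real score."""
    fake = np.asarray(d_fake_scores, dtype=float).ravel()
    real = np.asarray(d_real_scores, dtype=float).ravel()
    if fake.size == 0 or real.size == 0:
        raise ValueError("critic loss needs non-empty score batches")
    return float(fake.mean() - real.mean())


def policy_log_prob(prob: Tensor, actions: np.ndarray) -> Tensor:
    """Sum over pixels of log pi(a | s) for sampled binary actions."""
    a = Tensor(actions.astype(np.float64))
    eps = 1e-12
    log_p = (prob + eps).log() * a + (1.0 - prob + eps).log() * (1.0 - a)
    return log_p.sum()


def policy_gradient_step(gen: Module, image: SliceImage, truth: MaskImage,
                         reward_cfg: RewardConfig, alpha: float,
                         rng: np.random.Generator,
                         baseline: float = 0.0) -> dict[str, float]:
    """One exact policy-gradient ascent step on a single image episode.

    Samples per-pixel Bernoulli actions from the probability map, computes
    the mean shaped reward Rbar, and moves parameters along
    ``alpha * grad sum_pixels log pi(a|s) * (Rbar - baseline)``.  With
    ``alpha == 0`` or zero net reward the parameters are unchanged.
    """
    if image.pixels.shape != truth.shape:
        raise ValueError("image and truth shapes differ")
    gen.zero_grad()
    prob = gen(Tensor(image.pixels[None, None]))
    if not (0.0 < prob.data.min() and prob.data.max() < 1.0):
        raise FloatingPointError("policy probabilities left (0, 1)")
    actions = (rng.random(prob.shape) < prob.data).astype(np.uint8)
    rewards = reward_map(actions[0, 0], truth.labels, reward_cfg)
    r_bar = float(rewards.mean())
    objective = policy_log_prob(prob, actions) * (r_bar - baseline)
    objective.backward()
    for p in gen.parameters():
        if p.grad is not None:
            if np.isnan(p.grad).any():
                raise FloatingPointError("NaN in policy gradients")
            p.data += alpha * p.grad
    return {"mean_reward": r_bar, "objective": objective.item(),
            "actions": actions[0, 0]}


def segment(gen: UNetPolicy, image: SliceImage,
            threshold: float = 0.5) -> MaskImage:
    """Binarize the generator's probability map at ``threshold``."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    prob = gen.prob_map(image.pixels)
    return MaskImage((prob >= threshold).astype(np.uint8))


# --------------------------------------------------------------------------
# training (Model / Results)
# --------------------------------------------------------------------------

@dataclass
class SegTrainConfig:
    """Training configuration; defaults are the tuned segmentation optima
    (learning rate 0.01, lam 0.4 via RewardConfig, batch 64, momentum 0.9,
    weight decay 1e-4, 12-layer generator)."""

    alpha: float = 0.01
    epochs: int = 20
    batch_size: int = 64
    momentum: float = 0.9
    weight_decay: float = 0.0001
    base_channels: int = 8
    critic_channels: int = 8
    dilation_rates: tuple[int, ...] = (1, 2, 4)
    critic_clip: float = 0.05
    critic_feedback: bool = False
    critic_feedback_weight: float = 0.01
    nodule_channel: bool = False
    use_baseline: bool = True
    baseline_momentum: float = 0.9
    action_samples: int = 2  # Monte-Carlo action maps per image per step
    reward_aggregation: str = "pixel"  # "pixel" | "image" (see module docs)
    estimator: str = "sampled"  # "sampled" | "expected" (Rao-Blackwellised)
    entropy_weight: float = 0.5  # exploration bonus; prevents policy collapse
    entropy_weight_end: float = 0.02  # annealed linearly across epochs
    val_fraction: float = 0.2
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("learning rate alpha must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class SegmentationResults:
    """Fitted segmentation stage: trained networks plus per-epoch history."""

    generator: UNetPolicy
    critic: DilatedCritic
    history: pd.DataFrame
    config: SegTrainConfig
    reward_config: RewardConfig
    use_rl: bool

    def segment(self, image: SliceImage,
                threshold: float | None = None) -> MaskImage:
        return segment(self.generator, image,
                       threshold or self.config.threshold)

    def evaluate(self, cases: list[PhantomCase]) -> pd.DataFrame:
        rows = []
        for case in cases:
            for img, mask in zip(case.slices, case.masks):
                pred = self.segment(img)
                row = {"case_id": case.case_id, "slice_index": img.slice_index,
                       "iou": metrics.iou(pred, mask)}
                if pred.labels.any() and mask.labels.any():
                    row["hd"] = metrics.hausdorff(np.argwhere(pred.labels),
                                                  np.argwhere(mask.labels))
                else:
                    row["hd"] = np.nan
                rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Lung segmentation fit",
            "=====================",
            f"training mode:     {'policy gradient (RL)' if self.use_rl else 'cross-entropy (no RL)'}",
            f"lam (majority reward scale): {self.reward_config.lam}",
            f"epochs:            {len(self.history)}",
            f"generator params:  {self.generator.n_parameters()}",
        ]
        if len(self.history):
            last = self.history.iloc[-1]
            lines += [
                f"final mean reward: {last['mean_reward']:+.4f}",
                f"final critic loss: {last['critic_loss']:+.4f}",
                f"final val IoU:     {last['val_iou']:.4f}",
                f"final val HD:      {last['val_hd']:.4f}",
            ]
        return "\n".join(lines)


class LungSegmentationModel:
    """Segmentation stage bound to a set of phantom cases.

    ``fit`` trains the U-Net policy (reward-shaped policy gradient by
    default, plain pixel-wise cross-entropy with ``use_rl=False`` as the
    ablation arm) alongside the EM critic, and returns a
    :class:`SegmentationResults`.
    """

    def __init__(self, cases: list[PhantomCase],
                 config: SegTrainConfig | None = None,
                 reward_config: RewardConfig | None = None):
        if not cases:
            raise ValueError("need at least one case")
        self.cases = list(cases)
        self.config = config or SegTrainConfig()
        self.reward_config = reward_config or RewardConfig()

    def _split(self, rng: np.random.Generator):
        n = len(self.cases)
        n_val = max(1, int(round(self.config.val_fraction * n))) if n > 1 else 0
        order = rng.permutation(n)
        val_idx = set(order[:n_val].tolist())
        train = [c for i, c in enumerate(self.cases) if i not in val_idx]
        val = [c for i, c in enumerate(self.cases) if i in val_idx]
        return train, (val if val else train)

    def fit(self, use_rl: bool = True) -> SegmentationResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        gen = UNetPolicy(rng, base_channels=cfg.base_channels)
        critic_in = 2 if cfg.nodule_channel else 1
        critic = DilatedCritic(rng, channels=cfg.critic_channels,
                               dilation_rates=cfg.dilation_rates,
                               in_channels=critic_in)
        train_cases, val_cases = self._split(rng)

        images = np.stack([s.pixels for c in train_cases for s in c.slices])
        truths = np.stack([m.labels for c in train_cases for m in c.masks])
        nodule_masks = np.stack([(c.tumor_volume.voxels[i] > 0.5).astype(float)
                                 for c in train_cases
                                 for i, _ in enumerate(c.slices)])
        n_img = images.shape[0]

        gen_opt = SGD(gen.parameters(), lr=cfg.alpha, momentum=cfg.momentum,
                      weight_decay=cfg.weight_decay, maximize=use_rl)
        critic_opt = SGD(critic.parameters(), lr=cfg.alpha,
                         momentum=cfg.momentum)

        history = []
        baseline = 0.0
        for epoch in range(cfg.epochs):
            order = rng.permutation(n_img)
            epoch_rewards, epoch_closs = [], []
            for start in range(0, n_img, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                x = Tensor(images[idx][:, None])
                y = truths[idx]

                # ---- generator update
                gen.zero_grad()
                prob = gen(x)
                if use_rl:
                    eps = 1e-12
                    log_pos = (prob + eps).log()
                    log_neg = (1.0 - prob + eps).log()
                    lam = self.reward_config.lam
                    objective = None
                    r_means = []
                    if cfg.estimator == "expected":
                        # Rao-Blackwellised policy gradient: over a binary
                        # action space the REINFORCE expectation is exactly
                        # sum_a pi(a) grad log pi(a) R(a) = grad p (R1 - R0)
                        yf = y[:, None].astype(np.float64)
                        r1 = np.where(yf == 1, 1.0, -lam)
                        r0 = np.where(yf == 1, -1.0, lam)
                        objective = (prob * Tensor(r1)
                                     + (1.0 - prob) * Tensor(r0)).mean()
                        with no_grad():
                            sampled = (rng.random(prob.shape) < prob.data
                                       ).astype(np.uint8)
                        r_means.append(float(reward_map(
                            sampled[:, 0], y, self.reward_config).mean()))
                    elif cfg.estimator == "sampled":
                        # average the REINFORCE estimator over several
                        # sampled action maps (the network forward/backward
                        # is shared; extra samples cost only cheap
                        # elementwise work)
                        K = max(1, cfg.action_samples)
                        for _ in range(K):
                            actions = (rng.random(prob.shape) < prob.data
                                       ).astype(np.uint8)
                            rewards = reward_map(actions[:, 0], y,
                                                 self.reward_config)
                            r_bar = rewards.mean(axis=(1, 2))
                            r_means.append(float(r_bar.mean()))
                            a = Tensor(actions.astype(np.float64))
                            log_p = log_pos * a + log_neg * (1.0 - a)
                            if cfg.reward_aggregation == "pixel":
                                # each pixel is one step t of the episode
                                # and carries its own reward
                                weight = Tensor(rewards[:, None])
                            elif cfg.reward_aggregation == "image":
                                # literal collapsed form: the image-mean
                                # reward (minus a variance-reduction
                                # baseline) weights the log-policy sum
                                adv = r_bar - (baseline if cfg.use_baseline
                                               else 0.0)
                                weight = Tensor(adv.reshape(-1, 1, 1, 1))
                            else:
                                raise ValueError(
                                    f"unknown reward_aggregation "
                                    f"{cfg.reward_aggregation!r}")
                            term = (log_p * weight).mean() / float(K)
                            objective = term if objective is None \
                                else objective + term
                    else:
                        raise ValueError(
                            f"unknown estimator {cfg.estimator!r}")
                    beta = cfg.entropy_weight
                    if cfg.epochs > 1:
                        frac = epoch / (cfg.epochs - 1)
                        beta = (cfg.entropy_weight
                                + (cfg.entropy_weight_end
                                   - cfg.entropy_weight) * frac)
                    if beta > 0:
                        entropy = -(prob * log_pos
                                    + (1.0 - prob) * log_neg).mean()
                        objective = objective + entropy * beta
                    epoch_rewards.append(float(np.mean(r_means)))
                    if cfg.critic_feedback:
                        fake_in = self._critic_input(
                            prob, images[idx], nodule_masks[idx], cfg)
                        objective = objective + critic.forward(fake_in).mean() \
                            * cfg.critic_feedback_weight
                    objective.backward()
                    gen_opt.step()
                    if cfg.use_baseline:
                        m = cfg.baseline_momentum
                        baseline = m * baseline + (1 - m) * float(
                            np.mean(r_means))
                else:
                    yt = Tensor(y[:, None].astype(np.float64))
                    eps = 1e-12
                    bce = -((prob + eps).log() * yt
                            + (1.0 - prob + eps).log() * (1.0 - yt)).mean()
                    bce.backward()
                    gen_opt.step()
                    with no_grad():
                        actions = (prob.data >= 0.5).astype(np.uint8)
                    epoch_rewards.append(float(reward_map(
                        actions[:, 0], y, self.reward_config).mean()))

                # ---- critic update on masked slices
                critic.zero_grad()
                with no_grad():
                    fake_mask = gen(x)
                fake_in = self._critic_input(fake_mask, images[idx],
                                             nodule_masks[idx], cfg)
                real_in = self._critic_input(
                    Tensor(y[:, None].astype(np.float64)), images[idx],
                    nodule_masks[idx], cfg)
                c_obj = critic(fake_in).mean() - critic(real_in).mean()
                c_obj.backward()
                critic_opt.step()
                critic.clip_weights(cfg.critic_clip)
                epoch_closs.append(c_obj.item())

            val_iou, val_hd = self._validate(gen, val_cases, cfg.threshold)
            history.append({
                "epoch": epoch,
                "mean_reward": float(np.mean(epoch_rewards)),
                "critic_loss": float(np.mean(epoch_closs)),
                "val_iou": val_iou, "val_hd": val_hd,
            })

        return SegmentationResults(
            generator=gen, critic=critic,
            history=pd.DataFrame(
                history, columns=["epoch", "mean_reward", "critic_loss",
                                  "val_iou", "val_hd"]),
            config=cfg, reward_config=self.reward_config, use_rl=use_rl)

    @staticmethod
    def _critic_input(mask: Tensor, images: np.ndarray,
                      nodule_masks: np.ndarray, cfg: SegTrainConfig) -> Tensor:
        lung = masked_product(mask, Tensor(images[:, None]))
        if not cfg.nodule_channel:
            return lung
        from .nn import concat
        nod = Tensor((images * nodule_masks)[:, None])
        return concat([lung, nod], axis=1)

    @staticmethod
    def _validate(gen: UNetPolicy, cases: list[PhantomCase],
                  threshold: float) -> tuple[float, float]:
        ious, hds = [], []
        for case in cases:
            for img, mask in zip(case.slices, case.masks):
                pred = segment(gen, img, threshold)
                ious.append(metrics.iou(pred, mask))
                if pred.labels.any() and mask.labels.any():
                    hds.append(metrics.hausdorff(np.argwhere(pred.labels),
                                                 np.argwhere(mask.labels)))
        val_hd = float(np.mean(hds)) if hds else float("nan")
        return float(np.mean(ious)), val_hd


def train_segmentation(cases: list[PhantomCase],
                       cfg: SegTrainConfig | None = None,
                       reward: RewardConfig | None = None,
                       use_rl: bool = True) -> SegmentationResults:
    """Functional wrapper around :class:`LungSegmentationModel`."""
    return LungSegmentationModel(cases, cfg, reward).fit(use_rl=use_rl)
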