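"""Adversarially refined nodule detection inside segmented lung slices.

A lightweight region-proposal detector in the Mask-R-CNN mould, sized for
small slices: a convolutional backbone produces a feature map; a dense grid
of square anchors (single scale, single aspect ratio) is scored by a
classification head (nodule / background) and refined by a box-regression
head predicting normalised offsets.  The generator loss is

    L_G = L_cls + L_box + L_adv

where ``L_cls`` is binary cross-entropy on anchor scores, ``L_box`` a
smooth-L1 penalty on box offsets for positive anchors, and the adversarial
term ``L_adv = mean(-log Db(Gb(RoI)))`` scores RoI-pooled feature patches of
the predicted boxes with a box discriminator ``Db``.  ``Db`` itself sees the
feature patches of ground-truth and predicted boxes channel-concatenated and
is trained with the standard GAN discriminator loss
``mean(-[log Db(real) + log(1 - Db(fake))])``.

Probabilities are epsilon-clamped at 1e-7 before any logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics
from .datatypes import PhantomCase, SliceImage
from .nn import SGD, Conv2d, Linear, Module, Tensor, concat, no_grad

__all__ = [
    "BBoxPrediction", "DetLossTerms", "DetTrainConfig", "NoduleDetector",
    "BoxDiscriminator", "cls_loss", "box_loss", "adv_gen_loss",
    "generator_loss", "discriminator_loss", "detect", "train_detection",
    "TumorDetectionModel", "DetectionResults",
]

_EPS = 1e-7


@dataclass
class BBoxPrediction:
    """One detection: half-open pixel box plus nodule probability."""

    box: tuple[float, float, float, float]
    class_prob: float

    def __post_init__(self):
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate box {self.box}")
        if not (0.0 <= self.class_prob <= 1.0):
            raise ValueError("class_prob must lie in [0, 1]")


@dataclass
class DetLossTerms:
    """Logged loss components; the generator total is their exact sum."""

    l_cls: float
    l_box: float
    l_adv: float
    l_d: float

    @property
    def l_g(self) -> float:
        return self.l_cls + self.l_box + self.l_adv


# --------------------------------------------------------------------------
# loss primitives (closed forms, shared by training and tests)
# --------------------------------------------------------------------------

def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, _EPS, 1.0 - _EPS)


def cls_loss(pred_prob: float, truth: int) -> float:
    """Binary cross-entropy for one class prediction."""
    if truth not in (0, 1):
        raise ValueError("truth must be binary")
    p = float(_clamp(np.asarray(pred_prob, dtype=float)))
    return float(-(truth * np.log(p) + (1 - truth) * np.log(1.0 - p)))


def box_loss(pred_box, truth_box) -> float:
    """Smooth-L1 over the four box coordinates (transition at 1)."""
    d = np.asarray(pred_box, dtype=float) - np.asarray(truth_box, dtype=float)
    if d.shape != (4,):
        raise ValueError("boxes must have four coordinates")
    ad = np.abs(d)
    per = np.where(ad < 1.0, 0.5 * d**2, ad - 0.5)
    return float(per.sum())


def adv_gen_loss(d_scores) -> float:
    """Adversarial generator term: mean of -log discriminator scores."""
    s = np.asarray(d_scores, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("adversarial loss needs at least one score")
    return float(np.mean(-np.log(_clamp(s))))


def generator_loss(terms: DetLossTerms) -> float:
    """Exact sum L_cls + L_box + L_adv."""
    return terms.l_cls + terms.l_box + terms.l_adv


def discriminator_loss(d_real, d_fake) -> float:
    """Standard GAN discriminator loss, mean over the mini-batch."""
    real = _clamp(np.asarray(d_real, dtype=float).ravel())
    fake = _clamp(np.asarray(d_fake, dtype=float).ravel())
    if real.size == 0 or fake.size == 0:
        raise ValueError("discriminator loss needs non-empty batches")
    if real.size != fake.size:
        raise ValueError("real and fake batches must have equal size")
    return float(np.mean(-(np.log(real) + np.log(1.0 - fake))))


def _smooth_l1_tensor(diff: Tensor) -> Tensor:
    """Differentiable smooth-L1 (branch chosen from current values)."""
    quad = (np.abs(diff.data) < 1.0).astype(float)
    sign = np.sign(diff.data)
    return (Tensor(quad) * diff * diff * 0.5
            + Tensor(1.0 - quad) * (Tensor(sign) * diff - 0.5)).sum()


# --------------------------------------------------------------------------
# networks
# --------------------------------------------------------------------------

class NoduleDetector(Module):
    """Backbone + anchor classification/regression heads (the generator Gb).

    Single square anchor per grid cell (one scale, aspect ratio 1); the
    feature map has stride 2 relative to the input and anchors are laid out
    with a further stride of 2 feature cells.
    """

    def __init__(self, rng: np.random.Generator, channels: int = 8,
                 anchor_size: float = 8.0, anchor_stride: int = 4,
                 pool_size: int = 3):
        c = channels
        self.conv1 = Conv2d(1, c, 3, rng)
        self.conv2 = Conv2d(c, c, 3, rng)
        self.conv3 = Conv2d(c, c, 3, rng)
        self.score_head = Conv2d(c, 1, 1, rng)
        self.box_head = Conv2d(c, 4, 1, rng)
        self.channels = c
        self.anchor_size = anchor_size
        self.anchor_stride = anchor_stride  # in image pixels
        self.pool_size = pool_size
        self.feature_stride = 2

    def features(self, x: Tensor) -> Tensor:
        h = self.conv2(self.conv1(x).relu().avg_pool2d(2)).relu()
        return self.conv3(h).relu()

    def forward(self, x: Tensor):
        """x: (N,1,H,W) -> (features, score logits, box offsets per anchor)."""
        feats = self.features(x)
        step = self.anchor_stride // self.feature_stride
        scores = self.score_head(feats)[:, :, ::step, ::step]
        offsets = self.box_head(feats)[:, :, ::step, ::step]
        return feats, scores, offsets

    def anchor_grid(self, height: int, width: int) -> np.ndarray:
        """Anchor centres (n, 2) as (cy, cx) in image pixels."""
        step = self.anchor_stride
        cys = np.arange(step // 2, height, step, dtype=float)
        cxs = np.arange(step // 2, width, step, dtype=float)
        grid = np.stack(np.meshgrid(cys, cxs, indexing="ij"), axis=-1)
        return grid.reshape(-1, 2)

    def decode_boxes(self, offsets: np.ndarray, centres: np.ndarray,
                     height: int, width: int) -> np.ndarray:
        """Offsets (n, 4) as (tx, ty, tw, th) -> clipped pixel boxes (n, 4)."""
        a = self.anchor_size
        cx = centres[:, 1] + offsets[:, 0] * a
        cy = centres[:, 0] + offsets[:, 1] * a
        w = a * np.exp(np.clip(offsets[:, 2], -2, 2))
        h = a * np.exp(np.clip(offsets[:, 3], -2, 2))
        boxes = np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2],
                         axis=1)
        boxes[:, 0::2] = np.clip(boxes[:, 0::2], 0, width)
        boxes[:, 1::2] = np.clip(boxes[:, 1::2], 0, height)
        return boxes

    def encode_box(self, gt_box, centre) -> np.ndarray:
        """Ground-truth box -> regression target for an anchor centre."""
        a = self.anchor_size
        x0, y0, x1, y1 = gt_box
        gw, gh = max(x1 - x0, 1e-3), max(y1 - y0, 1e-3)
        gcx, gcy = (x0 + x1) / 2, (y0 + y1) / 2
        return np.array([(gcx - centre[1]) / a, (gcy - centre[0]) / a,
                         np.log(gw / a), np.log(gh / a)])

    def roi_pool(self, feats_one: Tensor, box, height: int,
                 width: int) -> Tensor:
        """Nearest-neighbour RoI pooling of one (C, Hf, Wf) feature map."""
        s = self.feature_stride
        P = self.pool_size
        x0, y0, x1, y1 = box
        Hf, Wf = feats_one.shape[1], feats_one.shape[2]
        rows = np.clip(((np.linspace(y0, y1, P, endpoint=False)
                         + (y1 - y0) / (2 * P)) / s).astype(int), 0, Hf - 1)
        cols = np.clip(((np.linspace(x0, x1, P, endpoint=False)
                         + (x1 - x0) / (2 * P)) / s).astype(int), 0, Wf - 1)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        return feats_one.take_pixels(rr, cc)


class BoxDiscriminator(Module):
    """Db: scores channel-concatenated RoI feature patches in (0, 1)."""

    def __init__(self, rng: np.random.Generator, channels: int = 8,
                 pool_size: int = 3):
        self.conv = Conv2d(2 * channels, channels, 3, rng)
        self.fc = Linear(channels * pool_size * pool_size, 1, rng)

    def forward(self, patch: Tensor) -> Tensor:
        """patch: (2C, P, P) -> scalar probability."""
        h = self.conv(patch.reshape(1, *patch.shape)).leaky_relu(0.2)
        return self.fc(h.reshape(1, -1)).sigmoid().reshape(())


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def _box_iou(a, b) -> float:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union > 0 else 0.0


def detect(detector: NoduleDetector, lung_image: SliceImage,
           score_threshold: float = 0.6,
           nms_iou: float = 0.3) -> list[BBoxPrediction]:
    """Detect nodules on a lung-masked slice.

    Anchors whose image patch is entirely zero (outside segmented lung
    tissue) are suppressed, so a blank input yields no detections.  Emitted
    boxes are clipped to the image and pruned by greedy non-maximum
    suppression; ``score_threshold`` defaults to the tuned mask threshold.
    """
    px = lung_image.pixels
    H, W = px.shape
    with no_grad():
        _, scores, offsets = detector(Tensor(px[None, None]))
    probs = 1.0 / (1.0 + np.exp(-scores.data[0, 0].ravel()))
    offs = offsets.data[0].reshape(4, -1).T
    centres = detector.anchor_grid(H, W)
    boxes = detector.decode_boxes(offs, centres, H, W)

    a = detector.anchor_size
    keep = []
    for i, (cy, cx) in enumerate(centres):
        y0, y1 = int(max(0, cy - a / 2)), int(min(H, cy + a / 2))
        x0, x1 = int(max(0, cx - a / 2)), int(min(W, cx + a / 2))
        if px[y0:y1, x0:x1].max(initial=0.0) <= 0.0:
            continue
        if probs[i] < score_threshold:
            continue
        if boxes[i, 0] >= boxes[i, 2] or boxes[i, 1] >= boxes[i, 3]:
            continue
        keep.append(i)

    keep.sort(key=lambda i: -probs[i])
    picked: list[int] = []
    for i in keep:
        if all(_box_iou(boxes[i], boxes[j]) < nms_iou for j in picked):
            picked.append(i)
    return [BBoxPrediction(box=tuple(boxes[i]), class_prob=float(probs[i]))
            for i in picked]


# --------------------------------------------------------------------------
# training (Model / Results)
# --------------------------------------------------------------------------

@dataclass
class DetTrainConfig:
    """Detection training knobs; learning rate 0.001 and positive-RoI ratio
    0.33 are the tuned optima, anchors use a single scale and ratio."""

    lr: float = 0.001
    epochs: int = 10
    channels: int = 8
    anchor_size: float = 8.0
    anchor_stride: int = 4
    pool_size: int = 3
    rois_per_image: int = 9
    roi_positive_ratio: float = 0.33
    positive_iou: float = 0.25
    score_threshold: float = 0.6
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if not (0.0 < self.roi_positive_ratio < 1.0):
            raise ValueError("roi_positive_ratio must lie in (0, 1)")


@dataclass
class DetectionResults:
    """Fitted detection stage with per-epoch loss history."""

    detector: NoduleDetector
    discriminator: BoxDiscriminator
    history: pd.DataFrame
    config: DetTrainConfig

    def detect(self, lung_image: SliceImage,
               score_threshold: float | None = None) -> list[BBoxPrediction]:
        thr = (self.config.score_threshold if score_threshold is None
               else score_threshold)
        return detect(self.detector, lung_image, score_threshold=thr)

    def summary(self) -> str:
        lines = [
            "Tumor detection fit",
            "===================",
            f"epochs:           {len(self.history)}",
            f"detector params:  {self.detector.n_parameters()}",
        ]
        if len(self.history):
            last = self.history.iloc[-1]
            lines += [
                f"final L_cls: {last['l_cls']:.4f}",
                f"final L_box: {last['l_box']:.4f}",
                f"final L_adv: {last['l_adv']:.4f}",
                f"final L_G:   {last['l_g']:.4f}",
                f"final L_D:   {last['l_d']:.4f}",
            ]
        return "\n".join(lines)


class TumorDetectionModel:
    """Detection stage bound to annotated cases (lung-masked slices)."""

    def __init__(self, cases: list[PhantomCase],
                 config: DetTrainConfig | None = None):
        if not any(c.annotations for c in cases):
            raise ValueError("need at least one annotated nodule")
        self.cases = list(cases)
        self.config = config or DetTrainConfig()

    @staticmethod
    def lung_masked_slices(case: PhantomCase) -> list[SliceImage]:
        """Slices multiplied by their lung masks (the stage-1 hand-off)."""
        return [
            SliceImage(s.pixels * m.labels, case_id=s.case_id,
                       slice_index=s.slice_index)
            for s, m in zip(case.slices, case.masks)
        ]

    def fit(self) -> DetectionResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        det = NoduleDetector(rng, channels=cfg.channels,
                             anchor_size=cfg.anchor_size,
                             anchor_stride=cfg.anchor_stride,
                             pool_size=cfg.pool_size)
        disc = BoxDiscriminator(rng, channels=cfg.channels,
                                pool_size=cfg.pool_size)
        g_opt = SGD(det.parameters(), lr=cfg.lr, momentum=cfg.momentum)
        d_opt = SGD(disc.parameters(), lr=cfg.lr, momentum=cfg.momentum)

        samples = []  # (pixels, list of gt boxes)
        for case in self.cases:
            boxes_by_slice: dict[int, list] = {}
            for ann in case.annotations:
                boxes_by_slice.setdefault(ann.slice_index, []).append(ann.box)
            for img in self.lung_masked_slices(case):
                gt = boxes_by_slice.get(img.slice_index, [])
                if gt:
                    samples.append((img.pixels, gt))
        if not samples:
            raise ValueError("no annotated slices available")

        history = []
        for epoch in range(cfg.epochs):
            terms_acc = {"l_cls": [], "l_box": [], "l_adv": [], "l_d": []}
            order = rng.permutation(len(samples))
            for si in order:
                px, gt_boxes = samples[si]
                step_terms = self._train_step(det, disc, g_opt, d_opt, px,
                                              gt_boxes, rng)
                if step_terms is None:
                    continue
                for key in terms_acc:
                    terms_acc[key].append(getattr(step_terms, key))
            if not terms_acc["l_cls"]:
                continue
            mean_terms = DetLossTerms(**{k: float(np.mean(v))
                                         for k, v in terms_acc.items()})
            history.append({"epoch": epoch, "l_cls": mean_terms.l_cls,
                            "l_box": mean_terms.l_box,
                            "l_adv": mean_terms.l_adv,
                            "l_g": mean_terms.l_g, "l_d": mean_terms.l_d})

        return DetectionResults(
            detector=det, discriminator=disc,
            history=pd.DataFrame(
                history,
                columns=["epoch", "l_cls", "l_box", "l_adv", "l_g", "l_d"]),
            config=cfg)

    def _train_step(self, det: NoduleDetector, disc: BoxDiscriminator,
                    g_opt: SGD, d_opt: SGD, px: np.ndarray, gt_boxes,
                    rng: np.random.Generator) -> DetLossTerms | None:
        cfg = self.config
        H, W = px.shape
        centres = det.anchor_grid(H, W)
        a = det.anchor_size
        anchor_boxes = np.stack([centres[:, 1] - a / 2, centres[:, 0] - a / 2,
                                 centres[:, 1] + a / 2, centres[:, 0] + a / 2],
                                axis=1)

        # anchor assignment: best anchor per gt is positive, plus any anchor
        # overlapping a gt above the positive-IoU floor
        ious = np.array([[_box_iou(ab, gb) for gb in gt_boxes]
                         for ab in anchor_boxes])
        pos_idx = set(np.argmax(ious, axis=0).tolist())
        pos_idx |= set(np.nonzero(ious.max(axis=1) >= cfg.positive_iou)[0])
        pos_idx = sorted(pos_idx)
        neg_pool = [i for i in range(len(centres)) if i not in set(pos_idx)]
        if not pos_idx:
            return None  # skipped batch: no positive RoIs
        n_pos = min(len(pos_idx),
                    max(1, int(round(cfg.rois_per_image
                                     * cfg.roi_positive_ratio))))
        n_neg = min(len(neg_pool), cfg.rois_per_image - n_pos)
        pos_sample = list(rng.choice(pos_idx, size=n_pos, replace=False))
        neg_sample = list(rng.choice(neg_pool, size=n_neg, replace=False))

        # ---- generator (detector) update
        det.zero_grad()
        feats, scores, offsets = det(Tensor(px[None, None]))
        flat_scores = scores.reshape(-1)
        flat_offsets = offsets[0].reshape(4, -1)

        eps = Tensor(_EPS)
        sampled = pos_sample + neg_sample
        labels = np.array([1.0] * len(pos_sample) + [0.0] * len(neg_sample))
        probs = flat_scores[np.array(sampled)].sigmoid()
        yt = Tensor(labels)
        l_cls_t = -((probs + eps).log() * yt
                    + (1.0 - probs + eps).log() * (1.0 - yt)).mean()

        box_terms = []
        for i in pos_sample:
            best_gt = gt_boxes[int(np.argmax(ious[i]))]
            target = det.encode_box(best_gt, centres[i])
            diff = flat_offsets[:, i] - Tensor(target)
            box_terms.append(_smooth_l1_tensor(diff))
        l_box_t = sum(box_terms[1:], box_terms[0]) / float(len(box_terms))

        offs_np = offsets.data[0].reshape(4, -1).T
        pred_boxes = det.decode_boxes(offs_np, centres, H, W)
        adv_scores = []
        for i in pos_sample:
            patch = det.roi_pool(feats[0], pred_boxes[i], H, W)
            gt_patch = det.roi_pool(
                feats[0], gt_boxes[int(np.argmax(ious[i]))], H, W)
            pair = concat([gt_patch, patch], axis=0)
            adv_scores.append(disc(pair))
        l_adv_t = -sum(((s + eps).log() for s in adv_scores),
                       Tensor(0.0)) / float(len(adv_scores))

        l_g_t = l_cls_t + l_box_t + l_adv_t
        l_g_t.backward()
        g_opt.step()

        # ---- discriminator update (fresh forward, detector frozen)
        disc.zero_grad()
        with no_grad():
            feats_d = det.features(Tensor(px[None, None]))
        d_real, d_fake = [], []
        for i in pos_sample:
            gt_box = gt_boxes[int(np.argmax(ious[i]))]
            gt_patch = det.roi_pool(feats_d[0], gt_box, H, W)
            pred_patch = det.roi_pool(feats_d[0], pred_boxes[i], H, W)
            d_real.append(disc(concat([gt_patch, gt_patch], axis=0)))
            d_fake.append(disc(concat([gt_patch, pred_patch], axis=0)))
        l_d_t = -sum((((r + eps).log() + (1.0 - f + eps).log())
                      for r, f in zip(d_real, d_fake)),
                     Tensor(0.0)) / float(len(d_real))
        l_d_t.backward()
        d_opt.step()

        return DetLossTerms(l_cls=l_cls_t.item(), l_box=l_box_t.item(),
                            l_adv=l_adv_t.item(), l_d=l_d_t.item())


def train_detection(cases: list[PhantomCase],
                    cfg: DetTrainConfig | None = None) -> DetectionResults:
    """Functional wrapper around :class:`TumorDetectionModel`."""
    return TumorDetectionModel(cases, cfg).fit()
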