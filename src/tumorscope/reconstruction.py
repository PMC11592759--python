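"""Slice-sequence to 3-D tumor volume reconstruction.

Ordered 2-D tumor slices are embedded by a VGG-pattern convolutional encoder
(stacked 3x3 convolutions with 2x pooling) into low-dimensional feature
vectors; an LSTM consumes the sequence and an additive attention layer
weights its hidden states into a single context vector; a transposed-style
volume generator (dense projection followed by upsample + 3-D convolution
stages) maps the context to an occupancy volume in [0, 1].  A 3-D critic
with dilated convolutions scores generated against reference volumes with
the same Earth-Mover objective as the segmentation critic; the generator is
additionally trained with a voxel-wise cross-entropy reconstruction term,
without which a conditional volume generator has no incentive to match the
particular case it is conditioned on.

The encoder is pluggable: a plainer single-stack CNN can be swapped in
without changing any shape or normalisation contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics
from .datatypes import PhantomCase, SliceImage, VoxelVolume
from .nn import (Adam, AdditiveAttention, Conv2d, Conv3d, Linear, LSTM,
                 Module, Tensor, no_grad)
from .segmentation import critic_loss as _em_loss

__all__ = [
    "FeatureSequence", "ReconSample", "VolumeGANSpec", "ReconTrainConfig",
    "VGGStyleEncoder", "PlainCNNEncoder", "VolumeGenerator", "VolumeCritic",
    "extract_features", "encode_sequence", "generate_volume",
    "volume_critic_loss", "reconstruct", "train_reconstruction",
    "ellipsoid_tumor_sample", "TumorReconstructionModel",
    "ReconstructionResults",
]


@dataclass
class FeatureSequence:
    """Ordered per-slice feature vectors of equal dimension."""

    vectors: np.ndarray  # (T, d)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("feature sequence must be (T, d)")

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class ReconSample:
    """One reconstruction training example: tumor slices + truth volume."""

    slices: list[SliceImage]
    volume: VoxelVolume

    def __post_init__(self):
        if not self.slices:
            raise ValueError("need at least one tumor slice")


def ellipsoid_tumor_sample(size: int = 16, seed: int = 0,
                           spacing=(1.0, 1.0, 1.0)) -> ReconSample:
    """Random axis-aligned ellipsoid tumor with its exact slice sections."""
    rng = np.random.default_rng(seed)
    semi = rng.uniform(0.18 * size, 0.35 * size, size=3)
    centre = size / 2 + rng.uniform(-0.08 * size, 0.08 * size, size=3)
    zz, yy, xx = np.mgrid[0:size, 0:size, 0:size].astype(float)
    inside = (((zz - centre[0]) / semi[0]) ** 2
              + ((yy - centre[1]) / semi[1]) ** 2
              + ((xx - centre[2]) / semi[2]) ** 2) <= 1.0
    volume = VoxelVolume(inside.astype(np.float64), spacing=spacing)
    slices = [SliceImage(volume.voxels[z], case_id=f"ellipsoid-{seed}",
                         slice_index=z) for z in range(size)]
    return ReconSample(slices=slices, volume=volume)


def tumor_sample_from_case(case: PhantomCase) -> ReconSample:
    """Extract the tumor slice stack of a phantom case."""
    vol = case.tumor_volume
    slices = [SliceImage(vol.voxels[z], case_id=case.case_id, slice_index=z)
              for z in range(vol.shape[0])]
    return ReconSample(slices=slices, volume=vol)


# --------------------------------------------------------------------------
# networks
# --------------------------------------------------------------------------

class VGGStyleEncoder(Module):
    """VGG-pattern encoder: paired 3x3 convs with 2x pooling, then a dense
    projection to a d-dimensional feature vector (d << H*W)."""

    def __init__(self, rng: np.random.Generator, image_size: int = 16,
                 channels: int = 8, feature_dim: int = 32):
        c = channels
        self.conv1a = Conv2d(1, c, 3, rng)
        self.conv1b = Conv2d(c, c, 3, rng)
        self.conv2a = Conv2d(c, 2 * c, 3, rng)
        self.conv2b = Conv2d(2 * c, 2 * c, 3, rng)
        reduced = image_size // 4
        n_flat = 2 * c * reduced * reduced
        if feature_dim >= image_size * image_size:
            raise ValueError("feature_dim must reduce dimensionality")
        self.proj = Linear(n_flat, feature_dim, rng)
        self.image_size = image_size
        self.feature_dim = feature_dim

    def forward(self, x: Tensor) -> Tensor:
        """x: (T, 1, H, W) -> (T, d)."""
        h = self.conv1b(self.conv1a(x).relu()).relu().avg_pool2d(2)
        h = self.conv2b(self.conv2a(h).relu()).relu().avg_pool2d(2)
        return self.proj(h.reshape(h.shape[0], -1)).tanh()


class PlainCNNEncoder(Module):
    """Minimal alternative backbone: one conv stack, same output contract."""

    def __init__(self, rng: np.random.Generator, image_size: int = 16,
                 channels: int = 8, feature_dim: int = 32):
        self.conv = Conv2d(1, channels, 3, rng)
        reduced = image_size // 2
        self.proj = Linear(channels * reduced * reduced, feature_dim, rng)
        self.image_size = image_size
        self.feature_dim = feature_dim

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv(x).relu().avg_pool2d(2)
        return self.proj(h.reshape(h.shape[0], -1)).tanh()


class VolumeGenerator(Module):
    """Context vector -> occupancy volume in [0, 1] of fixed shape."""

    def __init__(self, rng: np.random.Generator, context_dim: int,
                 output_shape: tuple[int, int, int] = (16, 16, 16),
                 channels: int = 8):
        D, H, W = output_shape
        for dim in (D, H, W):
            if dim % 4 != 0:
                raise ValueError("output dimensions must be multiples of 4")
        c = channels
        self.base = (D // 4, H // 4, W // 4)
        self.channels = c
        self.fc = Linear(context_dim, c * np.prod(self.base), rng)
        self.conv1 = Conv3d(c, c, 3, rng)
        self.conv2 = Conv3d(c, c, 3, rng)
        self.head = Conv3d(c, 1, 3, rng)
        self.output_shape = output_shape
        self.context_dim = context_dim

    def forward(self, context: Tensor) -> Tensor:
        """context: (d,) -> volume (D, H, W) with values in (0, 1)."""
        if context.shape != (self.context_dim,):
            raise ValueError(
                f"context dimension {context.shape} != {self.context_dim}")
        h = self.fc(context.reshape(1, -1)).relu()
        h = h.reshape(1, self.channels, *self.base)
        h = self.conv1(h.upsample3d(2)).relu()
        h = self.conv2(h.upsample3d(2)).relu()
        out = self.head(h).sigmoid()
        return out.reshape(self.output_shape)


class VolumeCritic(Module):
    """3-D EM critic with dilated convolutions, mirroring the generator."""

    def __init__(self, rng: np.random.Generator, channels: int = 6,
                 dilation_rates: tuple[int, ...] = (1, 2, 4)):
        if not any(r > 1 for r in dilation_rates):
            raise ValueError("at least one dilation rate must exceed 1")
        self.convs = []
        c_in = 1
        for rate in dilation_rates:
            self.convs.append(Conv3d(c_in, channels, 3, rng, dilation=rate))
            c_in = channels
        self.head = Conv3d(c_in, 1, 1, rng)

    def forward(self, vol: Tensor) -> Tensor:
        """vol: (D, H, W) -> scalar score."""
        h = vol.reshape(1, 1, *vol.shape)
        for conv in self.convs:
            h = conv(h).leaky_relu(0.2)
        return self.head(h).mean()

    def clip_weights(self, bound: float = 0.05) -> None:
        for p in self.parameters():
            np.clip(p.data, -bound, bound, out=p.data)


# --------------------------------------------------------------------------
# functional operations
# --------------------------------------------------------------------------

def extract_features(encoder: Module,
                     tumor_slices: list[SliceImage]) -> FeatureSequence:
    """One feature vector per slice, in slice order."""
    if not tumor_slices:
        raise ValueError("need at least one slice")
    shapes = {s.pixels.shape for s in tumor_slices}
    if len(shapes) != 1:
        raise ValueError(f"mixed slice sizes: {sorted(shapes)}")
    ordered = sorted(tumor_slices, key=lambda s: s.slice_index)
    x = np.stack([s.pixels for s in ordered])[:, None]
    with no_grad():
        feats = encoder(Tensor(x))
    return FeatureSequence(feats.data)


def encode_sequence(lstm: LSTM, attention: AdditiveAttention,
                    seq: FeatureSequence) -> tuple[np.ndarray, np.ndarray]:
    """Sequence -> (context vector, attention weights summing to 1)."""
    if len(seq) == 0:
        raise ValueError("cannot encode an empty sequence")
    with no_grad():
        hidden = lstm(Tensor(seq.vectors))
        context, weights = attention(hidden)
    return context.data.copy(), weights.data.copy()


def generate_volume(gen: VolumeGenerator, context: np.ndarray,
                    spacing=(1.0, 1.0, 1.0)) -> VoxelVolume:
    """Deterministic volume generation from a context vector."""
    context = np.asarray(context, dtype=np.float64)
    with no_grad():
        vol = gen(Tensor(context))
    return VoxelVolume(vol.data, spacing=spacing)


def volume_critic_loss(d_fake, d_real) -> float:
    """EM-style critic objective on volume scores (shared implementation)."""
    return _em_loss(d_fake, d_real)


def reconstruct(models: "ReconstructionResults",
                tumor_slices: list[SliceImage]) -> VoxelVolume:
    """Composition: features -> sequence context -> generated volume."""
    seq = extract_features(models.encoder, tumor_slices)
    context, _ = encode_sequence(models.lstm, models.attention, seq)
    return generate_volume(models.generator, context, spacing=models.spacing)


# --------------------------------------------------------------------------
# training (Model / Results)
# --------------------------------------------------------------------------

@dataclass
class VolumeGANSpec:
    """Architecture sizes (scaled-down defaults of the tuned configuration:
    512 LSTM units / 3 layers / dropout 0.25 at full scale)."""

    feature_dim: int = 32
    lstm_units: int = 64
    lstm_layers: int = 1
    dropout: float = 0.25
    output_shape: tuple[int, int, int] = (16, 16, 16)
    encoder_channels: int = 8
    generator_channels: int = 8
    critic_channels: int = 6
    dilation_rates: tuple[int, ...] = (1, 2, 4)
    encoder: str = "vgg"  # "vgg" | "plain"


@dataclass
class ReconTrainConfig:
    """Optimisation knobs (Adam lr 2e-4, beta1 0.5 are the tuned optima)."""

    lr: float = 0.0002
    beta1: float = 0.5
    beta2: float = 0.999
    epochs: int = 12
    recon_weight: float = 1.0
    adv_weight: float = 0.05
    critic_clip: float = 0.05
    val_fraction: float = 0.2
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class ReconstructionResults:
    """Fitted reconstruction stage: all four networks plus history."""

    encoder: Module
    lstm: LSTM
    attention: AdditiveAttention
    generator: VolumeGenerator
    critic: VolumeCritic
    history: pd.DataFrame
    spec: VolumeGANSpec
    config: ReconTrainConfig
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    val_indices: tuple[int, ...] = ()

    def reconstruct(self, tumor_slices: list[SliceImage]) -> VoxelVolume:
        return reconstruct(self, tumor_slices)

    def summary(self) -> str:
        lines = [
            "3-D tumor reconstruction fit",
            "============================",
            f"encoder:          {type(self.encoder).__name__}",
            f"feature dim:      {self.spec.feature_dim}",
            f"LSTM units:       {self.spec.lstm_units} x {self.spec.lstm_layers}",
            f"output shape:     {self.spec.output_shape}",
            f"epochs:           {len(self.history)}",
        ]
        if len(self.history):
            first, last = self.history.iloc[0], self.history.iloc[-1]
            lines += [
                f"val HD epoch 0:   {first['val_hd']:.4f}",
                f"val HD final:     {last['val_hd']:.4f}",
                f"val ED final:     {last['val_ed']:.4f}",
            ]
        return "\n".join(lines)


class TumorReconstructionModel:
    """Reconstruction stage bound to tumor samples.

    Accepts :class:`ReconSample` objects or :class:`PhantomCase` objects
    (whose tumor volumes are sectioned automatically).
    """

    def __init__(self, samples, spec: VolumeGANSpec | None = None,
                 config: ReconTrainConfig | None = None):
        coerced = []
        for s in samples:
            if isinstance(s, PhantomCase):
                s = tumor_sample_from_case(s)
            if not isinstance(s, ReconSample):
                raise TypeError("samples must be ReconSample or PhantomCase")
            if s.volume.binarize().sum() == 0:
                raise ValueError("each sample needs a non-empty tumor volume")
            coerced.append(s)
        if not coerced:
            raise ValueError("need at least one sample")
        self.samples = coerced
        self.spec = spec or VolumeGANSpec()
        self.config = config or ReconTrainConfig()

    def _build(self, rng: np.random.Generator):
        spec = self.spec
        image_size = self.samples[0].slices[0].pixels.shape[0]
        if spec.encoder == "vgg":
            encoder = VGGStyleEncoder(rng, image_size=image_size,
                                      channels=spec.encoder_channels,
                                      feature_dim=spec.feature_dim)
        elif spec.encoder == "plain":
            encoder = PlainCNNEncoder(rng, image_size=image_size,
                                      channels=spec.encoder_channels,
                                      feature_dim=spec.feature_dim)
        else:
            raise ValueError(f"unknown encoder {spec.encoder!r}")
        lstm = LSTM(spec.feature_dim, spec.lstm_units, rng,
                    n_layers=spec.lstm_layers, dropout=spec.dropout)
        attention = AdditiveAttention(spec.lstm_units,
                                      max(8, spec.lstm_units // 2), rng)
        generator = VolumeGenerator(rng, spec.lstm_units,
                                    output_shape=spec.output_shape,
                                    channels=spec.generator_channels)
        critic = VolumeCritic(rng, channels=spec.critic_channels,
                              dilation_rates=spec.dilation_rates)
        return encoder, lstm, attention, generator, critic

    def fit(self) -> ReconstructionResults:
        cfg, spec = self.config, self.spec
        rng = np.random.default_rng(cfg.seed)
        encoder, lstm, attention, generator, critic = self._build(rng)
        spacing = self.samples[0].volume.spacing

        n = len(self.samples)
        n_val = max(1, int(round(cfg.val_fraction * n))) if n > 1 else 0
        order = rng.permutation(n)
        val_idx = set(order[:n_val].tolist())
        train = [s for i, s in enumerate(self.samples) if i not in val_idx]
        val = [s for i, s in enumerate(self.samples) if i in val_idx] or train

        gen_params = (encoder.parameters() + lstm.parameters()
                      + attention.parameters() + generator.parameters())
        g_opt = Adam(gen_params, lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
        c_opt = Adam(critic.parameters(), lr=cfg.lr, beta1=cfg.beta1,
                     beta2=cfg.beta2)

        results = ReconstructionResults(
            encoder=encoder, lstm=lstm, attention=attention,
            generator=generator, critic=critic, history=pd.DataFrame(),
            spec=spec, config=cfg, spacing=spacing,
            val_indices=tuple(sorted(val_idx)))

        history: list[dict] = []
        for epoch in range(cfg.epochs):
            closses = []
            for si in rng.permutation(len(train)):
                sample = train[si]
                x = np.stack([s.pixels for s in
                              sorted(sample.slices,
                                     key=lambda s: s.slice_index)])[:, None]
                truth = sample.volume.voxels

                # ---- generator-side update
                for m in (encoder, lstm, attention, generator):
                    m.zero_grad()
                feats = encoder(Tensor(x))
                hidden = lstm(feats, rng=rng, training=True)
                context, _ = attention(hidden)
                vol = generator(context)
                yt = Tensor(truth)
                eps = 1e-12
                bce = -((vol + eps).log() * yt
                        + (1.0 - vol + eps).log() * (1.0 - yt)).mean()
                loss = bce * cfg.recon_weight
                if cfg.adv_weight > 0:
                    loss = loss - critic(vol) * cfg.adv_weight
                if np.isnan(loss.data).any():
                    raise FloatingPointError(
                        "reconstruction loss became NaN; aborting")
                loss.backward()
                g_opt.step()

                # ---- critic update
                critic.zero_grad()
                with no_grad():
                    feats_d = encoder(Tensor(x))
                    hidden_d = lstm(feats_d)
                    context_d, _ = attention(hidden_d)
                    fake = generator(context_d)
                c_obj = critic(Tensor(fake.data)) - critic(yt)
                c_obj.backward()
                c_opt.step()
                critic.clip_weights(cfg.critic_clip)
                closses.append(c_obj.item())

            history.append(self._epoch_row(epoch, float(np.mean(closses)),
                                           results, val))

        results.history = pd.DataFrame(
            history, columns=["epoch", "critic_loss", "val_hd", "val_ed"])
        return results

    def _epoch_row(self, epoch: int, closs: float,
                   results: ReconstructionResults, val) -> dict:
        hds, eds = [], []
        diag = float(np.linalg.norm(
            np.asarray(self.spec.output_shape, dtype=float)
            * np.asarray(self.samples[0].volume.spacing)))
        for sample in val:
            pred = results.reconstruct(sample.slices)
            try:
                m = metrics.surface_metrics(pred, sample.volume,
                                            self.config.threshold)
                hds.append(m["hd"])
                eds.append(m["ed"])
            except ValueError:
                # empty prediction: score the worst geometrically possible
                hds.append(diag)
                eds.append(diag)
        return {"epoch": epoch, "critic_loss": closs,
                "val_hd": float(np.mean(hds)), "val_ed": float(np.mean(eds))}


def train_reconstruction(samples, spec: VolumeGANSpec | None = None,
                         cfg: ReconTrainConfig | None = None
                         ) -> ReconstructionResults:
    """Functional wrapper around :class:`TumorReconstructionModel`."""
    return TumorReconstructionModel(samples, spec, cfg).fit()
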