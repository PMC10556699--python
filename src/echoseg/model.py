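"""Dilated U-Net backbone with a shared pixel classifier and a projector head.

The backbone is a classic U-Net encoder–decoder: two 3x3 conv + BN + ReLU
blocks per stage, channel count doubling at every downsampling, skip
connections at every depth. The configured downsampling stages replace their
plain convolutions with dilated ones (same kernel size, padding equal to the
dilation rate) so every intermediate feature map keeps the exact spatial
shape of the undilated network while the receptive field grows — dilation
adds no parameters.

Two heads read the decoder output:

* a 1x1-conv **classifier** producing per-pixel probabilities over the four
  cardiac classes (background, LV, myocardium, LA). One classifier object
  serves both the supervised and the unsupervised branch — parameter sharing
  is by identity, not by copying.
* a **projector** (1x1 conv -> BN -> ReLU -> 1x1 conv, i.e. two per-pixel
  linear layers) mapping features pooled to the contrastive-loss grid into
  the embedding space. With the projector disabled the raw pooled features
  are used, which is the "+Dilation" ablation; with an all-ones dilation
  schedule and no projector the network is the plain U-Net baseline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract."""


@dataclass
class BackboneConfig:
    in_channels: int = 1
    base_channels: int = 64
    depth: int = 4
    dilation_schedule: tuple = (1, 1, 2, 4)
    use_projector: bool = True
    num_classes: int = 4
    projector_dim: int = 256
    grid_stride: int = 8

    def __post_init__(self):
        self.dilation_schedule = tuple(int(d) for d in self.dilation_schedule)
        if self.depth < 2:
            raise ValidationError("depth must be >= 2")
        if len(self.dilation_schedule) != self.depth:
            raise ValidationError(
                f"dilation_schedule length {len(self.dilation_schedule)} "
                f"!= depth {self.depth}")
        if any(d < 1 for d in self.dilation_schedule):
            raise ValidationError("dilation rates must be >= 1")

    @classmethod
    def tiny(cls, **overrides) -> "BackboneConfig":
        """Small preset (base 8, depth 3) for CPU-scale experiments."""
        kwargs = dict(base_channels=8, depth=3, dilation_schedule=(1, 1, 2),
                      projector_dim=32)
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dilation_schedule"] = list(self.dilation_schedule)
        return d


@dataclass
class FeatureMap:
    """Per-pixel backbone features with their resolution stride."""
    values: Tensor
    stride: int = 1

    @property
    def shape(self):
        return self.values.shape


@dataclass
class ProbabilityMap:
    """Per-pixel class probabilities (N, K, H, W); rows sum to one."""
    values: Tensor

    @property
    def shape(self):
        return self.values.shape

    def pseudo_labels(self) -> np.ndarray:
        """Argmax class per pixel — the pseudo-label of unlabeled data."""
        return self.values.data.argmax(axis=1)

    def confidence(self) -> np.ndarray:
        """Max class probability per pixel."""
        return self.values.data.max(axis=1)


@dataclass
class EmbeddingMap:
    """Projected per-pixel embeddings on the contrastive-loss grid."""
    values: Tensor

    @property
    def shape(self):
        return self.values.shape


class _ConvBlock(nn.Module):
    def __init__(self, cin, cout, dilation, rng):
        super().__init__()
        self.block = nn.Sequential(
            nn.Conv2d(cin, cout, 3, dilation=dilation, rng=rng),
            nn.BatchNorm2d(cout), nn.ReLU(),
            nn.Conv2d(cout, cout, 3, dilation=dilation, rng=rng),
            nn.BatchNorm2d(cout), nn.ReLU())

    def forward(self, x):
        return self.block(x)


class _Projector(nn.Module):
    """Two per-pixel linear layers; BN + ReLU after the first."""

    def __init__(self, cin, dim, rng):
        super().__init__()
        self.block = nn.Sequential(
            nn.Conv2d(cin, cin, 1, rng=rng),
            nn.BatchNorm2d(cin), nn.ReLU(),
            nn.Conv2d(cin, dim, 1, rng=rng))

    def forward(self, x):
        return self.block(x)


class DilatedUNet(nn.Module):
    def __init__(self, config: BackboneConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.base_channels
        chans = [c * 2 ** i for i in range(config.depth)]
        self.enc = [
            _ConvBlock(config.in_channels if i == 0 else chans[i - 1],
                       chans[i], config.dilation_schedule[i], rng)
            for i in range(config.depth)]
        self.pool = nn.MaxPool2d(2)
        self.bottleneck = _ConvBlock(chans[-1], chans[-1] * 2, 1, rng)
        # decoder, deepest first: upsample + 3x3 conv halving channels,
        # concat skip, then a conv block
        self.up_convs = []
        self.dec = []
        up_in = chans[-1] * 2
        for i in reversed(range(config.depth)):
            self.up_convs.append(nn.Conv2d(up_in, chans[i], 3, rng=rng))
            self.dec.append(_ConvBlock(chans[i] * 2, chans[i], 1, rng))
            up_in = chans[i]
        self.classifier = nn.Conv2d(chans[0], config.num_classes, 1, rng=rng)
        self.projector = (_Projector(chans[0], config.projector_dim, rng)
                          if config.use_projector else None)

    # ------------------------------------------------------------------
    def _check_finite(self, t: Tensor, stage: str):
        if not np.all(np.isfinite(t.data)):
            raise RuntimeError(f"non-finite activations at stage '{stage}'")

    def forward_features(self, x, collect_stages: dict | None = None) -> FeatureMap:
        """Run the encoder–decoder; returns full-resolution decoder features."""
        x = nn.as_tensor(x)
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
        elif x.ndim == 3:
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        h, w = x.shape[2:]
        div = 2 ** self.config.depth
        if h % div or w % div:
            raise ValidationError(
                f"input size {h}x{w} must be divisible by {div}")
        skips = []
        for i, block in enumerate(self.enc):
            x = block(x)
            if collect_stages is not None:
                collect_stages[f"enc{i}"] = x.shape
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        self._check_finite(x, "bottleneck")
        if collect_stages is not None:
            collect_stages["bottleneck"] = x.shape
        for i, (up, block) in enumerate(zip(self.up_convs, self.dec)):
            x = up(F.upsample_nearest2d(x, 2))
            x = nn.concatenate([x, skips[-(i + 1)]], axis=1)
            x = block(x)
            if collect_stages is not None:
                collect_stages[f"dec{i}"] = x.shape
        self._check_finite(x, "decoder")
        return FeatureMap(values=x, stride=1)

    def classify(self, features: FeatureMap) -> ProbabilityMap:
        logits = self.classifier(features.values)
        return ProbabilityMap(values=F.softmax(logits, axis=1))

    def features_to_grid(self, features: FeatureMap) -> FeatureMap:
        """Average-pool features to the stride the contrastive loss acts on."""
        k = self.config.grid_stride // features.stride
        if k <= 1:
            return features
        return FeatureMap(values=F.avg_pool2d(features.values, k),
                          stride=self.config.grid_stride)

    def project(self, features: FeatureMap) -> EmbeddingMap:
        """Map loss-grid features to embeddings; identity when disabled."""
        if self.projector is None:
            return EmbeddingMap(values=features.values)
        return EmbeddingMap(values=self.projector(features.values))

    # ------------------------------------------------------------------
    def predict(self, image: np.ndarray) -> np.ndarray:
        """Label mask (argmax class) for one preprocessed image, eval mode."""
        was_training = self.training
        self.eval()
        try:
            feats = self.forward_features(np.asarray(image, dtype=np.float64))
            probs = self.classify(feats)
            return probs.pseudo_labels()[0].astype(np.int64)
        finally:
            self.train(was_training)

    def predict_probabilities(self, image: np.ndarray) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            feats = self.forward_features(np.asarray(image, dtype=np.float64))
            return self.classify(feats).values.data[0]
        finally:
            self.train(was_training)

    def describe(self, input_size: int = 64) -> str:
        stages: dict = {}
        was_training = self.training
        self.eval()
        x = np.zeros((1, self.config.in_channels, input_size, input_size))
        self.forward_features(x, collect_stages=stages)
        self.train(was_training)
        lines = [f"DilatedUNet(base={self.config.base_channels}, "
                 f"depth={self.config.depth}, "
                 f"dilation={list(self.config.dilation_schedule)}, "
                 f"projector={self.config.use_projector})"]
        for name, shape in stages.items():
            lines.append(f"  {name}: {tuple(shape)}")
        lines.append(f"  parameters: {self.param_count():,}")
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------
    def save(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        state = self.state_dict()
        with open(path, "wb") as fh:  # keep the exact filename (no .npz suffix)
            np.savez(fh, __config__=json.dumps(self.config.to_dict()), **state)

    @classmethod
    def load(cls, path) -> "DilatedUNet":
        with np.load(path, allow_pickle=False) as archive:
            config = BackboneConfig(**json.loads(str(archive["__config__"])))
            model = cls(config)
            model.load_state_dict(
                {k: archive[k] for k in archive.files if k != "__config__"})
        return model


def build_model(config: BackboneConfig, seed: int = 0) -> DilatedUNet:
    """Construct the network; raises :class:`ValidationError` on bad config."""
    return DilatedUNet(config, seed=seed)
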