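"""Desk-scale convolutional encoders.

Two registered architectures map (N, C, H, W) image batches to embeddings:

``small_conv``
    Three stride-2 3x3 convolutions (16, 32, 64 channels), global average
    pooling, and a linear head. Roughly 30k parameters — small enough that a
    full SSRL training runs in seconds on one CPU core while still learning
    shape/texture features on the synthetic datasets.

``resnet_small``
    The same stem with two residual blocks inserted, for checking that
    findings are not an artifact of the plain stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import MLP, BatchNorm2d, Conv2d, GlobalAvgPool, Linear, Module, ReLU, Sequential

__all__ = ["EncoderSpec", "Encoder", "build_encoder", "ENCODER_REGISTRY"]


@dataclass
class EncoderSpec:
    """Architecture choice plus head dimensions.

    ``projector_dims`` are the hidden/output widths of the projection MLP used
    only during SSRL training; probing and clustering consume the pre-projector
    embedding, the usual evaluation convention.
    """

    architecture: str = "small_conv"
    embedding_dim: int = 32
    projector_dims: list[int] = field(default_factory=lambda: [64, 32])

    def __post_init__(self):
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if self.architecture not in ENCODER_REGISTRY:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                f"registered: {sorted(ENCODER_REGISTRY)}"
            )


class _ResBlock(Module):
    def __init__(self, ch: int, rng: np.random.Generator):
        self.c1 = Conv2d(ch, ch, 3, stride=1, pad=1, rng=rng)
        self.c2 = Conv2d(ch, ch, 3, stride=1, pad=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = ad.relu(self.c1(x))
        return ad.relu(self.c2(h) + x)


class Encoder(Module):
    """Backbone + embedding head + training-time projector."""

    def __init__(self, spec: EncoderSpec, in_channels: int, rng: np.random.Generator):
        self.spec = spec
        self.in_channels = in_channels
        self.backbone = _build_backbone(spec.architecture, in_channels, rng)
        self.head = Linear(64, spec.embedding_dim, rng=rng)
        self.projector = MLP([spec.embedding_dim] + list(spec.projector_dims), rng=rng)

    def embed(self, x: Tensor) -> Tensor:
        """Pre-projector embedding (N, embedding_dim)."""
        return self.head(self.backbone(x))

    def forward(self, x: Tensor) -> Tensor:
        """Projected embedding used by the SSRL losses."""
        return self.projector(self.embed(x))

    def calibrate_norm_stats(self, images: np.ndarray, max_samples: int = 512):
        """Set normalization running statistics from the given image distribution.

        Training accumulates batch-norm statistics over *augmented views*,
        whose intensity and scale statistics can differ sharply from the
        un-augmented inference images (and, in a dual-composition training,
        are a mixture of two view distributions). One training-mode forward
        pass with momentum 0 replaces the running statistics with those of the
        inference distribution."""
        from .layers import BatchNorm2d

        if len(images) > max_samples:
            stride = int(np.ceil(len(images) / max_samples))
            images = images[::stride]
        bns = [m for m in self.walk() if isinstance(m, BatchNorm2d)]
        saved = [(bn.momentum, bn.training) for bn in bns]
        for bn in bns:
            bn.momentum = 0.0
            bn.training = True
        try:
            self.embed(Tensor(images))
        finally:
            for bn, (mom, tr) in zip(bns, saved):
                bn.momentum = mom
                bn.training = tr

    def embed_numpy(self, images: np.ndarray, batch: int = 256,
                    calibrate: bool = True) -> np.ndarray:
        """Embed an (N,C,H,W) float array in eval mode.

        With ``calibrate`` (default) the normalization statistics are first
        recalibrated on the images being embedded."""
        if calibrate:
            self.calibrate_norm_stats(images)
        self.set_training(False)
        try:
            outs = []
            for i in range(0, images.shape[0], batch):
                z = self.embed(Tensor(images[i : i + batch]))
                outs.append(z.data)
        finally:
            self.set_training(True)
        return np.concatenate(outs, axis=0)


def _small_conv(in_ch: int, rng: np.random.Generator) -> Module:
    return Sequential(
        Conv2d(in_ch, 16, 3, stride=2, pad=1, rng=rng), BatchNorm2d(16), ReLU(),
        Conv2d(16, 32, 3, stride=2, pad=1, rng=rng), BatchNorm2d(32), ReLU(),
        Conv2d(32, 64, 3, stride=2, pad=1, rng=rng), BatchNorm2d(64), ReLU(),
        GlobalAvgPool(),
    )


def _resnet_small(in_ch: int, rng: np.random.Generator) -> Module:
    return Sequential(
        Conv2d(in_ch, 16, 3, stride=2, pad=1, rng=rng), BatchNorm2d(16), ReLU(),
        _ResBlock(16, rng),
        Conv2d(16, 32, 3, stride=2, pad=1, rng=rng), BatchNorm2d(32), ReLU(),
        _ResBlock(32, rng),
        Conv2d(32, 64, 3, stride=2, pad=1, rng=rng), BatchNorm2d(64), ReLU(),
        GlobalAvgPool(),
    )


ENCODER_REGISTRY = {"small_conv": _small_conv, "resnet_small": _resnet_small}


def _build_backbone(arch: str, in_ch: int, rng: np.random.Generator) -> Module:
    return ENCODER_REGISTRY[arch](in_ch, rng)


def build_encoder(spec: EncoderSpec, in_channels: int, seed: int) -> Encoder:
    return Encoder(spec, in_channels, np.random.default_rng(seed))
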