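"""Compact convolutional slice encoder for the CNN comparison arms.

A small stacked-conv network: each block is a 3x3 convolution (the first
with stride 2) + ReLU + 2x2 average pooling, with channel width doubling
per block; global average pooling and a linear map produce the per-slice
feature vector. It emits FeatureSequences under exactly the same contract
as the ViT encoder, so the four architecture combinations
(CNN/ViT x Bi-LSTM/TST) are formed purely by composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, no_grad
from .nn import Conv2d, Linear, Module, avg_pool2
from .slicer import SliceSequence
from .vit_encoder import FeatureSequence, encode_volume as _encode_volume

__all__ = ["CNNConfig", "CNNEncoder", "cnn_encode_volume"]


@dataclass
class CNNConfig:
    n_conv_blocks: int = 4
    base_channels: int = 8
    feature_dim: int = 32
    input_side: int = 224
    in_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.feature_dim < 1 or self.n_conv_blocks < 1:
            raise ValueError("feature_dim and n_conv_blocks must be >= 1")
        # first conv strides 2, each block pools by 2
        factor = 2 ** (self.n_conv_blocks + 1)
        if self.input_side % factor:
            raise ValueError(f"input_side {self.input_side} must be divisible "
                             f"by {factor} for {self.n_conv_blocks} blocks")


class CNNEncoder(Module):
    """Stacked conv->ReLU->pool blocks, global average pool, linear readout."""

    def __init__(self, cfg: CNNConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.convs = []
        c_in = cfg.in_channels
        for b in range(cfg.n_conv_blocks):
            c_out = cfg.base_channels * 2 ** b
            stride = 2 if b == 0 else 1
            self.convs.append(Conv2d(c_in, c_out, 3, stride, 1, rng))
            c_in = c_out
        self.fc = Linear(c_in, cfg.feature_dim, rng)

    def __call__(self, batch: np.ndarray) -> Tensor:
        """(B, C, S, S) slice batch -> (B, feature_dim)."""
        batch = np.asarray(batch, dtype=np.float64)
        if batch.shape[-1] != self.cfg.input_side:
            raise ValueError(f"input side {batch.shape[-1]} != configured "
                             f"{self.cfg.input_side}")
        x = Tensor(batch)
        for conv in self.convs:
            x = avg_pool2(conv(x).relu())
        x = x.mean(axis=(2, 3))          # global average pool -> (B, C)
        return self.fc(x)

    def encode_slice(self, image: np.ndarray) -> np.ndarray:
        was = self.training
        self.eval()
        with no_grad():
            out = self(np.asarray(image)[None])[0]
        self.train(was)
        return out.data

    def freeze(self) -> "CNNEncoder":
        for p in self.parameters():
            p.requires_grad = False
        return self


def cnn_encode_volume(encoder: CNNEncoder, seq: SliceSequence,
                      batch_size: int = 32,
                      standardize: str = "none") -> FeatureSequence:
    """Order-preserving, label-propagating volume encoding (same contract as
    the ViT arm)."""
    return _encode_volume(encoder, seq, batch_size=batch_size,
                          standardize=standardize)
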