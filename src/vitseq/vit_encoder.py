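"""Vision-transformer slice encoder: patchify, embed, attend, read out.

Each 224x224 slice is cut into non-overlapping 16x16 patches on a 14x14
grid — 196 tokens — each flattened channel-major and linearly projected to
the model dimension D. A learnable class token is prepended and learnable
position embeddings added; `depth` pre-norm transformer blocks
(multi-head self-attention + feed-forward) then mix the tokens, and the
slice feature is the final-layer class-token state (or the token mean when
the class token is disabled). Encoding a whole slice sequence yields the
(n_slices x D) feature sequence consumed by the sequence heads.

Two stock configurations are provided: ``vit_b16_config()`` matching the
standard ViT-B/16 layout (D=768, depth 12, 12 heads), and
``test_scale_config()`` (D=32, depth 2, 2 heads) sized for CPU runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autograd import Tensor, no_grad
from .nn import LayerNorm, Linear, Module, Parameter, TransformerBlock
from .slicer import SliceSequence, to_encoder_input

__all__ = [
    "PatchSequence", "EncoderConfig", "FeatureSequence", "patchify",
    "unpatchify", "ViTEncoder", "encode_volume", "load_pretrained",
    "vit_b16_config", "test_scale_config",
    "save_feature_sequence", "load_feature_sequence",
]


@dataclass
class PatchSequence:
    """Row-major grid of flattened (channel-major) image patches."""

    tokens: np.ndarray            # (n_patches, channels * patch_side**2)
    patch_side: int
    grid: tuple[int, int]
    channels: int

    @property
    def n_patches(self) -> int:
        return self.tokens.shape[0]


@dataclass
class EncoderConfig:
    """Architecture hyperparameters for the slice encoder."""

    embed_dim: int = 768
    depth: int = 12
    n_heads: int = 12
    mlp_ratio: float = 4.0
    patch_side: int = 16
    image_side: int = 224
    in_channels: int = 3
    use_class_token: bool = True
    pretrained_weights: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} must be divisible by "
                f"n_heads {self.n_heads}")
        if self.image_side % self.patch_side != 0:
            raise ValueError(
                f"patch_side {self.patch_side} must divide image side "
                f"{self.image_side}")

    @property
    def grid(self) -> tuple[int, int]:
        g = self.image_side // self.patch_side
        return (g, g)

    @property
    def n_patches(self) -> int:
        g = self.grid
        return g[0] * g[1]


def vit_b16_config(**overrides) -> EncoderConfig:
    """ViT-B/16 layout: 768-dim, 12 blocks, 12 heads, 16-pixel patches."""
    return EncoderConfig(**overrides)


def test_scale_config(**overrides) -> EncoderConfig:
    """Small CPU-friendly encoder (D=32, depth 2, 2 heads), same geometry."""
    kw = dict(embed_dim=32, depth=2, n_heads=2, mlp_ratio=2.0)
    kw.update(overrides)
    return EncoderConfig(**kw)


@dataclass
class FeatureSequence:
    """Per-slice feature vectors (n_slices x D) for one volume and plane."""

    features: np.ndarray
    plane: str
    label: str | None = None
    subject_id: str | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("features must be (n_slices, D)")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")

    @property
    def n_slices(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


def patchify(image: np.ndarray, patch_side: int) -> PatchSequence:
    """Cut a (C, H, W) image into non-overlapping flattened patches.

    Patches are ordered row-major over the grid; each token is the patch
    flattened channel-major (C, p, p) -> C*p*p. The operation tiles the
    image exactly and is inverted by :func:`unpatchify`.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[None]
    C, H, W = image.shape
    p = patch_side
    if H % p or W % p:
        raise ValueError(f"patch side {p} does not divide image sides {(H, W)}")
    gh, gw = H // p, W // p
    tok = image.reshape(C, gh, p, gw, p).transpose(1, 3, 0, 2, 4)
    tokens = tok.reshape(gh * gw, C * p * p)
    return PatchSequence(tokens=tokens, patch_side=p, grid=(gh, gw), channels=C)


def unpatchify(patches: PatchSequence) -> np.ndarray:
    """Exact inverse of :func:`patchify`."""
    gh, gw = patches.grid
    p, C = patches.patch_side, patches.channels
    tok = patches.tokens.reshape(gh, gw, C, p, p).transpose(2, 0, 3, 1, 4)
    return tok.reshape(C, gh * p, gw * p)


def _batch_patchify(batch: np.ndarray, patch_side: int) -> np.ndarray:
    """(B, C, H, W) -> (B, n_patches, C*p*p), row-major grid, channel-major."""
    B, C, H, W = batch.shape
    p = patch_side
    gh, gw = H // p, W // p
    tok = batch.reshape(B, C, gh, p, gw, p).transpose(0, 2, 4, 1, 3, 5)
    return tok.reshape(B, gh * gw, C * p * p)


class ViTEncoder(Module):
    """Patch-embedding transformer producing one D-dim feature per slice."""

    def __init__(self, cfg: EncoderConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        patch_dim = cfg.in_channels * cfg.patch_side ** 2
        self.patch_proj = Linear(patch_dim, cfg.embed_dim, rng)
        n_tok = cfg.n_patches + (1 if cfg.use_class_token else 0)
        if cfg.use_class_token:
            self.cls_token = Parameter(rng.normal(0, 0.02, size=(1, 1, cfg.embed_dim)))
        self.pos_embed = Parameter(rng.normal(0, 0.02, size=(1, n_tok, cfg.embed_dim)))
        self.blocks = [TransformerBlock(cfg.embed_dim, cfg.n_heads,
                                        cfg.mlp_ratio, rng)
                       for _ in range(cfg.depth)]
        self.norm = LayerNorm(cfg.embed_dim)
        if cfg.pretrained_weights is not None:
            load_pretrained(self, cfg.pretrained_weights)

    # -- token-level pieces (exposed for testing/inspection) ----------------

    def embed_tokens(self, patch_tokens: Tensor | np.ndarray) -> Tensor:
        """Project patches to D, prepend class token, add position embeddings."""
        if not isinstance(patch_tokens, Tensor):
            patch_tokens = Tensor(np.asarray(patch_tokens, dtype=np.float64))
        if patch_tokens.ndim == 2:
            patch_tokens = patch_tokens.reshape(1, *patch_tokens.shape)
        B, N, _ = patch_tokens.shape
        x = self.patch_proj(patch_tokens)                     # (B, N, D)
        if self.cfg.use_class_token:
            cls = self.cls_token * Tensor(np.ones((B, 1, 1)))  # broadcast copy
            x = Tensor.concat([cls, x], axis=1)
        return x + self.pos_embed

    def forward_tokens(self, batch: np.ndarray) -> Tensor:
        """Full forward pass returning all token states (B, T, D)."""
        tokens = _batch_patchify(np.asarray(batch, dtype=np.float64),
                                 self.cfg.patch_side)
        x = self.embed_tokens(Tensor(tokens))
        for blk in self.blocks:
            x = blk(x)
        return self.norm(x)

    def __call__(self, batch: np.ndarray) -> Tensor:
        """(B, C, S, S) slice batch -> (B, D) slice features."""
        x = self.forward_tokens(batch)
        if self.cfg.use_class_token:
            return x[:, 0, :]
        return x.mean(axis=1)

    # -- convenience ---------------------------------------------------------

    def encode_slice(self, image: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode feature for one (C, S, S) slice."""
        was_training = self.training
        self.eval()
        with no_grad():
            out = self(np.asarray(image)[None])[0]
        self.train(was_training)
        return out.data

    def freeze(self) -> "ViTEncoder":
        for p in self.parameters():
            p.requires_grad = False
        return self

    def unfreeze(self) -> "ViTEncoder":
        for p in self.parameters():
            p.requires_grad = True
        return self


def encode_volume(encoder: Module, seq: SliceSequence,
                  batch_size: int = 32, standardize: str = "none") -> FeatureSequence:
    """Encode every slice of a prepared sequence, preserving order and label."""
    batch = to_encoder_input(seq, standardize=standardize)
    was_training = getattr(encoder, "training", False)
    if hasattr(encoder, "eval"):
        encoder.eval()
    feats = []
    with no_grad():
        for i in range(0, batch.shape[0], batch_size):
            feats.append(encoder(batch[i:i + batch_size]).data)
    if hasattr(encoder, "train"):
        encoder.train(was_training)
    return FeatureSequence(features=np.concatenate(feats, axis=0),
                           plane=seq.plane, label=seq.label,
                           subject_id=seq.subject_id)


def load_pretrained(encoder: ViTEncoder, weights: str | Path | None,
                    freeze: bool = False) -> ViTEncoder:
    """Load encoder parameters from an .npz state file.

    A missing/None path leaves the seeded random initialization in place.
    Layout mismatches are reported per-parameter by ``load_state_dict``.
    """
    if weights is not None and Path(weights).exists():
        with np.load(str(weights)) as z:
            encoder.load_state_dict({k: z[k] for k in z.files})
    if freeze:
        encoder.freeze()
    return encoder


def save_weights(encoder: Module, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(str(path), **encoder.state_dict())
    return path


def save_feature_sequence(fs: FeatureSequence, path: str | Path) -> Path:
    """One .npz per volume: features plus plane/label/subject metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(str(path), features=fs.features,
             plane=np.array(fs.plane),
             label=np.array(fs.label if fs.label is not None else ""),
             subject_id=np.array(fs.subject_id if fs.subject_id is not None else ""))
    return path


def save_feature_sequence_csv(fs: FeatureSequence, path: str | Path) -> Path:
    """CSV export (rows = slices, columns = feature dims); handy for small D."""
    import pandas as pd
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(fs.features,
                      columns=[f"f{i}" for i in range(fs.dim)])
    df.insert(0, "slice", np.arange(fs.n_slices))
    df.to_csv(path, index=False)
    return path


def load_feature_sequence(path: str | Path) -> FeatureSequence:
    with np.load(str(path)) as z:
        label = str(z["label"]) or None
        subject = str(z["subject_id"]) or None
        return FeatureSequence(features=z["features"], plane=str(z["plane"]),
                               label=label, subject_id=subject)
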