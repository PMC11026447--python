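"""Sequence heads classifying per-slice feature sequences.

Two heads share the FeatureSequence contract:

* :class:`TSTClassifier` — the time-series transformer. Because each slice
  already arrives as a D-dimensional feature vector from the encoder, the
  model needs no embedding module: its model dimension must equal the
  incoming feature dimension. Sinusoidal (or learned) positional encodings
  restore slice order, transformer blocks mix along the slice axis, tokens
  are pooled (mean by default, or a class token) and a linear head emits
  class probabilities.
* :class:`BiLSTMClassifier` — the recurrent baseline: a bidirectional LSTM
  over the slice axis whose final forward and backward states are
  concatenated and linearly mapped to class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .nn import (BiLSTM, Dropout, Linear, Module, Parameter, TransformerBlock)
from .vit_encoder import FeatureSequence

__all__ = ["TSTConfig", "BiLSTMConfig", "sinusoidal_positional_encoding",
           "positional_encode", "TSTClassifier", "BiLSTMClassifier",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TSTConfig:
    """Time-series-transformer head; ``model_dim`` must equal the encoder D."""

    model_dim: int
    n_classes: int
    depth: int = 2
    n_heads: int = 2
    mlp_ratio: float = 2.0
    pooling: str = "mean"                  # or "class_token"
    positional: str = "sinusoidal"         # "sinusoidal" | "learned" | "none"
    max_len: int = 160                     # for learned positions
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.pooling not in ("mean", "class_token"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.positional not in ("sinusoidal", "learned", "none"):
            raise ValueError(f"unknown positional mode {self.positional!r}")
        if self.positional == "sinusoidal" and self.model_dim % 2:
            raise ValueError("sinusoidal positional encoding needs an even "
                             "model_dim (sin/cos pairing)")


@dataclass
class BiLSTMConfig:
    """Bidirectional-LSTM head over the slice axis."""

    n_classes: int
    hidden_dim: int = 128
    n_layers: int = 1
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if self.hidden_dim < 1 or self.n_layers < 1:
            raise ValueError("hidden_dim and n_layers must be >= 1")


def sinusoidal_positional_encoding(n_positions: int, dim: int) -> np.ndarray:
    """Fixed sin/cos position table: pe[t, 2i] = sin(t / 10000^(2i/dim)),
    pe[t, 2i+1] = cos(same). Position 0 is therefore (0, 1, 0, 1, ...)."""
    if dim % 2:
        raise ValueError("sinusoidal encoding requires an even dimension")
    pos = np.arange(n_positions)[:, None]
    i = np.arange(dim // 2)[None, :]
    angle = pos / np.power(10000.0, 2 * i / dim)
    pe = np.empty((n_positions, dim))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def positional_encode(features: np.ndarray) -> np.ndarray:
    """Add the sinusoidal table to an (n_slices, D) or (B, n, D) array."""
    features = np.asarray(features, dtype=np.float64)
    n, d = features.shape[-2], features.shape[-1]
    return features + sinusoidal_positional_encoding(n, d)


def _coerce_batch(features) -> np.ndarray:
    if isinstance(features, FeatureSequence):
        features = features.features
    arr = np.asarray(features, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("expected (n_slices, D) or (B, n_slices, D) features")
    return arr


class TSTClassifier(Module):
    def __init__(self, cfg: TSTConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.model_dim
        if cfg.pooling == "class_token":
            self.cls_token = Parameter(rng.normal(0, 0.02, size=(1, 1, d)))
        if cfg.positional == "learned":
            self.pos_embed = Parameter(rng.normal(0, 0.02, size=(1, cfg.max_len, d)))
        self.blocks = [TransformerBlock(d, cfg.n_heads, cfg.mlp_ratio, rng,
                                        dropout=cfg.dropout)
                       for _ in range(cfg.depth)]
        self.drop = Dropout(cfg.dropout, rng)
        self.head = Linear(d, cfg.n_classes, rng)

    def _positions(self, n: int) -> Tensor | None:
        if self.cfg.positional == "sinusoidal":
            return Tensor(sinusoidal_positional_encoding(n, self.cfg.model_dim)[None])
        if self.cfg.positional == "learned":
            if n > self.cfg.max_len:
                raise ValueError(f"sequence length {n} exceeds max_len "
                                 f"{self.cfg.max_len} for learned positions")
            return self.pos_embed[:, :n, :]
        return None

    def logits(self, features) -> Tensor:
        x = _coerce_batch(features)
        B, n, d = x.shape
        if d != self.cfg.model_dim:
            raise ValueError(
                f"feature dim {d} != model_dim {self.cfg.model_dim}; the TST "
                "has no embedding module, so dimensions must match")
        t = Tensor(x)
        pos = self._positions(n)
        if pos is not None:
            t = t + pos
        if self.cfg.pooling == "class_token":
            cls = self.cls_token * Tensor(np.ones((B, 1, 1)))
            t = Tensor.concat([cls, t], axis=1)
        t = self.drop(t)
        for blk in self.blocks:
            t = blk(t)
        pooled = t[:, 0, :] if self.cfg.pooling == "class_token" else t.mean(axis=1)
        return self.head(pooled)

    def __call__(self, features) -> Tensor:
        return self.logits(features)

    def predict_proba(self, features) -> np.ndarray:
        was = self.training
        self.eval()
        from .autograd import no_grad
        with no_grad():
            p = self.logits(features).softmax(axis=-1).data
        self.train(was)
        return p


class BiLSTMClassifier(Module):
    def __init__(self, cfg: BiLSTMConfig, feature_dim: int):
        super().__init__()
        self.cfg = cfg
        self.feature_dim = feature_dim
        rng = np.random.default_rng(cfg.seed)
        self.rnn = BiLSTM(feature_dim, cfg.hidden_dim, cfg.n_layers, rng)
        self.drop = Dropout(cfg.dropout, rng)
        self.head = Linear(2 * cfg.hidden_dim, cfg.n_classes, rng)

    def logits(self, features) -> Tensor:
        x = _coerce_batch(features)
        if x.shape[-1] != self.feature_dim:
            raise ValueError(f"feature dim {x.shape[-1]} != expected "
                             f"{self.feature_dim}")
        state = self.rnn(Tensor(x))
        return self.head(self.drop(state))

    def __call__(self, features) -> Tensor:
        return self.logits(features)

    def predict_proba(self, features) -> np.ndarray:
        was = self.training
        self.eval()
        from .autograd import no_grad
        with no_grad():
            p = self.logits(features).softmax(axis=-1).data
        self.train(was)
        return p


def save_checkpoint(model: Module, path) -> None:
    """Save head weights with the config embedded, so a checkpoint is
    self-describing."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(model.cfg)
    kind = "tst" if isinstance(model, TSTClassifier) else "bilstm"
    meta = {"kind": kind, "config": cfg}
    if kind == "bilstm":
        meta["feature_dim"] = model.feature_dim
    state = {f"param::{k}": v for k, v in model.state_dict().items()}
    np.savez(str(path), __meta__=np.array(json.dumps(meta)), **state)


def load_checkpoint(path) -> Module:
    """Rebuild a sequence head (and its weights) from a checkpoint file."""
    import json

    with np.load(str(path)) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k[len("param::"):]: z[k] for k in z.files
                 if k.startswith("param::")}
    if meta["kind"] == "tst":
        model: Module = TSTClassifier(TSTConfig(**meta["config"]))
    else:
        model = BiLSTMClassifier(BiLSTMConfig(**meta["config"]),
                                 feature_dim=meta["feature_dim"])
    model.load_state_dict(state)
    return model
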