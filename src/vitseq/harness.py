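"""Experimental protocol: splits, training, metrics, repeated runs and the
architectures x planes comparison.

The protocol mirrors a slice-sequence classification study design:

* random 60/20/20 train/test/validation split of scans (test and validation
  counts floored, train takes the remainder — the rule that maps 351 scans
  to (211, 70, 70) and 2294 to (1378, 458, 458)), optionally stratified;
* per-slice features from a frozen encoder (ViT or CNN arm) feed a sequence
  head (TST or Bi-LSTM) trained with Adam on cross-entropy with early
  stopping on validation loss;
* evaluation via a fixed-class-order confusion matrix from which accuracy,
  per-class and macro precision/recall/F1 are derived;
* k repeated split/train/evaluate cycles reported as mean +/- sample
  standard deviation of each metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autograd import no_grad
from .cnn_baseline import CNNConfig, CNNEncoder
from .nn import Adam, Module, cross_entropy
from .phantom import CLASS_ORDER
from .seq_models import (BiLSTMClassifier, BiLSTMConfig, TSTClassifier,
                         TSTConfig)
from .slicer import extract_slices, resize_sequence
from .vit_encoder import (EncoderConfig, ViTEncoder, encode_volume,
                          test_scale_config)

__all__ = [
    "SplitSpec", "split_counts", "random_split", "EvaluationReport",
    "report_from_confusion", "TrainConfig", "train", "evaluate",
    "RunAggregate", "repeated_runs", "featurize_dataset",
    "compare_architectures", "ARCHITECTURES", "make_encoder", "make_head",
]

ARCHITECTURES: tuple[str, ...] = ("CNN-Bi-LSTM", "CNN-TST",
                                  "ViT-Bi-LSTM", "ViT-TST")

#: scan counts per diagnostic class of the two ADNI collections the method
#: was designed around (access-restricted; used for split-arithmetic checks)
REFERENCE_COLLECTIONS: dict[str, dict[str, int]] = {
    "complete_3yr_3t": {"NC": 129, "MCI": 145, "AD": 77},
    "complete_1yr_1_5t": {"NC": 705, "MCI": 1113, "AD": 476},
}


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_counts(n_total: int,
                 fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                 ) -> tuple[int, int, int]:
    """(n_train, n_test, n_val) under floor(test)/floor(val)/remainder(train)."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    f_train, f_test, f_val = fractions
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    n_test = int(np.floor(f_test * n_total))
    n_val = int(np.floor(f_val * n_total))
    n_train = n_total - n_test - n_val
    return n_train, n_test, n_val


@dataclass
class SplitSpec:
    n_total: int
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    @property
    def counts(self) -> tuple[int, int, int]:
        return split_counts(self.n_total, self.fractions)


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integerize proportional targets so they sum to `total`."""
    base = np.floor(targets).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(targets - base), kind="stable")
        base[order[:short]] += 1
    return base


def random_split(labels, spec: SplitSpec, stratified: bool = True,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive (train, test, val) index arrays.

    Deterministic given ``spec.seed``. When stratified, each split's class
    composition matches the overall proportions within one item (largest
    remainder apportionment inside each split).
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n != spec.n_total:
        raise ValueError(f"labels length {n} != spec.n_total {spec.n_total}")
    n_train, n_test, n_val = spec.counts
    classes = [c for c in CLASS_ORDER if c in set(labels)] or \
        sorted(set(labels))
    if n < len(classes):
        raise ValueError("cannot split fewer items than classes")
    rng = np.random.default_rng(spec.seed)

    if not stratified:
        perm = rng.permutation(n)
        test = perm[:n_test]
        val = perm[n_test:n_test + n_val]
        train = perm[n_test + n_val:]
        return np.sort(train), np.sort(test), np.sort(val)

    counts = np.array([(labels == c).sum() for c in classes])
    if np.any(counts == 0):
        raise ValueError("stratified split infeasible: empty class")
    test_alloc = _largest_remainder(n_test * counts / n, n_test)
    val_alloc = _largest_remainder(n_val * counts / n, n_val)
    # every class must be represented in every nonempty split
    if (np.any(test_alloc + val_alloc >= counts)
            or (n_test > 0 and np.any(test_alloc == 0))
            or (n_val > 0 and np.any(val_alloc == 0))):
        raise ValueError("stratified split infeasible for tiny classes")
    train_idx, test_idx, val_idx = [], [], []
    for c, t_c, v_c in zip(classes, test_alloc, val_alloc):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        test_idx.append(idx[:t_c])
        val_idx.append(idx[t_c:t_c + v_c])
        train_idx.append(idx[t_c + v_c:])
    return (np.sort(np.concatenate(train_idx)),
            np.sort(np.concatenate(test_idx)),
            np.sort(np.concatenate(val_idx)))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Confusion matrix (rows = true, cols = predicted) and derived metrics.

    All metrics are computed from the matrix alone. Accuracy is a percent;
    precision/recall/F1 are in [0, 1]. A class with no predicted (resp.
    true) instances gets precision (resp. recall) 0 with an explicit
    ``undefined_*`` flag instead of a silent NaN.
    """

    confusion: np.ndarray
    class_names: tuple[str, ...]
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    undefined_precision: np.ndarray
    undefined_recall: np.ndarray

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    @property
    def n_samples(self) -> int:
        return int(self.confusion.sum())


def report_from_confusion(confusion, class_names) -> EvaluationReport:
    M = np.asarray(confusion, dtype=np.int64)
    K = len(class_names)
    if M.shape != (K, K):
        raise ValueError(f"confusion must be {K}x{K}")
    if np.any(M < 0) or M.sum() == 0:
        raise ValueError("confusion entries must be >= 0 with positive total")
    diag = np.diag(M).astype(float)
    col = M.sum(axis=0).astype(float)
    row = M.sum(axis=1).astype(float)
    undef_p = col == 0
    undef_r = row == 0
    precision = np.where(undef_p, 0.0, diag / np.where(col == 0, 1, col))
    recall = np.where(undef_r, 0.0, diag / np.where(row == 0, 1, row))
    pr = precision + recall
    f1 = np.where(pr == 0, 0.0, 2 * precision * recall / np.where(pr == 0, 1, pr))
    return EvaluationReport(
        confusion=M, class_names=tuple(class_names),
        accuracy=100.0 * diag.sum() / M.sum(),
        precision=precision, recall=recall, f1=f1,
        undefined_precision=undef_p, undefined_recall=undef_r)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 8
    epochs: int = 100
    patience: int = 10
    seed: int = 0


def _batch_loss_acc(model: Module, X: np.ndarray, y: np.ndarray,
                    batch_size: int = 32) -> tuple[float, float]:
    was = model.training
    model.eval()
    losses, correct = [], 0
    with no_grad():
        for i in range(0, len(X), batch_size):
            xb, yb = X[i:i + batch_size], y[i:i + batch_size]
            logits = model.logits(xb)
            losses.append(float(cross_entropy(logits, yb).data) * len(xb))
            correct += int((logits.data.argmax(axis=1) == yb).sum())
    model.train(was)
    return sum(losses) / len(X), correct / len(X)


def train(model: Module, X: np.ndarray, y: np.ndarray,
          X_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
          cfg: TrainConfig | None = None) -> dict:
    """Minimize cross-entropy with Adam; early-stop on validation loss.

    Returns a history dict with per-epoch train/val loss and accuracy.
    The best-validation-loss parameters are restored on exit (final
    parameters when no validation set is given). Fully deterministic given
    ``cfg.seed`` and the model's init.
    """
    cfg = cfg or TrainConfig()
    if len(X) == 0:
        raise ValueError("empty training split")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    history: dict = {"train_loss": [], "train_acc": [],
                     "val_loss": [], "val_acc": []}
    best_val = np.inf
    best_state = None
    since_best = 0
    model.train(True)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            logits = model.logits(xb)
            loss = cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite training loss (divergence)")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(idx)
            ep_correct += int((logits.data.argmax(axis=1) == yb).sum())
        history["train_loss"].append(ep_loss / len(X))
        history["train_acc"].append(ep_correct / len(X))
        if X_val is not None and len(X_val):
            vl, va = _batch_loss_acc(model, X_val, y_val)
            history["val_loss"].append(vl)
            history["val_acc"].append(va)
            if vl < best_val - 1e-12:
                best_val = vl
                best_state = model.state_dict()
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return history


def evaluate(model: Module, X: np.ndarray, y: np.ndarray,
             class_names) -> EvaluationReport:
    """Argmax prediction per volume -> fixed-class-order confusion -> metrics."""
    if len(X) == 0:
        raise ValueError("empty evaluation set")
    y = np.asarray(y)
    K = len(class_names)
    if y.min() < 0 or y.max() >= K:
        raise ValueError("label outside the declared class set")
    probs = []
    for i in range(0, len(X), 32):
        probs.append(model.predict_proba(X[i:i + 32]))
    preds = np.concatenate(probs).argmax(axis=1)
    M = np.zeros((K, K), dtype=np.int64)
    np.add.at(M, (y, preds), 1)
    return report_from_confusion(M, class_names)


# ---------------------------------------------------------------------------
# Architecture factories and featurization
# ---------------------------------------------------------------------------

def make_encoder(arch: str, seed: int, scale: str = "test",
                 feature_dim: int = 32) -> Module:
    """Frozen per-slice encoder for the given architecture arm."""
    if arch not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {arch!r}; "
                         f"choose from {ARCHITECTURES}")
    if arch.startswith("ViT"):
        if scale == "test":
            cfg = test_scale_config(embed_dim=feature_dim, seed=seed)
        else:
            cfg = EncoderConfig(seed=seed)
        return ViTEncoder(cfg)
    return CNNEncoder(CNNConfig(feature_dim=feature_dim, seed=seed))


def make_head(arch: str, model_dim: int, n_classes: int, seed: int,
              tst_overrides: dict | None = None,
              bilstm_overrides: dict | None = None) -> Module:
    if arch.endswith("TST"):
        kw = dict(depth=2, n_heads=2)
        kw.update(tst_overrides or {})
        return TSTClassifier(TSTConfig(model_dim=model_dim,
                                       n_classes=n_classes, seed=seed, **kw))
    kw = dict(hidden_dim=32, n_layers=1)
    kw.update(bilstm_overrides or {})
    return BiLSTMClassifier(BiLSTMConfig(n_classes=n_classes, seed=seed, **kw),
                            feature_dim=model_dim)


def featurize_dataset(volumes, plane: str, encoder: Module,
                      ) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Slice, resize and encode every volume; returns (X, y, class_names).

    X is (n_volumes, n_slices, D); labels are mapped to integers in the
    fixed severity order NC < MCI < AD.
    """
    present = {v.label for v in volumes}
    class_names = tuple(c for c in CLASS_ORDER if c in present)
    feats, ys = [], []
    for vol in volumes:
        seq = resize_sequence(extract_slices(vol, plane))
        fs = encode_volume(encoder, seq)
        feats.append(fs.features)
        ys.append(class_names.index(vol.label))
    return np.stack(feats), np.asarray(ys), class_names


# ---------------------------------------------------------------------------
# Repeated runs and the full comparison
# ---------------------------------------------------------------------------

@dataclass
class RunAggregate:
    """k repeated split/train/evaluate cycles, aggregated as mean +/- sd."""

    runs: list[EvaluationReport]
    accuracy_mean: float
    accuracy_std: float
    macro_precision_mean: float
    macro_recall_mean: float
    macro_f1_mean: float
    confusion_total: np.ndarray = field(default=None)

    @property
    def k(self) -> int:
        return len(self.runs)


def _aggregate(runs: list[EvaluationReport]) -> RunAggregate:
    accs = np.array([r.accuracy for r in runs])
    std = float(accs.std(ddof=1)) if len(accs) > 1 else 0.0
    return RunAggregate(
        runs=runs,
        accuracy_mean=float(accs.mean()), accuracy_std=std,
        macro_precision_mean=float(np.mean([r.macro_precision for r in runs])),
        macro_recall_mean=float(np.mean([r.macro_recall for r in runs])),
        macro_f1_mean=float(np.mean([r.macro_f1 for r in runs])),
        confusion_total=np.sum([r.confusion for r in runs], axis=0))


def repeated_runs(X: np.ndarray, y: np.ndarray, class_names, arch: str,
                  k: int, base_seed: int, train_cfg: TrainConfig | None = None,
                  fractions=(0.6, 0.2, 0.2), stratified: bool = True,
                  head_overrides: dict | None = None,
                  standardize_features: bool = True) -> RunAggregate:
    """k independent split/train/evaluate cycles with seeds base_seed..+k-1.

    Per cycle, feature dimensions are z-scored with statistics fitted on the
    training split only (``standardize_features``): frozen random encoders
    can emit arbitrarily scaled features, and the heads (positional
    encodings, LSTM gates) expect unit-scale inputs.
    """
    if k < 2:
        raise ValueError("repeated_runs needs k >= 2")
    train_cfg = train_cfg or TrainConfig()
    labels = np.asarray([class_names[i] for i in y])
    runs = []
    for run in range(k):
        seed = base_seed + run
        spec = SplitSpec(n_total=len(X), fractions=fractions, seed=seed)
        tr, te, va = random_split(labels, spec, stratified=stratified)
        if standardize_features:
            mu = X[tr].mean(axis=(0, 1))
            sd = X[tr].std(axis=(0, 1))
            sd[sd == 0] = 1.0
            Xrun = (X - mu) / sd
        else:
            Xrun = X
        head = make_head(arch, X.shape[-1], len(class_names), seed,
                         tst_overrides=head_overrides if arch.endswith("TST") else None,
                         bilstm_overrides=head_overrides if arch.endswith("LSTM") else None)
        cfg = TrainConfig(lr=train_cfg.lr, batch_size=train_cfg.batch_size,
                          epochs=train_cfg.epochs, patience=train_cfg.patience,
                          seed=seed)
        train(head, Xrun[tr], y[tr], Xrun[va], y[va], cfg)
        runs.append(evaluate(head, Xrun[te], y[te], class_names))
    return _aggregate(runs)


def compare_architectures(volumes, planes, architectures, task: str, k: int,
                          base_seed: int = 0,
                          train_cfg: TrainConfig | None = None,
                          feature_dim: int = 32, scale: str = "test",
                          ) -> tuple[pd.DataFrame, dict]:
    """Plane x architecture comparison table (mean ACC +/- sd, macro P/R/F1).

    ``task`` is "binary" (NC/AD only — MCI volumes are dropped before
    splitting) or "multiclass" (NC/MCI/AD). Returns the results table plus
    the summed test-set confusion matrix per (plane, architecture) cell.
    """
    if task not in ("binary", "multiclass"):
        raise ValueError("task must be 'binary' or 'multiclass'")
    planes = list(planes)
    architectures = list(architectures)
    if not planes or not architectures:
        raise ValueError("empty plane or architecture selection")
    bad = set(architectures) - set(ARCHITECTURES)
    if bad:
        raise ValueError(f"unknown architectures {sorted(bad)}")
    if task == "binary":
        volumes = [v for v in volumes if v.label != "MCI"]
    # desk-scale schedule: small heads converge within ~120 epochs at 1e-3
    train_cfg = train_cfg or TrainConfig(lr=1e-3, epochs=120, patience=25)
    rows, confusions = [], {}
    for plane in planes:
        feature_cache: dict[str, tuple] = {}
        for arch in architectures:
            arm = "ViT" if arch.startswith("ViT") else "CNN"
            if arm not in feature_cache:
                encoder = make_encoder(arch, seed=base_seed, scale=scale,
                                       feature_dim=feature_dim)
                if hasattr(encoder, "freeze"):
                    encoder.freeze()
                feature_cache[arm] = featurize_dataset(volumes, plane, encoder)
            X, y, class_names = feature_cache[arm]
            agg = repeated_runs(X, y, class_names, arch, k=k,
                                base_seed=base_seed, train_cfg=train_cfg)
            rows.append({
                "plane": plane, "architecture": arch, "task": task,
                "acc_mean": agg.accuracy_mean, "acc_std": agg.accuracy_std,
                "precision": agg.macro_precision_mean,
                "recall": agg.macro_recall_mean,
                "f1": agg.macro_f1_mean, "k": agg.k,
            })
            confusions[(plane, arch)] = agg.confusion_total
    return pd.DataFrame(rows), confusions
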