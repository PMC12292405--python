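"""Balanced-batch training, slide-level prediction, and evaluation metrics.

Training follows the reference protocol: Adam with learning rate 0.001,
categorical cross-entropy, up to 400 epochs with batch size 8, early
stopping on validation loss with patience 20, restoring the weights of the
best validation epoch.  Every batch holds exactly ``batch_size / 2`` samples
of each class; the minority class is oversampled with replacement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import f1_score, precision_score, recall_score, roc_auc_score

from .graphs import SlideGraph
from .nn.layers import Adam

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "balanced_batches",
    "graphs_to_arrays",
    "train",
    "predict_slide",
    "metrics",
    "dice",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    epochs: int = 400
    batch_size: int = 8
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate, epochs, batch_size must be positive")
        if self.patience < 0 or self.patience > self.epochs:
            raise ValueError("patience must be in [0, epochs]")


@dataclass
class MetricsReport:
    acc: float
    auc: float
    macro_f1: float
    precision: dict[int, float] = field(default_factory=dict)
    recall: dict[int, float] = field(default_factory=dict)
    dice: float | None = None

    def to_dict(self) -> dict:
        out = {"acc": self.acc, "auc": self.auc, "macro_f1": self.macro_f1}
        out.update({f"precision_{k}": v for k, v in self.precision.items()})
        out.update({f"recall_{k}": v for k, v in self.recall.items()})
        if self.dice is not None:
            out["dice"] = self.dice
        return out


def balanced_batches(
    labels: Sequence[int], batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Index batches with exactly ``batch_size/2`` samples per class.

    The larger class is covered once per epoch in shuffled order; the
    smaller class is sampled with replacement as needed, so its indices may
    repeat within an epoch.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("balanced batching requires exactly two classes present")
    if batch_size % 2 != 0:
        raise ValueError("batch_size must be even")
    half = batch_size // 2
    idx = {c: rng.permutation(np.flatnonzero(y == c)) for c in classes}
    n_batches = max(1, math.ceil(max(len(v) for v in idx.values()) / half))
    streams = {}
    for c, order in idx.items():
        need = n_batches * half
        if len(order) < need:
            extra = rng.choice(np.flatnonzero(y == c), size=need - len(order),
                               replace=True)
            order = np.concatenate([order, extra])
        streams[c] = order[:need]
    batches = []
    for b in range(n_batches):
        chunk = np.concatenate(
            [streams[c][b * half:(b + 1) * half] for c in classes]
        )
        batches.append(rng.permutation(chunk))
    return batches


def graphs_to_arrays(
    graphs: Sequence[SlideGraph], input_keys: Sequence[str] = ("X",)
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Stack per-slide tensors into batched arrays keyed for the heads."""
    source = {
        "X": lambda g: g.X,
        "A_hat": lambda g: g.A_hat,
        "mask": lambda g: g.node_mask.astype(np.float64),
        "H": lambda g: g.X,
    }
    inputs = {k: np.stack([source[k](g) for g in graphs]) for k in input_keys}
    labels = np.array([g.label for g in graphs], dtype=int)
    return inputs, labels


def _onehot(y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


def train(
    head,
    train_graphs: Sequence[SlideGraph],
    val_graphs: Sequence[SlideGraph],
    config: TrainConfig | None = None,
) -> tuple[object, dict[str, list[float]]]:
    """Train a head with balanced batches and early stopping.

    Returns the head with the minimum-validation-loss weights restored, and
    a history dict (per-epoch train loss, val loss, val accuracy).
    """
    if config is None:
        config = TrainConfig()
    if not train_graphs or not val_graphs:
        raise ValueError("train and validation splits must be non-empty")
    rng = np.random.default_rng(config.seed)
    keys = head.input_keys
    Xtr, ytr = graphs_to_arrays(train_graphs, keys)
    Xva, yva = graphs_to_arrays(val_graphs, keys)
    onehot_va = _onehot(yva)
    optimizer = Adam(head.parameters(), lr=config.learning_rate)

    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "val_acc": []}
    best_state = head.state_dict()
    best_val = np.inf
    since_best = 0

    for epoch in range(config.epochs):
        epoch_losses = []
        for batch in balanced_batches(ytr, config.batch_size, rng):
            inputs = {k: v[batch] for k, v in Xtr.items()}
            head.zero_grad()
            loss = head.loss(_onehot(ytr[batch]), **inputs)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}"
                )
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))

        val_loss = float(head.loss(onehot_va, **Xva).data)
        probs = head.predict_proba(**Xva)
        val_acc = float(np.mean((probs[:, 1] > 0.5).astype(int) == yva))
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)

        if val_loss < best_val:
            best_val = val_loss
            best_state = head.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best > config.patience:
                logger.info("early stopping at epoch %d (best val %.4f)",
                            epoch, best_val)
                break

    head.load_state_dict(best_state)
    return head, history


def predict_slide(head, graph: SlideGraph, threshold: float = 0.5) -> int:
    """Slide label: 1 iff P(class 1) strictly exceeds ``threshold``."""
    inputs, _ = graphs_to_arrays([graph], head.input_keys)
    probs = head.predict_proba(**inputs)
    return int(probs[0, 1] > threshold)


def metrics(labels: Sequence[int], probabilities: np.ndarray) -> MetricsReport:
    """ACC at the 0.5 threshold, rank AUC (ties get half credit), macro-F1.

    ``probabilities`` may be (n,) class-1 probabilities or an (n, 2) matrix.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim == 2:
        p = p[:, 1]
    if np.unique(y).size < 2:
        raise ValueError("AUC undefined: only one class present")
    pred = (p > 0.5).astype(int)
    acc = float(np.mean(pred == y))
    auc = float(roc_auc_score(y, p))
    macro_f1 = float(f1_score(y, pred, average="macro", zero_division=0))
    prec = precision_score(y, pred, average=None, labels=[0, 1], zero_division=0)
    rec = recall_score(y, pred, average=None, labels=[0, 1], zero_division=0)
    return MetricsReport(
        acc=acc, auc=auc, macro_f1=macro_f1,
        precision={0: float(prec[0]), 1: float(prec[1])},
        recall={0: float(rec[0]), 1: float(rec[1])},
    )


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient ``2|A n B| / (|A| + |B|)``; both-empty masks give 1."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / total)
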