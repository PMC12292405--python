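"""Slide-level classifier heads.

All heads map per-slide inputs to probabilities over {0 = AC, 1 = SCC}:

* :class:`OneDCNN` — node features stacked without spatial information,
  1-D convolutions along the node axis (32 then 64 filters, kernel 3),
  max-pool, global average pool, dense softmax.  The reference head of the
  pipeline.  Global average pooling runs over the full padded axis (plain
  zero padding; padded rows are zero by construction).
* :class:`TwoDCNN` — treats the (N_max, d_out) matrix as a one-channel
  image; two 2-D conv blocks, pooling, global average pool, dense softmax.
* :class:`GCNN` — two graph convolutions ``H <- ReLU(A_hat H W)`` with the
  symmetric normalized adjacency, mask-aware mean over real nodes, dense
  softmax.
* :class:`GatedAttentionMIL` — gated attention over a bag of fixed-length
  graph embeddings (Ilse-style): ``e_k = w^T (tanh(V h_k) * sigmoid(U h_k))``,
  masked softmax weights, weighted bag vector, dense softmax.
* :class:`TransMILHead` — a learnable class token prepended to the bag, a
  trainable positional embedding, two single-head transformer encoder
  blocks with padding-mask-aware self-attention, classification from the
  class token.
* :func:`classical_features` + :class:`ClassicalHead` — mask-aware mean
  aggregation per slide, then a decision tree / random forest / SVM /
  XGBoost fitted through the established library implementations.

Layer widths and kernel sizes are fixed reference defaults; they can be
changed via constructor arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .graphs import SlideGraph
from .nn.autograd import Tensor, concat, softmax, softmax_cross_entropy
from .nn.layers import (
    Module,
    conv1d,
    conv2d,
    glorot,
    layer_norm,
    maxpool1d,
    maxpool2d,
)

__all__ = [
    "OneDCNN",
    "TwoDCNN",
    "GCNN",
    "GatedAttentionMIL",
    "TransMILHead",
    "classical_features",
    "ClassicalHead",
    "make_head",
]


class _SoftmaxHead(Module):
    """Shared helpers: probability output and thresholded prediction."""

    def predict_proba(self, **inputs) -> np.ndarray:
        logits = self.forward(**{k: Tensor(v) for k, v in inputs.items()})
        return softmax(logits).data

    def loss(self, onehot: np.ndarray, **inputs) -> Tensor:
        logits = self.forward(**{k: Tensor(v) for k, v in inputs.items()})
        return softmax_cross_entropy(logits, onehot)


class OneDCNN(_SoftmaxHead):
    """conv(32, k3) -> ReLU -> conv(64, k3) -> ReLU -> maxpool(2) -> GAP -> dense."""

    input_keys = ("X",)

    def __init__(self, d_in: int, filters: tuple[int, int] = (32, 64),
                 kernel: int = 3, n_classes: int = 2, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        f1, f2 = filters
        self.W1 = self.param("W1", glorot(rng, (kernel, d_in, f1)))
        self.b1 = self.param("b1", np.zeros(f1))
        self.W2 = self.param("W2", glorot(rng, (kernel, f1, f2)))
        self.b2 = self.param("b2", np.zeros(f2))
        self.Wd = self.param("Wd", glorot(rng, (f2, n_classes)))
        self.bd = self.param("bd", np.zeros(n_classes))

    def forward(self, X: Tensor) -> Tensor:
        h = conv1d(X, self.W1, self.b1).relu()
        h = conv1d(h, self.W2, self.b2).relu()
        h = maxpool1d(h, 2)
        h = h.mean(axis=1)           # global average pool over the node axis
        return h @ self.Wd + self.bd


class TwoDCNN(_SoftmaxHead):
    """Two conv-2D blocks on the (N_max, d_out, 1) 'image', pool, GAP, dense."""

    input_keys = ("X",)

    def __init__(self, d_in: int, filters: tuple[int, int] = (8, 16),
                 kernel: int = 3, n_classes: int = 2, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        f1, f2 = filters
        self.W1 = self.param("W1", glorot(rng, (kernel, kernel, 1, f1)))
        self.b1 = self.param("b1", np.zeros(f1))
        self.W2 = self.param("W2", glorot(rng, (kernel, kernel, f1, f2)))
        self.b2 = self.param("b2", np.zeros(f2))
        self.Wd = self.param("Wd", glorot(rng, (f2, n_classes)))
        self.bd = self.param("bd", np.zeros(n_classes))

    def forward(self, X: Tensor) -> Tensor:
        B, N, d = X.shape
        h = X.reshape(B, N, d, 1)
        h = conv2d(h, self.W1, self.b1).relu()
        h = maxpool2d(h, 2) if N >= 2 and d >= 2 else h
        h = conv2d(h, self.W2, self.b2).relu()
        h = h.mean(axis=1).mean(axis=1)   # global average pool over H and W
        return h @ self.Wd + self.bd


class GCNN(_SoftmaxHead):
    """Two normalized-adjacency graph convolutions, masked mean, dense softmax."""

    input_keys = ("X", "A_hat", "mask")

    def __init__(self, d_in: int, hidden: tuple[int, int] = (16, 32),
                 n_classes: int = 2, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        h1, h2 = hidden
        self.W1 = self.param("W1", glorot(rng, (d_in, h1)))
        self.b1 = self.param("b1", np.zeros(h1))
        self.W2 = self.param("W2", glorot(rng, (h1, h2)))
        self.b2 = self.param("b2", np.zeros(h2))
        self.Wd = self.param("Wd", glorot(rng, (h2, n_classes)))
        self.bd = self.param("bd", np.zeros(n_classes))

    def forward(self, X: Tensor, A_hat: Tensor, mask: Tensor) -> Tensor:
        H1 = (A_hat @ (X @ self.W1 + self.b1)).relu()
        H2 = (A_hat @ (H1 @ self.W2 + self.b2)).relu()
        m = mask.reshape(*mask.shape, 1)
        pooled = (H2 * m).sum(axis=1) / m.sum(axis=1)
        return pooled @ self.Wd + self.bd


class GatedAttentionMIL(_SoftmaxHead):
    """Gated attention pooling over a bag of instance embeddings."""

    input_keys = ("H", "mask")

    def __init__(self, d_in: int, d_att: int = 16, n_classes: int = 2,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.V = self.param("V", glorot(rng, (d_in, d_att)))
        self.U = self.param("U", glorot(rng, (d_in, d_att)))
        self.w = self.param("w", glorot(rng, (d_att, 1)))
        self.Wd = self.param("Wd", glorot(rng, (d_in, n_classes)))
        self.bd = self.param("bd", np.zeros(n_classes))

    def attention(self, H: Tensor, mask: Tensor) -> Tensor:
        """Masked softmax attention weights over instances, (B, K)."""
        if not np.asarray(mask.data, dtype=bool).any(axis=-1).all():
            raise ValueError("every bag needs at least one real instance")
        gate = (H @ self.V).tanh() * (H @ self.U).sigmoid()
        e = (gate @ self.w).reshape(H.shape[0], H.shape[1])
        neg = Tensor((1.0 - mask.data) * -1e9)
        return softmax(e + neg, axis=-1)

    def forward(self, H: Tensor, mask: Tensor) -> Tensor:
        a = self.attention(H, mask)
        z = (H * a.reshape(*a.shape, 1)).sum(axis=1)
        return z @ self.Wd + self.bd


class TransMILHead(_SoftmaxHead):
    """Class token + positional embedding + two transformer encoder blocks.

    Single attention head, model width 64 by default; the attention mask
    excludes padded instances as keys (the class token is always attended).
    """

    input_keys = ("H", "mask")

    def __init__(self, d_in: int, n_positions: int, d_model: int = 64,
                 d_ff: int = 128, n_blocks: int = 2, n_classes: int = 2,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.d_model = d_model
        self.n_blocks = n_blocks
        self.Win = self.param("Win", glorot(rng, (d_in, d_model)))
        self.bin = self.param("bin", np.zeros(d_model))
        self.cls = self.param("cls", rng.normal(0, 0.02, size=(1, 1, d_model)))
        self.pos = self.param(
            "pos", rng.normal(0, 0.02, size=(1, n_positions + 1, d_model))
        )
        for i in range(n_blocks):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                self.param(f"{name}{i}", glorot(rng, (d_model, d_model)))
            self.param(f"F1_{i}", glorot(rng, (d_model, d_ff)))
            self.param(f"f1b_{i}", np.zeros(d_ff))
            self.param(f"F2_{i}", glorot(rng, (d_ff, d_model)))
            self.param(f"f2b_{i}", np.zeros(d_model))
            self.param(f"g1_{i}", np.ones(d_model))
            self.param(f"beta1_{i}", np.zeros(d_model))
            self.param(f"g2_{i}", np.ones(d_model))
            self.param(f"beta2_{i}", np.zeros(d_model))
        self.Wd = self.param("Wd", glorot(rng, (d_model, n_classes)))
        self.bd = self.param("bd", np.zeros(n_classes))

    def forward(self, H: Tensor, mask: Tensor) -> Tensor:
        if not np.asarray(mask.data, dtype=bool).any(axis=-1).all():
            raise ValueError("every bag needs at least one real instance")
        B, K, _ = H.shape
        x = H @ self.Win + self.bin
        cls = Tensor(np.ones((B, 1, 1))) * self.cls
        x = concat([cls, x], axis=1)                       # (B, K+1, d_model)
        x = x + self.pos[:, : K + 1, :]
        key_mask = np.concatenate(
            [np.ones((B, 1)), np.asarray(mask.data, dtype=np.float64)], axis=1
        )
        neg = Tensor(((1.0 - key_mask) * -1e9)[:, None, :])  # (B, 1, K+1)
        scale = 1.0 / np.sqrt(self.d_model)
        p = self._params
        for i in range(self.n_blocks):
            q = x @ p[f"Wq{i}"]
            k = x @ p[f"Wk{i}"]
            v = x @ p[f"Wv{i}"]
            scores = q @ k.transpose((0, 2, 1)) * scale + neg
            att = softmax(scores, axis=-1)
            attended = (att @ v) @ p[f"Wo{i}"]
            x = layer_norm(x + attended, p[f"g1_{i}"], p[f"beta1_{i}"])
            ff = ((x @ p[f"F1_{i}"] + p[f"f1b_{i}"]).relu()
                  @ p[f"F2_{i}"] + p[f"f2b_{i}"])
            x = layer_norm(x + ff, p[f"g2_{i}"], p[f"beta2_{i}"])
        cls_out = x[:, 0, :]
        return cls_out @ self.Wd + self.bd


def classical_features(graphs: Sequence[SlideGraph]) -> np.ndarray:
    """One row per slide: mask-aware mean of node features over real nodes."""
    if not graphs:
        raise ValueError("no graphs given")
    rows = []
    for g in graphs:
        if g.n_real == 0:
            raise ValueError(f"slide {g.slide_id} has zero real nodes")
        rows.append(g.X[g.node_mask].mean(axis=0))
    return np.stack(rows)


class ClassicalHead:
    """Uniform fit/predict wrapper over DT / RF / SVM / XGBoost."""

    KINDS = ("dt", "rf", "svm", "xgb")

    def __init__(self, kind: str, seed: int = 0, **kwargs):
        if kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}")
        self.kind = kind
        if kind == "dt":
            from sklearn.tree import DecisionTreeClassifier
            self.model = DecisionTreeClassifier(random_state=seed, **kwargs)
        elif kind == "rf":
            from sklearn.ensemble import RandomForestClassifier
            self.model = RandomForestClassifier(random_state=seed, **kwargs)
        elif kind == "svm":
            from sklearn.svm import SVC
            self.model = SVC(probability=True, random_state=seed, **kwargs)
        else:
            from xgboost import XGBClassifier
            self.model = XGBClassifier(random_state=seed, **kwargs)

    def fit(self, graphs: Sequence[SlideGraph], labels: Sequence[int]):
        self.model.fit(classical_features(graphs), np.asarray(labels))
        return self

    def predict_proba(self, graphs: Sequence[SlideGraph]) -> np.ndarray:
        return self.model.predict_proba(classical_features(graphs))


def make_head(kind: str, d_in: int, seed: int = 0, **kwargs):
    """Factory over all head kinds used by the pipeline and CLI."""
    table = {
        "onedcnn": OneDCNN,
        "twodcnn": TwoDCNN,
        "gcnn": GCNN,
        "mil": GatedAttentionMIL,
        "transmil": TransMILHead,
    }
    if kind in table:
        return table[kind](d_in=d_in, seed=seed, **kwargs)
    if kind.startswith("classical:"):
        return ClassicalHead(kind.split(":", 1)[1], seed=seed, **kwargs)
    raise ValueError(f"unknown head kind {kind!r}")
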