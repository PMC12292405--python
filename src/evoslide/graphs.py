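"""Per-slide graphs from projected patch features and patch positions.

Each slide becomes a fixed-size node set: projected feature rows ordered
raster-style (row-major by patch box origin), zero-padded or trimmed to
``N_max`` nodes.  Edges connect patches whose centers lie within a Euclidean
radius (default ``stride * 1.05``, a 4-neighborhood on a regular tiling),
found with a KD-tree.  The propagation operator is the symmetric normalized
adjacency

    A_hat = D^{-1/2} (A + I) D^{-1/2},   D = degree matrix of (A + I),

computed over real nodes only; the padded block of ``A_hat`` is the identity
so batched tensors stay well-formed.  Graphs persist as JSON containers with
a sha256 payload checksum (a portable, versioned replacement for pickled
graphs).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .preprocess import PatchRecord

__all__ = [
    "SlideGraph",
    "assemble_slide",
    "infer_nmax",
    "build_graph",
    "normalize_adjacency",
    "save_graph",
    "load_graph",
]

GRAPH_FORMAT_VERSION = 1


@dataclass
class SlideGraph:
    """Padded node features, adjacency, normalized adjacency and metadata."""

    X: np.ndarray            # (N_max, d_out), zero-padded
    A: np.ndarray            # (N_max, N_max) binary, zero diagonal
    A_hat: np.ndarray        # (N_max, N_max), identity on the padded block
    node_mask: np.ndarray    # (N_max,) bool
    n_real: int
    label: int
    slide_id: str
    positions: np.ndarray    # (n_real, 2) patch centers, pixels

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.A = np.asarray(self.A)
        self.A_hat = np.asarray(self.A_hat, dtype=np.float64)
        self.node_mask = np.asarray(self.node_mask, dtype=bool)
        self.positions = np.asarray(self.positions, dtype=np.float64)

    def validate(self) -> None:
        N = self.X.shape[0]
        assert self.A.shape == (N, N) and self.A_hat.shape == (N, N)
        assert self.node_mask.shape == (N,)
        assert self.node_mask.sum() == self.n_real
        assert np.array_equal(self.A, self.A.T)
        assert not self.A.diagonal().any()
        pad = ~self.node_mask
        assert not self.A[pad].any() and not self.A[:, pad].any()
        assert not self.X[pad].any()


def assemble_slide(
    records: Sequence[PatchRecord],
    projected: np.ndarray,
    N_max: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Order nodes raster-style, then pad or trim to ``N_max``.

    ``records`` and rows of ``projected`` must be aligned one-to-one.  If
    there are more than ``N_max`` patches, the first ``N_max`` in raster
    order are kept.  Returns ``(X, positions, node_mask)``.
    """
    projected = np.asarray(projected, dtype=np.float64)
    if len(records) != projected.shape[0]:
        raise ValueError(
            f"{len(records)} records but {projected.shape[0]} feature rows"
        )
    if N_max < 1:
        raise ValueError("N_max must be >= 1")
    order = sorted(range(len(records)), key=lambda i: (records[i].box[1], records[i].box[0]))
    order = order[:N_max]
    d = projected.shape[1]
    X = np.zeros((N_max, d))
    mask = np.zeros(N_max, dtype=bool)
    positions = np.empty((len(order), 2))
    for slot, i in enumerate(order):
        X[slot] = projected[i]
        mask[slot] = True
        x0, y0, x1, y1 = records[i].box
        positions[slot] = ((x0 + x1) / 2.0, (y0 + y1) / 2.0)
    return X, positions, mask


def infer_nmax(node_counts: Sequence[int]) -> int:
    """Largest node count over the training slides (persisted with the model)."""
    counts = list(node_counts)
    if not counts:
        raise ValueError("infer_nmax needs at least one slide")
    return int(max(counts))


def build_graph(positions: np.ndarray, radius: float) -> np.ndarray:
    """Radius-neighbor adjacency over patch centers (inclusive boundary).

    Implemented with a KD-tree; pairs at distance exactly ``radius`` are
    connected.  Duplicate positions are rejected.
    """
    pts = np.asarray(positions, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("positions must be (n, 2)")
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = pts.shape[0]
    if len({tuple(p) for p in pts}) != n:
        raise ValueError("duplicate patch positions")
    A = np.zeros((n, n), dtype=np.int8)
    if n > 1:
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(r=radius):
            A[i, j] = A[j, i] = 1
    return A


def normalize_adjacency(
    A: np.ndarray, node_mask: np.ndarray | None = None
) -> np.ndarray:
    """Symmetric normalization ``D^{-1/2} (A + I) D^{-1/2}`` over real nodes."""
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("A must be symmetric")
    if A.diagonal().any():
        raise ValueError("A must have a zero diagonal")
    N = A.shape[0]
    if node_mask is None:
        node_mask = np.ones(N, dtype=bool)
    node_mask = np.asarray(node_mask, dtype=bool)
    real = np.flatnonzero(node_mask)
    A_hat = np.eye(N)
    if real.size:
        Ar = A[np.ix_(real, real)] + np.eye(real.size)
        dinv = 1.0 / np.sqrt(Ar.sum(axis=1))
        A_hat[np.ix_(real, real)] = dinv[:, None] * Ar * dinv[None, :]
    return A_hat


def _payload(graph: SlideGraph) -> dict:
    return {
        "X": graph.X.tolist(),
        "A": graph.A.astype(int).tolist(),
        "A_hat": graph.A_hat.tolist(),
        "node_mask": graph.node_mask.astype(int).tolist(),
        "positions": graph.positions.tolist(),
    }


def _checksum(payload: dict) -> str:
    canonical = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


def save_graph(graph: SlideGraph, path) -> None:
    """Write a graph as a versioned, checksummed JSON container."""
    payload = _payload(graph)
    doc = {
        "format": "evoslide-graph",
        "version": GRAPH_FORMAT_VERSION,
        "slide_id": graph.slide_id,
        "label": int(graph.label),
        "n_real": int(graph.n_real),
        "N_max": int(graph.X.shape[0]),
        "d_out": int(graph.X.shape[1]),
        "checksum": _checksum(payload),
        "payload": payload,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_graph(path) -> SlideGraph:
    """Inverse of :func:`save_graph`; verifies version and checksum."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "evoslide-graph":
        raise ValueError("not an evoslide graph file")
    if doc.get("version") != GRAPH_FORMAT_VERSION:
        raise ValueError(
            f"graph format version {doc.get('version')} not supported "
            f"(expected {GRAPH_FORMAT_VERSION})"
        )
    payload = doc["payload"]
    if _checksum(payload) != doc["checksum"]:
        raise ValueError("graph payload checksum mismatch")
    return SlideGraph(
        X=np.array(payload["X"], dtype=np.float64),
        A=np.array(payload["A"], dtype=np.int8),
        A_hat=np.array(payload["A_hat"], dtype=np.float64),
        node_mask=np.array(payload["node_mask"], dtype=bool),
        n_real=int(doc["n_real"]),
        label=int(doc["label"]),
        slide_id=doc["slide_id"],
        positions=np.array(payload["positions"], dtype=np.float64),
    )
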