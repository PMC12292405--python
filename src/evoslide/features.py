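"""Patch featurization: a deterministic built-in extractor plus a plug-in
contract for pretrained backbones.

The built-in extractor produces, per patch, a 64-bin intensity histogram
concatenated with a 32-bin gradient-orientation histogram (magnitude
weighted), each block L1-normalized, giving ``d_in = 96``.  It needs no
downloaded weights, is fully deterministic, and separates the synthetic
texture classes (isotropic blobs vs oriented stripes) by construction: the
orientation block concentrates for stripes and spreads for blobs.

A pretrained CNN backbone (the reference setup used a 1024-dimensional
DenseNet121 embedding) can be plugged in through ``ExtractorSpec`` with
``kind="external_backbone"`` and a callable mapping a patch batch to a
feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage.filters import sobel_h, sobel_v
from skimage.transform import resize

__all__ = ["FeatureMatrix", "ExtractorSpec", "extract_features", "augment"]

N_INTENSITY_BINS = 64
N_ORIENT_BINS = 32
BUILTIN_DIM = N_INTENSITY_BINS + N_ORIENT_BINS


@dataclass
class FeatureMatrix:
    """n_patches x d_in feature rows with row <-> patch correspondence."""

    values: np.ndarray
    row_index: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.row_index) != self.values.shape[0]:
            raise ValueError("row_index length must equal number of rows")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")

    @property
    def d_in(self) -> int:
        return self.values.shape[1]

    @property
    def n_patches(self) -> int:
        return self.values.shape[0]


@dataclass
class ExtractorSpec:
    kind: str = "builtin_histogram"
    resize_to: int = 224
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("builtin_histogram", "external_backbone"):
            raise ValueError(f"unknown extractor kind {self.kind!r}")
        if self.resize_to < 16:
            raise ValueError("resize_to must be >= 16")


def _to_gray(patch: np.ndarray) -> np.ndarray:
    arr = np.asarray(patch, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise ValueError("patch must be a 2-D grayscale or RGB image")
    return arr


def _builtin_row(patch: np.ndarray, resize_to: int) -> np.ndarray:
    img = _to_gray(patch)
    if img.shape != (resize_to, resize_to):
        img = resize(
            img, (resize_to, resize_to), order=1, mode="reflect",
            anti_aliasing=img.shape[0] > resize_to, preserve_range=True,
        )
    hist, _ = np.histogram(img, bins=N_INTENSITY_BINS, range=(0.0, 256.0))
    hist = hist.astype(np.float64)
    if hist.sum() > 0:
        hist /= hist.sum()

    gy, gx = sobel_h(img), sobel_v(img)
    mag = np.hypot(gx, gy)
    ang = np.arctan2(gy, gx)
    ohist, _ = np.histogram(
        ang, bins=N_ORIENT_BINS, range=(-np.pi, np.pi), weights=mag
    )
    ohist = ohist.astype(np.float64)
    if ohist.sum() > 0:
        ohist /= ohist.sum()
    return np.concatenate([hist, ohist])


def extract_features(
    patches: Sequence[np.ndarray],
    spec: ExtractorSpec | None = None,
    patch_ids: Sequence | None = None,
) -> FeatureMatrix:
    """Featurize patches in order; rows follow the input patch order."""
    if spec is None:
        spec = ExtractorSpec()
    patches = list(patches)
    if not patches:
        raise ValueError("no patches to featurize")
    if patch_ids is None:
        patch_ids = list(range(len(patches)))
    if spec.kind == "external_backbone":
        fn: Callable = spec.params.get("fn")
        if fn is None:
            raise ValueError("external_backbone requires params['fn']")
        values = np.asarray(fn(patches), dtype=np.float64)
        if values.shape[0] != len(patches):
            raise ValueError("backbone returned wrong number of rows")
    else:
        values = np.stack([_builtin_row(p, spec.resize_to) for p in patches])
    return FeatureMatrix(values=values, row_index=list(patch_ids))


_AUG_OPS = (
    lambda p: p,
    lambda p: p[:, ::-1],          # horizontal flip
    lambda p: p[::-1, :],          # vertical flip
    lambda p: np.rot90(p, 1),
    lambda p: np.rot90(p, 2),
    lambda p: np.rot90(p, 3),
)


def augment(patch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One of identity / flips / right-angle rotations, chosen by ``rng``.

    All operations are label-preserving pixel permutations, so the intensity
    histogram of the built-in extractor is exactly invariant.
    """
    op = _AUG_OPS[int(rng.integers(len(_AUG_OPS)))]
    return np.ascontiguousarray(op(np.asarray(patch)))
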