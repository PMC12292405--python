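"""Synthetic data: labeled feature sets and miniature textured slides.

Two generators replace the non-public slide cohorts:

* :func:`gen_feature_set` draws labeled Gaussian feature matrices in which the
  class signal sits on designated *low-variance* axes while the remaining axes
  carry high-variance nuisance noise.  Variance-maximizing projections (PCA)
  then align with the nuisance axes and achieve near-zero class silhouette,
  while a supervised search can recover the signal axes — the qualitative
  regime the evolutionary projection is designed for.

* :func:`gen_slide` renders a miniature "slide": a uniform glass-gray
  background (level 230, zero gradient, so gradient-based masking excludes
  it) with high-gradient texture on tissue patches.  Class 0 tissue carries
  isotropic Gaussian blobs, class 1 carries oriented stripes; both are found
  by Sobel+Otsu masking but differ in histogram features, so the built-in
  extractor separates the classes.

All outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import FeatureMatrix

__all__ = [
    "SyntheticFeatureSpec",
    "SyntheticSlideSpec",
    "SyntheticSlide",
    "gen_feature_set",
    "gen_slide",
    "gen_dataset",
    "random_slide_spec",
]

BACKGROUND_LEVEL = 230


@dataclass
class SyntheticFeatureSpec:
    """Recipe for a two-class Gaussian feature set.

    Class 0 has mean zero everywhere; class 1 has mean ``separation_delta``
    on every signal axis.  Per-axis standard deviation is ``signal_sd`` on
    signal axes and ``nuisance_sd`` elsewhere.
    """

    n_per_class: int = 200
    dim: int = 20
    signal_axes: tuple[int, ...] = (0,)
    separation_delta: float = 6.0
    signal_sd: float = 0.5
    nuisance_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.signal_axes = tuple(int(a) for a in self.signal_axes)
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if not self.signal_axes:
            raise ValueError("at least one signal axis required")
        if any(a < 0 or a >= self.dim for a in self.signal_axes):
            raise ValueError("signal_axes must lie in [0, dim)")
        if len(set(self.signal_axes)) != len(self.signal_axes):
            raise ValueError("signal_axes must be distinct")
        if self.signal_sd <= 0 or self.nuisance_sd <= 0:
            raise ValueError("standard deviations must be positive")


def gen_feature_set(
    spec: SyntheticFeatureSpec,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Draw ``2 * n_per_class`` labeled feature rows (class 0 first)."""
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_class
    sds = np.full(spec.dim, spec.nuisance_sd)
    sds[list(spec.signal_axes)] = spec.signal_sd
    X = rng.normal(0.0, 1.0, size=(n, spec.dim)) * sds
    labels = np.repeat([0, 1], spec.n_per_class)
    X[spec.n_per_class:, list(spec.signal_axes)] += spec.separation_delta
    fm = FeatureMatrix(values=X, row_index=[f"sample_{i}" for i in range(n)])
    return fm, labels


@dataclass
class SyntheticSlideSpec:
    """Recipe for one miniature slide on a ``grid_rows x grid_cols`` patch grid."""

    grid_rows: int = 8
    grid_cols: int = 8
    patch_px: int = 32
    tissue_region: np.ndarray = None  # bool (grid_rows, grid_cols)
    tumor_region: np.ndarray = None   # bool, subset of tissue_region
    class_label: int = 0
    texture_kind: str | None = None   # default: blobs for class 0, stripes for 1
    seed: int = 0
    slide_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.patch_px < 4:
            raise ValueError("patch_px must be >= 4")
        if self.class_label not in (0, 1):
            raise ValueError("class_label must be 0 or 1")
        shape = (self.grid_rows, self.grid_cols)
        if self.tissue_region is None:
            self.tissue_region = np.ones(shape, dtype=bool)
        self.tissue_region = np.asarray(self.tissue_region, dtype=bool)
        if self.tissue_region.shape != shape:
            raise ValueError("tissue_region shape must match the grid")
        if not self.tissue_region.any():
            raise ValueError("tissue_region must contain at least one patch")
        if self.tumor_region is None:
            self.tumor_region = self.tissue_region.copy()
        self.tumor_region = np.asarray(self.tumor_region, dtype=bool)
        if self.tumor_region.shape != shape:
            raise ValueError("tumor_region shape must match the grid")
        if (self.tumor_region & ~self.tissue_region).any():
            raise ValueError("tumor_region must be a subset of tissue_region")
        if self.texture_kind is None:
            self.texture_kind = "blobs" if self.class_label == 0 else "stripes"
        if self.texture_kind not in ("blobs", "stripes"):
            raise ValueError("texture_kind must be 'blobs' or 'stripes'")


@dataclass
class SyntheticSlide:
    """A rendered miniature slide with ground-truth masks."""

    spec: SyntheticSlideSpec
    thumbnail: np.ndarray      # uint8 (rows*patch_px, cols*patch_px)
    tissue_mask: np.ndarray    # bool, pixel level
    tumor_mask: np.ndarray     # bool, pixel level

    @property
    def slide_id(self) -> str:
        return self.spec.slide_id

    @property
    def label(self) -> int:
        return self.spec.class_label

    def patch(self, row: int, col: int) -> np.ndarray:
        p = self.spec.patch_px
        return self.thumbnail[row * p:(row + 1) * p, col * p:(col + 1) * p]


def _blob_texture(p: int, rng: np.random.Generator) -> np.ndarray:
    """Isotropic dark Gaussian blobs on a light field."""
    yy, xx = np.mgrid[0:p, 0:p]
    tex = np.zeros((p, p))
    n_blobs = 4 + int(rng.integers(4))
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, p, size=2)
        s = rng.uniform(p / 12, p / 6)
        tex += np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s)))
    tex = tex / max(tex.max(), 1e-9)
    return tex


def _stripe_texture(p: int, rng: np.random.Generator) -> np.ndarray:
    """Oriented sinusoidal stripes; orientation fixed per class, phase random."""
    yy, xx = np.mgrid[0:p, 0:p]
    period = p / 2
    phase = rng.uniform(0, 2 * np.pi)
    tex = 0.5 + 0.5 * np.sin(2 * np.pi * (xx + yy) / (np.sqrt(2) * period) + phase)
    return tex


def gen_slide(spec: SyntheticSlideSpec) -> SyntheticSlide:
    """Render a slide: flat background outside tissue, texture inside."""
    rng = np.random.default_rng(spec.seed)
    p = spec.patch_px
    H, W = spec.grid_rows * p, spec.grid_cols * p
    img = np.full((H, W), float(BACKGROUND_LEVEL))
    for r in range(spec.grid_rows):
        for c in range(spec.grid_cols):
            if not spec.tissue_region[r, c]:
                continue
            if spec.texture_kind == "blobs":
                tex = _blob_texture(p, rng)
                amp, offset = 140.0, 0.0
            else:
                tex = _stripe_texture(p, rng)
                # moderate stripe contrast keeps the Otsu threshold governed
                # by the carrier rather than the stripe edges; the constant
                # offset darkens stripe tissue so the intensity histogram
                # separates the classes
                amp, offset = 40.0, 50.0
            tile = BACKGROUND_LEVEL - offset - tex * amp
            # a fine two-axis carrier keeps the gradient magnitude high at
            # essentially every tissue pixel (its zeros are isolated points),
            # so gradient-based masking recovers the full tissue area; random
            # speckle would not survive the morphological opening
            yy, xx = np.mgrid[0:p, 0:p]
            carrier = 30.0 * (np.sin(2 * np.pi * xx / 8.0)
                              + np.cos(2 * np.pi * yy / 8.0))
            tile = tile - carrier + rng.normal(0.0, 2.0, size=tile.shape)
            img[r * p:(r + 1) * p, c * p:(c + 1) * p] = tile
    thumbnail = np.clip(img, 0, 255).astype(np.uint8)
    tissue_mask = np.kron(spec.tissue_region, np.ones((p, p), dtype=bool))
    tumor_mask = np.kron(spec.tumor_region, np.ones((p, p), dtype=bool))
    return SyntheticSlide(
        spec=spec, thumbnail=thumbnail, tissue_mask=tissue_mask,
        tumor_mask=tumor_mask,
    )


def random_slide_spec(
    label: int,
    seed: int,
    grid_rows: int = 8,
    grid_cols: int = 8,
    patch_px: int = 32,
    slide_id: str = "synthetic",
) -> SyntheticSlideSpec:
    """A random connected-ish tissue blob with a tumor sub-region.

    The tissue region is grown from a few random grid seeds by dilation until
    it covers roughly half the grid; the tumor region is a random ~75% subset
    of the tissue (always non-empty).
    """
    rng = np.random.default_rng(seed)
    shape = (grid_rows, grid_cols)
    tissue = np.zeros(shape, dtype=bool)
    n_seeds = 2 + int(rng.integers(2))
    for _ in range(n_seeds):
        tissue[int(rng.integers(grid_rows)), int(rng.integers(grid_cols))] = True
    target = grid_rows * grid_cols // 2
    while tissue.sum() < target:
        grown = tissue.copy()
        grown[1:, :] |= tissue[:-1, :]
        grown[:-1, :] |= tissue[1:, :]
        grown[:, 1:] |= tissue[:, :-1]
        grown[:, :-1] |= tissue[:, 1:]
        # randomly keep ~60% of the newly grown rim to roughen the boundary
        rim = grown & ~tissue
        keep = rng.random(shape) < 0.6
        tissue |= rim & keep
    tumor = tissue & (rng.random(shape) < 0.75)
    if not tumor.any():
        r, c = np.argwhere(tissue)[0]
        tumor[r, c] = True
    return SyntheticSlideSpec(
        grid_rows=grid_rows, grid_cols=grid_cols, patch_px=patch_px,
        tissue_region=tissue, tumor_region=tumor, class_label=label,
        seed=int(rng.integers(2**31 - 1)), slide_id=slide_id,
    )


def gen_dataset(
    n_slides: int,
    class_balance: float = 0.5,
    seed: int = 0,
    grid_rows: int = 8,
    grid_cols: int = 8,
    patch_px: int = 32,
) -> list[SyntheticSlide]:
    """A reproducible collection of slides with the requested label balance.

    ``class_balance`` is the fraction of class-1 slides; the class-1 count is
    ``floor(n_slides * class_balance + 0.5)`` (round half up).
    """
    if n_slides < 2:
        raise ValueError("n_slides must be >= 2")
    if not 0.0 < class_balance < 1.0:
        raise ValueError("class_balance must be in (0, 1)")
    n1 = int(np.floor(n_slides * class_balance + 0.5))
    n1 = min(max(n1, 1), n_slides - 1)
    labels = [0] * (n_slides - n1) + [1] * n1
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_slides)]
    slides = []
    for i, (lab, s) in enumerate(zip(labels, child_seeds)):
        spec = random_slide_spec(
            label=lab, seed=s, grid_rows=grid_rows, grid_cols=grid_cols,
            patch_px=patch_px, slide_id=f"synthetic_{i:03d}",
        )
        slides.append(gen_slide(spec))
    return slides
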