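"""Tissue segmentation and sliding-window patch extraction.

Masking pipeline: Sobel gradient magnitude -> Otsu threshold on the gradient
-> morphological opening (disk, radius 2 thumbnail pixels) -> hole filling.
Glass background is near-constant, so it carries no gradient and is excluded.

Patches are gated by two strict rules: more than 10% of the patch box must be
mask-positive tissue, and a tumor scorer must assign more than 50% tumor
likelihood.  The tumor scorer is an interface; the shipped
:class:`MaskFractionScorer` is a synthetic oracle returning the tumor-mask
fraction of the box (training a patch-wise tumor CNN is out of scope here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import imageio.v3 as iio
from scipy.ndimage import binary_fill_holes
from skimage.filters import sobel, threshold_otsu
from skimage.morphology import disk, opening, remove_small_objects

__all__ = [
    "TissueMask",
    "PatchRecord",
    "TumorScorer",
    "MaskFractionScorer",
    "tissue_mask",
    "tile_positions",
    "score_patches",
    "patch_filter",
    "export_annotated_thumbnail",
]

logger = logging.getLogger(__name__)

TISSUE_THRESHOLD = 0.10
TUMOR_THRESHOLD = 0.50


@dataclass
class TissueMask:
    """Binary tissue mask aligned to the thumbnail.

    ``scale`` maps thumbnail pixels to full-resolution pixels (1.0 when the
    thumbnail is the working magnification, as for the synthetic slides).
    """

    mask: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class PatchRecord:
    """One tile: half-open pixel box at working magnification, plus gating state."""

    slide_id: str
    box: tuple[int, int, int, int]  # (x0, y0, x1, y1), top-left origin
    tissue_fraction: float = 0.0
    tumor_probability: float = 0.0
    retained: bool = False

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"degenerate box {self.box}")

    def to_dict(self) -> dict:
        return {
            "slide_id": self.slide_id,
            "box": list(self.box),
            "tissue_fraction": self.tissue_fraction,
            "tumor_probability": self.tumor_probability,
            "retained": self.retained,
        }


TumorScorer = Callable[[PatchRecord], float]


@dataclass
class MaskFractionScorer:
    """Synthetic tumor oracle: fraction of tumor-mask pixels inside the box."""

    tumor_mask: np.ndarray
    scale: float = 1.0

    def __call__(self, record: PatchRecord) -> float:
        x0, y0, x1, y1 = (int(round(v / self.scale)) for v in record.box)
        h, w = self.tumor_mask.shape
        x0, x1 = max(0, x0), min(w, x1)
        y0, y1 = max(0, y0), min(h, y1)
        if x1 <= x0 or y1 <= y0:
            return 0.0
        sub = self.tumor_mask[y0:y1, x0:x1]
        return float(sub.mean())


def tissue_mask(
    thumbnail: np.ndarray, opening_radius: int = 2, min_size: int = 64,
    scale: float = 1.0,
) -> TissueMask:
    """Segment tissue on a grayscale thumbnail via gradient thresholding.

    Pipeline: Sobel gradient magnitude, Otsu threshold on the gradient,
    morphological opening (disk of ``opening_radius``), hole filling, and
    removal of residual fragments below ``min_size`` pixels.
    """
    img = np.asarray(thumbnail, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.ndim != 2 or min(img.shape) < 32:
        raise ValueError("thumbnail must be a 2-D image of at least 32x32")
    grad = sobel(img)
    if np.ptp(grad) == 0:
        logger.warning("constant gradient image: returning empty tissue mask")
        return TissueMask(mask=np.zeros(img.shape, dtype=bool), scale=scale)
    thr = threshold_otsu(grad)
    binary = grad > thr
    opened = opening(binary, disk(opening_radius))
    filled = binary_fill_holes(opened)
    # max_size removes components of <= that many pixels
    cleaned = remove_small_objects(filled, max_size=min_size - 1)
    return TissueMask(mask=cleaned, scale=scale)


def tile_positions(
    slide_w: int, slide_h: int, patch: int, stride: int
) -> list[tuple[int, int, int, int]]:
    """Row-major half-open boxes of a sliding window fully inside the slide."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if patch < 1:
        raise ValueError("patch must be >= 1")
    if patch > slide_w or patch > slide_h:
        logger.warning(
            "patch %d exceeds slide extent (%d x %d): no positions",
            patch, slide_w, slide_h,
        )
        return []
    boxes = []
    for y0 in range(0, slide_h - patch + 1, stride):
        for x0 in range(0, slide_w - patch + 1, stride):
            boxes.append((x0, y0, x0 + patch, y0 + patch))
    return boxes


def score_patches(
    records: Sequence[PatchRecord],
    mask: TissueMask,
    scorer: TumorScorer,
    tissue_threshold: float = TISSUE_THRESHOLD,
    tumor_threshold: float = TUMOR_THRESHOLD,
) -> list[PatchRecord]:
    """Annotate every record with tissue fraction, tumor probability, retained.

    Retention is strict on both thresholds: ``tissue_fraction > 0.10`` AND
    ``tumor_probability > 0.50``.
    """
    out = []
    h, w = mask.mask.shape
    for rec in records:
        x0, y0, x1, y1 = (int(round(v / mask.scale)) for v in rec.box)
        cx0, cx1 = max(0, x0), min(w, x1)
        cy0, cy1 = max(0, y0), min(h, y1)
        if cx1 <= cx0 or cy1 <= cy0:
            tf = 0.0
        else:
            tf = float(mask.mask[cy0:cy1, cx0:cx1].mean())
        tp = float(scorer(rec))
        if not 0.0 <= tp <= 1.0:
            raise ValueError(f"tumor scorer returned {tp}, outside [0, 1]")
        out.append(
            PatchRecord(
                slide_id=rec.slide_id,
                box=rec.box,
                tissue_fraction=tf,
                tumor_probability=tp,
                retained=(tf > tissue_threshold and tp > tumor_threshold),
            )
        )
    return out


def patch_filter(
    records: Sequence[PatchRecord],
    mask: TissueMask,
    scorer: TumorScorer,
    tissue_threshold: float = TISSUE_THRESHOLD,
    tumor_threshold: float = TUMOR_THRESHOLD,
) -> list[PatchRecord]:
    """Retained records only (see :func:`score_patches` for the rules)."""
    scored = score_patches(records, mask, scorer, tissue_threshold, tumor_threshold)
    return [r for r in scored if r.retained]


def export_annotated_thumbnail(
    thumbnail: np.ndarray,
    records: Sequence[PatchRecord],
    path=None,
    scale: float = 1.0,
) -> np.ndarray:
    """Write the thumbnail with one rectangle outline per retained record.

    Out-of-bounds boxes are clipped with a warning.  Returns the annotated
    RGB image (also written to ``path`` when given).
    """
    img = np.asarray(thumbnail)
    if img.ndim == 2:
        rgb = np.stack([img] * 3, axis=2).astype(np.uint8)
    else:
        rgb = img.astype(np.uint8).copy()
    h, w = rgb.shape[:2]
    for rec in records:
        x0, y0, x1, y1 = (int(round(v / scale)) for v in rec.box)
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            logger.warning("record box %s outside thumbnail: clipped", rec.box)
        x0, x1 = max(0, x0), min(w, x1)
        y0, y1 = max(0, y0), min(h, y1)
        if x1 <= x0 or y1 <= y0:
            continue
        rgb[y0:y1, [x0, x1 - 1]] = (255, 0, 0)
        rgb[[y0, y1 - 1], x0:x1] = (255, 0, 0)
    if path is not None:
        iio.imwrite(path, rgb)
    return rgb
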