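"""Region-of-interest masking: dataset variants used to probe shortcut learning.

A classifier that performs well on images whose clinically relevant region
(lungs in a chest X-ray, optic disc in a fundus photograph) has been removed
must be using something else — a shortcut.  This module builds the five
dataset variants that make that observable:

``FULL``
    the unmodified image,
``ONLY_ROI`` / ``NO_ROI``
    keep only the inside / only the outside of the precise ROI mask,
``ONLY_ROI_BB`` / ``NO_ROI_BB``
    the same with the tightest axis-aligned bounding box of the mask, which
    removes shape information and captures (or excludes) structures adjacent
    to the ROI.

Masked-out pixels take the value 0 ("black"), identical to the padding added
during preprocessing, so that removed regions are indistinguishable from the
image border.  Masking is applied to the [0, 1]-scaled image *before* any
model-specific standardization.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage.morphology import dilation as _gray_dilation, disk
from skimage.transform import resize

logger = logging.getLogger(__name__)

__all__ = [
    "MaskingStrategy",
    "BoundingBox",
    "DilationSpec",
    "DegenerateMaskError",
    "preprocess_image",
    "binarize_mask",
    "compute_bounding_box",
    "bounding_box_mask",
    "apply_strategy",
    "dilate_mask",
    "filter_records",
    "padchest_filter",
    "StrategyMasker",
]


class MaskingStrategy(str, enum.Enum):
    """The five dataset variants. ``FULL`` is the identity."""

    FULL = "FULL"
    NO_ROI = "NO_ROI"
    NO_ROI_BB = "NO_ROI_BB"
    ONLY_ROI = "ONLY_ROI"
    ONLY_ROI_BB = "ONLY_ROI_BB"

    @property
    def uses_bounding_box(self) -> bool:
        return self in (MaskingStrategy.NO_ROI_BB, MaskingStrategy.ONLY_ROI_BB)

    @property
    def keeps_roi(self) -> bool:
        return self in (MaskingStrategy.ONLY_ROI, MaskingStrategy.ONLY_ROI_BB)


class DegenerateMaskError(ValueError):
    """Raised for an all-zero ROI mask where a nonempty one is required."""


@dataclass(frozen=True)
class BoundingBox:
    """Tightest axis-aligned box around the nonzero mask pixels.

    Coordinates are row-major, 0-based, with *inclusive* corners.
    """

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise ValueError(f"inverted bounding box {self}")


@dataclass(frozen=True)
class DilationSpec:
    """A mask-growth step for dilation sweeps.

    factor
        radius, in pixels at the working resolution, of the Euclidean disk
        structuring element; 0 is the identity.
    subset
        which records get their mask dilated: ``all`` for plain sweeps,
        ``positives_only`` / ``negatives_only`` for class-conditional sweeps
        that expose size-of-ROI confounds.
    """

    factor: int
    subset: str = "all"

    _SUBSETS = ("all", "positives_only", "negatives_only")

    def __post_init__(self) -> None:
        if self.factor < 0:
            raise ValueError(f"dilation factor must be >= 0, got {self.factor}")
        if self.subset not in self._SUBSETS:
            raise ValueError(f"subset must be one of {self._SUBSETS}, got {self.subset!r}")


def _to_unit_float(image: np.ndarray) -> np.ndarray:
    """Scale intensities to [0, 1]: integer images by their dtype range,
    float images clipped."""
    if np.issubdtype(image.dtype, np.integer):
        return image.astype(np.float64) / np.iinfo(image.dtype).max
    return np.clip(image.astype(np.float64), 0.0, 1.0)


def preprocess_image(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    size: int = 512,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Resize to ``size``x``size`` preserving aspect ratio, pad with black.

    The image is scaled by ``size / max(H, W)``, centered, and padded with
    zeros to a square; intensities are scaled to [0, 1].  If a mask is given
    the identical geometric transform is applied to it with nearest-neighbor
    interpolation so it stays binary.

    Returns the image, or ``(image, mask)`` when a mask was passed.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 3:  # channels-last RGB: collapse to luminance for the audit
        image = image.mean(axis=2)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D (or HxWx3) image, got shape {image.shape}")

    image = _to_unit_float(image)
    h, w = image.shape
    scale = size / max(h, w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    if (nh, nw) != (h, w):
        image = resize(image, (nh, nw), order=1, anti_aliasing=scale < 1, mode="constant")
    out = np.zeros((size, size), dtype=np.float64)
    r0 = (size - nh) // 2
    c0 = (size - nw) // 2
    out[r0 : r0 + nh, c0 : c0 + nw] = image

    if mask is None:
        return out

    mask = binarize_mask(mask)
    if mask.shape != (h, w):
        raise ValueError(f"mask shape {mask.shape} != image shape {(h, w)}")
    if (nh, nw) != (h, w):
        mask = resize(mask.astype(float), (nh, nw), order=0, mode="constant") > 0.5
    mout = np.zeros((size, size), dtype=np.uint8)
    mout[r0 : r0 + nh, c0 : c0 + nw] = mask.astype(np.uint8)
    return out, mout


def binarize_mask(mask: np.ndarray) -> np.ndarray:
    """Coerce a mask array to {0, 1}.

    8-bit (and wider integer) masks binarize at > 127; float masks at > 0.5.
    """
    mask = np.asarray(mask)
    if np.issubdtype(mask.dtype, np.integer) and mask.max(initial=0) > 1:
        return (mask > 127).astype(np.uint8)
    if np.issubdtype(mask.dtype, np.floating):
        return (mask > 0.5).astype(np.uint8)
    return (mask != 0).astype(np.uint8)


def compute_bounding_box(mask: np.ndarray) -> BoundingBox:
    """Tightest inclusive bounding box of the nonzero pixels.

    Raises :class:`DegenerateMaskError` on an all-zero mask; callers exclude
    such records (with a logged warning) rather than fabricating a box.
    """
    mask = binarize_mask(mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise DegenerateMaskError("all-zero mask has no bounding box")
    return BoundingBox(int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max()))


def bounding_box_mask(mask: np.ndarray) -> np.ndarray:
    """Filled-rectangle mask covering the bounding box of ``mask``."""
    bb = compute_bounding_box(mask)
    out = np.zeros_like(binarize_mask(mask))
    out[bb.row_min : bb.row_max + 1, bb.col_min : bb.col_max + 1] = 1
    return out


def apply_strategy(
    image: np.ndarray,
    mask: np.ndarray,
    strategy: MaskingStrategy | str,
) -> np.ndarray:
    """Apply one of the five masking strategies to a preprocessed image.

    Zeroed pixels take the padding value 0, before any model-specific
    standardization.  ``FULL`` returns the image unchanged.  For the ``_BB``
    variants the filled bounding box of the mask plays the role of the mask;
    an all-zero mask then raises :class:`DegenerateMaskError`.
    """
    strategy = MaskingStrategy(strategy)
    image = np.asarray(image, dtype=np.float64)
    mask = binarize_mask(mask)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    if strategy is MaskingStrategy.FULL:
        return image.copy()
    effective = bounding_box_mask(mask) if strategy.uses_bounding_box else mask
    if strategy.keeps_roi:
        return image * effective
    return image * (1 - effective)


def dilate_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Morphological dilation by a Euclidean disk of radius ``factor`` pixels.

    ``factor=0`` is the identity.  The output is binary and a superset of the
    input.
    """
    if factor < 0:
        raise ValueError(f"dilation factor must be >= 0, got {factor}")
    mask = binarize_mask(mask)
    if factor == 0:
        return mask.copy()
    return _gray_dilation(mask.astype(bool), footprint=disk(factor)).astype(np.uint8)


def filter_records(records: Sequence, quality_threshold: float = 0.7) -> list:
    """Keep records whose mask exists and whose quality is strictly above
    ``quality_threshold``.

    Mirrors the use of automatic mask-quality scores (reverse classification
    accuracy Dice): only masks scored *above* 0.7 are trusted, so a score of
    exactly 0.7 is removed.  Removal counts are logged.
    """
    kept: list = []
    n_no_mask = 0
    n_low_quality = 0
    for rec in records:
        mask = getattr(rec, "mask", None)
        if mask is None or np.asarray(mask).sum() == 0:
            n_no_mask += 1
            continue
        if not (getattr(rec, "mask_quality") > quality_threshold):
            n_low_quality += 1
            continue
        kept.append(rec)
    logger.info(
        "filter_records: kept %d / %d (removed %d without usable mask, %d with quality <= %.3g)",
        len(kept), len(records), n_no_mask, n_low_quality, quality_threshold,
    )
    return kept


_EXCLUDED_LABEL_TOKENS = ("suboptimal study", "exclude", "unchanged")


def padchest_filter(
    metadata_table: pd.DataFrame,
    mask_table: pd.DataFrame,
    quality_threshold: float = 0.7,
    *,
    image_id_column: str = "ImageID",
    projection_column: str = "Projection",
    labels_column: str = "Labels",
    quality_column: str = "Dice RCA (Mean)",
) -> tuple[pd.DataFrame, int]:
    """Record filtering for chest X-ray metadata + mask-quality tables.

    Applies, in order: drop lateral views (``Projection == "L"``); drop rows
    with a null label; drop rows whose label list contains any of
    ``"suboptimal study"``, ``"exclude"``, ``"unchanged"`` (substring match);
    inner-join to the mask table on the image id; keep rows with mask quality
    strictly above ``quality_threshold``.  Column names default to the
    PadChest / CheXmask CSV dialects but are remappable for synthetic
    manifests.

    Returns the surviving rows and their count.
    """
    for col, table, name in (
        (projection_column, metadata_table, "metadata_table"),
        (labels_column, metadata_table, "metadata_table"),
        (image_id_column, metadata_table, "metadata_table"),
        (quality_column, mask_table, "mask_table"),
        (image_id_column, mask_table, "mask_table"),
    ):
        if col not in table.columns:
            raise KeyError(f"required column {col!r} missing from {name}")

    n0 = len(metadata_table)
    df = metadata_table[metadata_table[projection_column] != "L"]
    n1 = len(df)
    df = df[df[labels_column].notna()]
    n2 = len(df)
    labels = df[labels_column].astype(str).str.lower()
    bad = np.zeros(len(df), dtype=bool)
    for token in _EXCLUDED_LABEL_TOKENS:
        bad |= labels.str.contains(token, regex=False).to_numpy()
    df = df[~bad]
    n3 = len(df)
    df = df.merge(mask_table[[image_id_column, quality_column]], on=image_id_column, how="inner")
    n4 = len(df)
    df = df[df[quality_column] > quality_threshold]
    n5 = len(df)
    logger.info(
        "padchest_filter: %d -> %d (lateral) -> %d (null label) -> %d (excluded labels) "
        "-> %d (mask available) -> %d (quality > %.3g)",
        n0, n1, n2, n3, n4, n5, quality_threshold,
    )
    return df.reset_index(drop=True), n5


class StrategyMasker:
    """sklearn-style transformer wrapping :func:`apply_strategy`.

    Stateless; ``fit`` is a no-op.  ``transform`` takes a stack of images and
    the matching stack of masks (masks are data, not parameters, so they are
    an argument of ``transform``).
    """

    def __init__(self, strategy: MaskingStrategy | str = MaskingStrategy.FULL, dilation: int = 0):
        self.strategy = strategy
        self.dilation = dilation

    def get_params(self, deep: bool = True) -> dict:
        return {"strategy": self.strategy, "dilation": self.dilation}

    def set_params(self, **params) -> "StrategyMasker":
        for k, v in params.items():
            if k not in ("strategy", "dilation"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y=None) -> "StrategyMasker":
        return self

    def transform(self, X: Iterable[np.ndarray], masks: Iterable[np.ndarray]) -> np.ndarray:
        out = []
        for image, mask in zip(X, masks):
            if self.dilation:
                mask = dilate_mask(mask, self.dilation)
            out.append(apply_strategy(image, mask, self.strategy))
        return np.stack(out)
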