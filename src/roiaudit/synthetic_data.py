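"""Synthetic image datasets with a known disease signal and planted shortcuts.

The audit in this package asks whether a classifier uses the clinically
relevant region of an image (the ROI) or something else.  To validate the
audit itself we need datasets where the answer is known.  This module
generates grayscale images that emulate the *confound structure* of chest
X-ray and fundus data — not their appearance:

* an anatomically plausible ROI per image (two lung-like ellipses with a
  mediastinal gap, or a single bright optic-disc-like circle),
* a disease signal (an additive Gaussian blob) drawn strictly inside the ROI
  of positive images,
* configurable shortcut signals placed strictly *outside* the ROI: a small
  bright device-like token (think pacemaker), a text-like glyph band along a
  border (think burnt-in camera annotations), or a global intensity offset,
  each present with a configurable label correlation rho,
* an optional ROI-size/label confound (positives get larger ROIs, emulating
  a disc-size bias),
* label-correlated tabular metadata (sex, birth year, projection) with a
  target discriminability, for the tabular baseline.

All randomness flows from one seed through per-record child streams, so the
same config always yields byte-identical images and any subset of records is
reproducible on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.stats import norm
from skimage.morphology import erosion as _gray_erosion, disk

logger = logging.getLogger(__name__)

__all__ = [
    "ShortcutSpec",
    "SyntheticConfig",
    "ImageRecord",
    "ShortcutPlacementError",
    "generate_dataset",
    "generate_metadata",
    "write_dataset",
    "load_dataset",
]

CLASS_NAME = "disease"


class ShortcutPlacementError(RuntimeError):
    """Raised when a shortcut cannot be placed without touching the ROI."""


@dataclass(frozen=True)
class ShortcutSpec:
    """One planted spurious signal.

    kind
        ``token``: small bright rounded rectangle with a lead-like line,
        placed anywhere outside the ROI.
        ``border_text``: high-contrast glyph band in a corner strip of the
        image border.
        ``global_offset``: constant intensity offset on all non-ROI pixels.
    correlation
        rho in [0, 1]: probability that shortcut presence matches the label.
        rho=0.5 makes the shortcut independent of the label; rho=1 makes it a
        perfect proxy.
    placement
        ``outside_roi`` or ``image_border`` (informational for ``token``;
        forced for ``border_text``).
    amplitude
        added intensity on the [0, 1] scale.
    """

    kind: str = "token"
    correlation: float = 0.9
    placement: str = "outside_roi"
    amplitude: float = 0.45

    def __post_init__(self) -> None:
        if self.kind not in ("token", "border_text", "global_offset"):
            raise ValueError(f"unknown shortcut kind {self.kind!r}")
        if not 0.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must lie in [0, 1]")
        if self.placement not in ("outside_roi", "image_border"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    Defaults give a desk-scale dataset (n=600 at 128x128) with a learnable
    in-ROI disease signal, no planted shortcut (all correlations would need a
    spec), balanced labels, and uninformative metadata.  ``image_size=512``
    mirrors full-scale preprocessing.
    """

    n_images: int = 600
    image_size: int = 128
    prevalence: float = 0.5
    roi_shape: str = "two_lungs"  # or "disc"
    disease_amplitude: float = 0.25
    shortcut_specs: tuple[ShortcutSpec, ...] = ()
    roi_size_label_slope: float = 0.0
    metadata_auc: float = 0.5
    noise_sd: float = 0.05
    low_quality_fraction: float = 0.1
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.roi_shape not in ("two_lungs", "disc"):
            raise ValueError(f"unknown roi_shape {self.roi_shape!r}")
        if not 0.5 <= self.metadata_auc <= 1.0:
            raise ValueError("metadata_auc must lie in [0.5, 1]")
        object.__setattr__(self, "shortcut_specs", tuple(self.shortcut_specs))


@dataclass
class ImageRecord:
    """One image with its ROI mask, labels, metadata and bookkeeping.

    ``mask_quality`` stands in for an automatic segmentation-quality score
    (reverse-classification-accuracy Dice); records below 0.7 are meant to be
    filtered out downstream.  ``shortcut_mask`` is generator ground truth
    (the exact pixels any shortcut touched) used to verify that shortcuts
    never intersect the ROI.
    """

    index: int
    image: np.ndarray
    mask: np.ndarray
    labels: np.ndarray
    metadata: dict
    fold: int
    mask_quality: float
    shortcuts_present: dict = field(default_factory=dict)
    shortcut_mask: np.ndarray | None = None
    image_path: str = ""
    mask_path: str = ""


# ---------------------------------------------------------------------------
# geometry


def _ellipse(shape: tuple[int, int], cr: float, cc: float, rr: float, rc: float) -> np.ndarray:
    r = np.arange(shape[0])[:, None]
    c = np.arange(shape[1])[None, :]
    return (((r - cr) / rr) ** 2 + ((c - cc) / rc) ** 2) <= 1.0


def _roi_mask(config: SyntheticConfig, rng: np.random.Generator, positive: bool) -> np.ndarray:
    s = config.image_size
    grow = 1.0 + (config.roi_size_label_slope if positive else 0.0)
    if config.roi_shape == "two_lungs":
        cr = s * (0.50 + 0.02 * rng.normal())
        rr = s * 0.28 * grow * (1 + 0.05 * rng.normal())
        rc = s * 0.11 * grow * (1 + 0.05 * rng.normal())
        left = _ellipse((s, s), cr, s * (0.33 + 0.01 * rng.normal()), rr, rc)
        right = _ellipse((s, s), cr, s * (0.67 + 0.01 * rng.normal()), rr, rc)
        return (left | right).astype(np.uint8)
    # optic disc: one filled circle at a (mildly) jittered position —
    # disc location in fundus photographs is anatomically consistent
    cr = s * (0.5 + 0.03 * rng.normal())
    cc = s * (0.5 + 0.03 * rng.normal())
    radius = s * 0.11 * grow * (1 + 0.06 * rng.normal())
    return _ellipse((s, s), cr, cc, radius, radius).astype(np.uint8)


def _base_image(config: SyntheticConfig, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    s = config.image_size
    if config.roi_shape == "two_lungs":
        # torso: bright ellipse on dark background; lungs darker than soft tissue
        body = _ellipse((s, s), s * 0.52, s * 0.5, s * 0.46, s * 0.42)
        img = np.full((s, s), 0.12)
        img[body] = 0.55
        img[mask.astype(bool)] = 0.30
    else:
        # fundus: retina circle on black background; bright disc
        eye = _ellipse((s, s), s * 0.5, s * 0.5, s * 0.47, s * 0.47)
        img = np.full((s, s), 0.05)
        img[eye] = 0.42
        img[mask.astype(bool)] = 0.68
    img += config.noise_sd * rng.standard_normal((s, s))
    return img


def _disease_signal(
    config: SyntheticConfig, mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Additive center-surround contrast pattern at a random in-ROI pixel,
    clipped to the ROI so the signal cannot leak outside it.

    The pattern is a difference of Gaussians with (approximately) zero net
    intensity — a bright core inside a dark annulus — so disease manifests
    as local contrast, not as extra brightness.  A net-brightness signal
    would let any model read the label off the total visible intensity,
    which would confound every manipulation that changes the visible area
    (dilation sweeps, bounding boxes); clinically, lesions and cupping are
    contrast changes too.
    """
    s = config.image_size
    sigma = 0.04 * s
    # center the pattern well inside the ROI (like a lesion in the organ, not
    # on its rim), so the boundary ring carries no disease information
    interior = _gray_erosion(mask.astype(bool), footprint=disk(int(2 * sigma)))
    rows, cols = np.nonzero(interior if interior.any() else mask)
    i = rng.integers(rows.size)
    cr, cc = rows[i], cols[i]
    r = np.arange(s)[:, None]
    c = np.arange(s)[None, :]
    d2 = (r - cr) ** 2 + (c - cc) ** 2
    core = np.exp(-d2 / (2 * sigma**2))
    surround = np.exp(-d2 / (2 * (2 * sigma) ** 2))
    # the signal carrier follows the modality: opacities are bright smooth
    # blobs against the dark lung fields, while disc disease shows as local
    # structural irregularity — a zero-mean texture patch — so that neither
    # total brightness nor visible area is a proxy for the label
    if config.roi_shape == "two_lungs":
        blob = core - 0.25 * surround  # integrals cancel: zero net intensity
        texture = 0.25 * rng.standard_normal((s, s)) * (core > 0.4)
        return config.disease_amplitude * (blob + texture) * mask
    # compact patch, hard-truncated so it never reaches the disc boundary:
    # boundary-straddling features must stay disease-free, otherwise the
    # label could be read off partially visible rim content
    window = np.exp(-d2 / (2 * (0.6 * sigma) ** 2)) * (d2 <= (1.5 * sigma) ** 2)
    texture = rng.standard_normal((s, s)) * window
    return config.disease_amplitude * texture * mask


# ---------------------------------------------------------------------------
# shortcuts


def _token_footprint(s: int, r0: int, c0: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of a pacemaker-like token: a rounded rectangle with
    a short lead-like line below it. Top-left corner at (r0, c0)."""
    th, tw = max(4, s // 20), max(6, s // 14)
    rows, cols = [], []
    for dr in range(th):
        for dc in range(tw):
            corner = (dr in (0, th - 1)) and (dc in (0, tw - 1))
            if not corner:
                rows.append(r0 + dr)
                cols.append(c0 + dc)
    lead_len = max(4, s // 16)
    for dr in range(lead_len):  # diagonal lead
        rows.append(r0 + th + dr)
        cols.append(c0 + tw // 2 + dr // 2)
    return np.array(rows), np.array(cols)


def _glyph_band(s: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Text-like band: a row of short bright rectangles in a corner strip."""
    strip_h = max(4, s // 18)
    r0 = rng.choice([1, s - strip_h - 1])  # top or bottom border strip
    rows, cols = [], []
    c = 2
    while c < s // 2:
        w = int(rng.integers(2, max(3, s // 32) + 1))
        gap = int(rng.integers(1, 3))
        h = int(rng.integers(strip_h - 2, strip_h + 1))
        for dr in range(h):
            for dc in range(w):
                rows.append(r0 + dr)
                cols.append(c + dc)
        c += w + gap
    return np.array(rows), np.array(cols)


def _apply_shortcut(
    image: np.ndarray,
    mask: np.ndarray,
    spec: ShortcutSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one shortcut onto ``image`` in place; returns the pixels touched.

    Raises :class:`ShortcutPlacementError` if no placement avoids the ROI.
    """
    s = image.shape[0]
    touched = np.zeros_like(mask, dtype=bool)
    if spec.kind == "global_offset":
        outside = mask == 0
        image[outside] += spec.amplitude
        touched[outside] = True
        return touched
    if spec.kind == "border_text":
        for _ in range(50):
            rows, cols = _glyph_band(s, rng)
            if not mask[rows, cols].any():
                image[rows, cols] += spec.amplitude
                touched[rows, cols] = True
                return touched
        raise ShortcutPlacementError(
            f"border_text shortcut {spec} cannot be placed without touching the ROI"
        )
    # token
    th = max(4, s // 20) + max(4, s // 16)
    tw = max(6, s // 14)
    for _ in range(200):
        if spec.placement == "image_border":
            r0 = int(rng.choice([2, s - th - 2]))
            c0 = int(rng.integers(2, s - tw - 2))
        else:
            r0 = int(rng.integers(2, s - th - 2))
            c0 = int(rng.integers(2, s - tw - 2))
        rows, cols = _token_footprint(s, r0, c0)
        if not mask[rows, cols].any():
            image[rows, cols] += spec.amplitude
            touched[rows, cols] = True
            return touched
    raise ShortcutPlacementError(
        f"token shortcut {spec} cannot be placed outside the ROI (ROI covers placement zone)"
    )


# ---------------------------------------------------------------------------
# metadata


def generate_metadata(
    labels: np.ndarray, metadata_auc: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Tabular metadata (sex, birth_year, projection) with a target label
    discriminability.

    A continuous latent with binormal separability ``metadata_auc`` (mean
    shift sqrt(2) * Phi^-1(AUC) between classes) is quantile-binned into
    birth years; sex and projection are label-independent.  At
    ``metadata_auc=0.5`` every column is independent of the label; at 1.0 the
    classes are linearly separable by birth year.
    """
    if not 0.5 <= metadata_auc <= 1.0:
        raise ValueError("metadata_auc must lie in [0.5, 1]")
    labels = np.asarray(labels).astype(int).ravel()
    n = labels.size
    if metadata_auc >= 1.0:
        # disjoint year ranges: a threshold separates the classes exactly
        birth_year = 1940 + 35 * labels + rng.integers(0, 30, size=n)
    else:
        mu = np.sqrt(2.0) * norm.ppf(metadata_auc)
        latent = mu * labels + rng.standard_normal(n)
        ranks = np.argsort(np.argsort(latent))
        birth_year = 1930 + (75 * (ranks + 0.5) / n).astype(int)
    sex = rng.integers(0, 2, size=n)
    projection = np.where(rng.random(n) < 0.5, "PA", "AP")
    return pd.DataFrame(
        {"sex": sex, "birth_year": birth_year.astype(int), "projection": projection}
    )


# ---------------------------------------------------------------------------
# dataset


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Label-stratified fold ids 0..k-1 (round-robin within shuffled strata)."""
    folds = np.empty(labels.size, dtype=int)
    for value in np.unique(labels):
        idx = np.flatnonzero(labels == value)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def generate_dataset(config: SyntheticConfig) -> tuple[list[ImageRecord], pd.DataFrame]:
    """Generate the dataset described by ``config``.

    Returns the records and a manifest table (one row per record; image and
    mask path columns are filled by :func:`write_dataset`).  The positive
    count is exactly ``round(n_images * prevalence)`` by stratified
    assignment, not sampling.
    """
    n, s = config.n_images, config.image_size
    ss = np.random.SeedSequence(config.seed)
    record_seeds = ss.spawn(n)
    global_rng = np.random.default_rng(ss.spawn(1)[0])

    n_pos = round(n * config.prevalence)
    labels = np.zeros(n, dtype=int)
    labels[global_rng.permutation(n)[:n_pos]] = 1

    metadata = generate_metadata(labels, config.metadata_auc, global_rng)
    folds = _stratified_folds(labels, config.n_folds, global_rng)

    records: list[ImageRecord] = []
    for i in range(n):
        rng = np.random.default_rng(record_seeds[i])
        y = int(labels[i])
        mask = _roi_mask(config, rng, positive=bool(y))
        image = _base_image(config, mask, rng)
        if y and config.disease_amplitude > 0:
            image += _disease_signal(config, mask, rng)
        shortcut_mask = np.zeros((s, s), dtype=bool)
        present: dict[str, bool] = {}
        for spec in config.shortcut_specs:
            has = y if rng.random() < spec.correlation else 1 - y
            present[spec.kind] = bool(has)
            if has:
                shortcut_mask |= _apply_shortcut(image, mask, spec, rng)
        image = np.clip(image, 0.0, 1.0)
        if rng.random() < config.low_quality_fraction:
            quality = float(rng.uniform(0.40, 0.695))
        else:
            quality = float(rng.uniform(0.72, 0.99))
        records.append(
            ImageRecord(
                index=i,
                image=image,
                mask=mask,
                labels=np.array([y]),
                metadata=dict(metadata.iloc[i]),
                fold=int(folds[i]),
                mask_quality=quality,
                shortcuts_present=present,
                shortcut_mask=shortcut_mask,
            )
        )

    manifest = metadata.copy()
    manifest.insert(0, "mask_path", "")
    manifest.insert(0, "image_path", "")
    manifest[CLASS_NAME] = labels
    manifest["fold"] = folds
    manifest["mask_quality"] = [r.mask_quality for r in records]
    for spec in config.shortcut_specs:
        manifest[f"shortcut_{spec.kind}_present"] = [
            int(r.shortcuts_present.get(spec.kind, 0)) for r in records
        ]
    logger.info(
        "generated %d images (%d positive) at %dx%d, roi=%s, %d shortcut spec(s)",
        n, n_pos, s, s, config.roi_shape, len(config.shortcut_specs),
    )
    return records, manifest


def write_dataset(
    records: Sequence[ImageRecord], manifest: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Write 8-bit grayscale PNG images, 0/255 PNG masks and the manifest CSV.

    Returns the manifest path.  Record paths are updated in place.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    for rec in records:
        img_path = out_dir / "images" / f"{rec.index:05d}.png"
        mask_path = out_dir / "masks" / f"{rec.index:05d}.png"
        Image.fromarray((np.clip(rec.image, 0, 1) * 255).round().astype(np.uint8)).save(img_path)
        Image.fromarray((rec.mask * 255).astype(np.uint8)).save(mask_path)
        rec.image_path = str(img_path)
        rec.mask_path = str(mask_path)
        manifest.loc[rec.index, "image_path"] = str(img_path)
        manifest.loc[rec.index, "mask_path"] = str(mask_path)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def load_dataset(manifest_path: str | Path) -> tuple[list[ImageRecord], pd.DataFrame]:
    """Load a dataset previously written by :func:`write_dataset` (or any
    manifest CSV in the same layout)."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    label_cols = [
        c
        for c in manifest.columns
        if c
        not in ("image_path", "mask_path", "sex", "birth_year", "projection", "fold", "mask_quality")
        and not c.startswith("shortcut_")
    ]
    records = []
    for i, row in manifest.iterrows():
        image = np.asarray(Image.open(row["image_path"]), dtype=np.float64) / 255.0
        mask = (np.asarray(Image.open(row["mask_path"])) > 127).astype(np.uint8)
        records.append(
            ImageRecord(
                index=i,
                image=image,
                mask=mask,
                labels=np.array([int(row[c]) for c in label_cols]),
                metadata={k: row[k] for k in ("sex", "birth_year", "projection") if k in row},
                fold=int(row["fold"]),
                mask_quality=float(row["mask_quality"]),
                shortcuts_present={
                    c[len("shortcut_") : -len("_present")]: bool(row[c])
                    for c in manifest.columns
                    if c.startswith("shortcut_") and c.endswith("_present")
                },
                image_path=row["image_path"],
                mask_path=row["mask_path"],
            )
        )
    return records, manifest


def null_config(**overrides) -> SyntheticConfig:
    """A dataset with no disease signal and no shortcut: every classifier
    should score at chance on it."""
    base = dict(disease_amplitude=0.0, shortcut_specs=(), roi_size_label_slope=0.0)
    base.update(overrides)
    return SyntheticConfig(**base)
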