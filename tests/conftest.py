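"""Shared fixtures.

The expensive fixtures (trained fold models on planted-shortcut datasets)
are session-scoped and shared between the unit tests and the acceptance
tests, so each dataset/model pair is built exactly once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from roiaudit.audit import train_strategy_models
from roiaudit.classifier import TrainingConfig
from roiaudit.synthetic_data import ShortcutSpec, SyntheticConfig, generate_dataset

SEED = 0


def stack(records):
    images = np.stack([r.image for r in records])
    masks = np.stack([r.mask for r in records])
    labels = np.stack([r.labels for r in records])
    folds = np.array([r.fold for r in records])
    return images, masks, labels, folds


@pytest.fixture(scope="session")
def small_dataset():
    """Quick 60-image dataset for structural tests."""
    cfg = SyntheticConfig(n_images=60, image_size=64, seed=SEED)
    records, manifest = generate_dataset(cfg)
    return cfg, records, manifest


def _train_test(config, strategy, n_train=450):
    records, _ = generate_dataset(config)
    images, masks, labels, folds = stack(records)
    tr = np.arange(n_train)
    te = np.arange(n_train, config.n_images)
    models = train_strategy_models(
        images[tr], masks[tr], labels[tr], folds[tr],
        strategy, TrainingConfig.desk_scale(seed=SEED), ["disease"],
    )
    return dict(
        config=config, images=images, masks=masks, labels=labels,
        folds=folds, train=tr, test=te, models={(strategy, h.fold): h for h in models},
        strategy=strategy,
    )


@pytest.fixture(scope="session")
def token_no_roi_run():
    """Planted token shortcut (rho=0.9); models trained without the ROI."""
    cfg = SyntheticConfig(
        n_images=600, image_size=128, seed=SEED,
        shortcut_specs=(ShortcutSpec(kind="token", correlation=0.9),),
    )
    return _train_test(cfg, "NO_ROI")


@pytest.fixture(scope="session")
def control_no_roi_run():
    """Matched control: same token spec but label-independent (rho=0.5)."""
    cfg = SyntheticConfig(
        n_images=600, image_size=128, seed=SEED,
        shortcut_specs=(ShortcutSpec(kind="token", correlation=0.5),),
    )
    return _train_test(cfg, "NO_ROI")


@pytest.fixture(scope="session")
def disc_slope_run():
    """Disc ROI whose size correlates with the label (size confound)."""
    cfg = SyntheticConfig(
        n_images=600, image_size=128, seed=SEED, roi_shape="disc",
        roi_size_label_slope=0.15,
    )
    return _train_test(cfg, "ONLY_ROI")


@pytest.fixture(scope="session")
def disc_flat_run():
    """Matched control disc dataset with no size/label link."""
    cfg = SyntheticConfig(
        n_images=600, image_size=128, seed=SEED, roi_shape="disc",
        roi_size_label_slope=0.0,
    )
    return _train_test(cfg, "ONLY_ROI")


@pytest.fixture(scope="session")
def border_text_full_run():
    """Border-text shortcut (rho=0.95); model trained on FULL images."""
    cfg = SyntheticConfig(
        n_images=600, image_size=128, seed=SEED,
        shortcut_specs=(ShortcutSpec(kind="border_text", correlation=0.95, amplitude=0.5),),
    )
    return _train_test(cfg, "FULL")


@pytest.fixture(scope="session")
def clean_full_run():
    """Shortcut-free dataset; model trained on FULL images."""
    cfg = SyntheticConfig(n_images=600, image_size=128, seed=SEED)
    return _train_test(cfg, "FULL")
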