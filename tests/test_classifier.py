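"""Folds, the pooled-MLP backbone, embeddings and the tabular baseline."""

import numpy as np
import pandas as pd
import pytest

from roiaudit.classifier import (
    ModelHandle,
    PooledMLPClassifier,
    TrainingConfig,
    extract_embeddings,
    load_model,
    make_folds,
    predict_proba,
    save_model,
    train_image_classifier,
    train_tabular_baseline,
)
from roiaudit.evaluation import auc
from roiaudit.masking import apply_strategy
from roiaudit.synthetic_data import SyntheticConfig, generate_dataset, null_config
from conftest import stack


class TestTrainingConfig:
    def test_full_scale_defaults(self):
        cfg = TrainingConfig()
        assert cfg.batch_size == 32
        assert cfg.max_epochs == 250
        assert cfg.early_stop_patience == 10
        assert cfg.early_stop_delta == 1e-3
        assert cfg.rotation_deg == 45.0
        assert cfg.hflip_prob == 0.5
        assert cfg.brightness_range == (0.7, 1.1)

    def test_invalid_patience_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(early_stop_patience=0)

    def test_inverted_brightness_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(brightness_range=(1.2, 0.8))


class TestMakeFolds:
    def test_equal_fold_sizes(self):
        folds = make_folds(np.array([0, 1] * 50), k=5, seed=0)
        assert all((folds == f).sum() == 20 for f in range(5))

    def test_stratification_exact_per_fold(self):
        y = np.zeros(1000, dtype=int)
        y[:300] = 1
        folds = make_folds(y, k=5, seed=1)
        for f in range(5):
            assert y[folds == f].sum() == 60

    def test_deterministic_given_seed(self):
        y = np.random.default_rng(2).integers(0, 2, 200)
        assert np.array_equal(make_folds(y, seed=3), make_folds(y, seed=3))

    def test_tiny_stratum_degrades_with_warning(self):
        y = np.array([0] * 50 + [1] * 2)
        with pytest.warns(UserWarning, match="unstratified"):
            folds = make_folds(y, k=5, seed=4)
        assert folds.size == 52


@pytest.fixture(scope="module")
def easy_dataset():
    """Strong in-ROI disease signal: any competent model separates it."""
    cfg = SyntheticConfig(n_images=600, image_size=128, seed=0, disease_amplitude=0.6)
    records, _ = generate_dataset(cfg)
    return stack(records)


class TestPooledMLP:
    def test_learns_strong_disease_signal(self, easy_dataset):
        images, masks, labels, folds = easy_dataset
        tr = np.arange(450)
        te = np.arange(450, 600)
        handle = train_image_classifier(
            images[tr], labels[tr], folds[tr], fold=0,
            config=TrainingConfig.desk_scale(), class_names=["disease"],
        )
        scores = predict_proba(handle, images[te])[:, 0]
        assert auc(scores, labels[te, 0]) > 0.95

    def test_null_dataset_scores_at_chance(self):
        cfg = null_config(n_images=600, image_size=64, seed=1)
        records, _ = generate_dataset(cfg)
        images, masks, labels, folds = stack(records)
        handle = train_image_classifier(
            images[:400], labels[:400], folds[:400], fold=0,
            config=TrainingConfig.desk_scale(), class_names=["disease"],
        )
        # large freshly generated evaluation set keeps the chance band tight
        eval_cfg = null_config(n_images=1000, image_size=64, seed=2)
        eval_records, _ = generate_dataset(eval_cfg)
        ev_images, _, ev_labels, _ = stack(eval_records)
        scores = predict_proba(handle, ev_images)[:, 0]
        assert 0.45 <= auc(scores, ev_labels[:, 0]) <= 0.55

    def test_constant_images_stop_early(self):
        rng = np.random.default_rng(3)
        X = np.zeros((120, 32, 32))
        y = rng.integers(0, 2, 120)
        est = PooledMLPClassifier(max_epochs=100, random_state=0)
        est.fit(X, y)
        assert est.n_epochs_ < 100

    def test_early_stopping_best_epoch_dominates_history(self, easy_dataset):
        images, _, labels, folds = easy_dataset
        handle = train_image_classifier(
            images[:300], labels[:300], folds[:300], fold=0,
            config=TrainingConfig.desk_scale(), class_names=["disease"],
        )
        est = handle.model
        best = est.best_val_loss_
        assert all(best <= later + est.early_stop_delta
                   for later in est.val_loss_history_[est.best_epoch_ :])

    def test_single_class_labels_rejected(self):
        X = np.random.default_rng(4).random((30, 32, 32))
        with pytest.raises(ValueError, match="single class"):
            PooledMLPClassifier().fit(X, np.ones(30))

    def test_predict_proba_shape_range_and_duplicates(self, easy_dataset):
        images, _, labels, folds = easy_dataset
        handle = train_image_classifier(
            images[:200], labels[:200], folds[:200], fold=0,
            config=TrainingConfig.desk_scale(), class_names=["disease"],
        )
        batch = np.concatenate([images[200:205], images[200:205]])
        probs = predict_proba(handle, batch)
        assert probs.shape == (10, 1)
        assert np.all((probs >= 0) & (probs <= 1))
        assert np.allclose(probs[:5], probs[5:])

    def test_wrong_spatial_size_rejected(self, easy_dataset):
        images, _, labels, folds = easy_dataset
        handle = train_image_classifier(
            images[:200], labels[:200], folds[:200], fold=0,
            config=TrainingConfig.desk_scale(), class_names=["disease"],
        )
        with pytest.raises(ValueError, match="fitted size"):
            predict_proba(handle, np.zeros((2, 64, 64)))

    def test_embeddings_consistent_with_head(self, easy_dataset):
        images, _, labels, folds = easy_dataset
        handle = train_image_classifier(
            images[:200], labels[:200], folds[:200], fold=0,
            config=TrainingConfig.desk_scale(), class_names=["disease"],
        )
        emb = extract_embeddings(handle, images[200:220])
        assert emb.shape == (20, handle.embedding_dim)
        # the stored head applied to the embedding reproduces the classifier
        assert np.allclose(handle.model.head(emb), predict_proba(handle, images[200:220]))
        # identical images embed identically
        assert np.allclose(
            extract_embeddings(handle, images[200:201]),
            extract_embeddings(handle, images[200:201]),
        )

    def test_reproducible_given_seed(self, easy_dataset):
        images, _, labels, folds = easy_dataset
        handles = [
            train_image_classifier(
                images[:300], labels[:300], folds[:300], fold=0,
                config=TrainingConfig.desk_scale(), class_names=["disease"],
            )
            for _ in range(2)
        ]
        p = [predict_proba(h, images[300:320]) for h in handles]
        assert np.allclose(p[0], p[1])

    def test_only_roi_model_invariant_outside_roi(self, easy_dataset):
        """Pixels outside the ROI cannot influence an ONLY_ROI model because
        masking zeroes them before the model sees them."""
        images, masks, labels, folds = easy_dataset
        masked = np.stack(
            [apply_strategy(i, m, "ONLY_ROI") for i, m in zip(images[:200], masks[:200])]
        )
        handle = train_image_classifier(
            masked, labels[:200], folds[:200], fold=0,
            config=TrainingConfig.desk_scale(), class_names=["disease"],
        )
        test_img, test_mask = images[201], masks[201]
        noise = np.random.default_rng(5).random(test_img.shape)
        tampered = test_img + noise * (1 - test_mask)  # only outside the ROI
        a = predict_proba(handle, apply_strategy(test_img, test_mask, "ONLY_ROI")[None])
        b = predict_proba(handle, apply_strategy(tampered, test_mask, "ONLY_ROI")[None])
        assert np.allclose(a, b)

    def test_save_load_roundtrip(self, easy_dataset, tmp_path):
        images, _, labels, folds = easy_dataset
        handle = train_image_classifier(
            images[:200], labels[:200], folds[:200], fold=0,
            config=TrainingConfig.desk_scale(), class_names=["disease"], strategy="FULL",
        )
        path = save_model(handle, tmp_path, TrainingConfig.desk_scale())
        loaded = load_model(path)
        assert np.allclose(
            predict_proba(loaded, images[200:210]), predict_proba(handle, images[200:210])
        )
        assert loaded.class_names == ["disease"]

    def test_sklearn_params_protocol(self):
        est = PooledMLPClassifier(hidden_dim=32)
        params = est.get_params()
        assert params["hidden_dim"] == 32
        est.set_params(hidden_dim=16)
        assert est.hidden_dim == 16


class TestTabularBaseline:
    def test_null_metadata_scores_at_chance(self):
        from roiaudit.synthetic_data import generate_metadata

        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 2000)
        meta = generate_metadata(y, 0.5, rng)
        folds = np.arange(2000) % 5
        _, cv_auc = train_tabular_baseline(meta, y, folds)
        assert 0.45 <= cv_auc[0] <= 0.55

    def test_separable_feature_gives_near_perfect_auc(self):
        n = 400
        y = np.array([0, 1] * (n // 2))
        meta = pd.DataFrame(
            {"sex": y, "birth_year": 1970 + np.zeros(n, dtype=int), "projection": ["PA"] * n}
        )
        _, cv_auc = train_tabular_baseline(meta, y, np.arange(n) % 5)
        assert cv_auc[0] > 0.99

    def test_rows_with_missing_features_excluded(self):
        n = 100
        y = np.array([0, 1] * (n // 2))
        meta = pd.DataFrame(
            {
                "sex": [np.nan] + [0] * (n - 1),
                "birth_year": 1970 + np.arange(n) % 30,
                "projection": ["PA"] * n,
            }
        )
        models, _ = train_tabular_baseline(meta, y, np.arange(n) % 5)
        assert len(models) == 5  # fit succeeded on the 99 complete rows

    def test_all_rows_missing_rejected(self):
        meta = pd.DataFrame(
            {"sex": [np.nan, np.nan], "birth_year": [np.nan, np.nan],
             "projection": [None, None]}
        )
        with pytest.raises(ValueError, match="dropped"):
            train_tabular_baseline(meta, np.array([0, 1]), np.array([0, 1]))
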