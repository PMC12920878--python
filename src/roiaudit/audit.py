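"""End-to-end shortcut-learning audit.

``run_audit`` composes the whole pipeline: generate (or load) a dataset,
filter records by mask quality, split train/test, train one model per
(masking strategy, fold), compute the cross-masking AUC matrix, fold-wise
DeLong comparisons against the FULL model, dilation sweeps, embedding
similarity, and occlusion-Shapley attribution — and writes a consolidated
report with a shortcut-risk verdict.

The verdict rule: shortcut risk is flagged when, for any class, the
``NO_ROI`` or ``NO_ROI_BB`` diagonal cell (model trained and evaluated
without the ROI) is significantly above a label-permuted null in at least
three of the five folds.  A model that cannot beat chance without the ROI
has no measurable shortcut; one that can is using something outside the
clinically relevant region.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import attribution as attr_mod
from . import classifier as clf_mod
from . import embeddings as emb_mod
from . import evaluation as eval_mod
from . import masking as mask_mod
from . import synthetic_data as synth_mod
from .classifier import ModelHandle, TrainingConfig
from .evaluation import AUCMatrix, STRATEGY_ORDER
from .masking import MaskingStrategy, apply_strategy

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_audit", "train_strategy_models", "shortcut_risk_verdict"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Fully serializable description of one audit run."""

    synthetic: synth_mod.SyntheticConfig | None = None
    manifest_path: str | None = None
    strategies: tuple[str, ...] = tuple(STRATEGY_ORDER)
    dilation_factors: tuple[int, ...] = (0, 2, 5, 12, 25)
    class_conditional_sweep: bool = True
    training: TrainingConfig = field(default_factory=TrainingConfig.desk_scale)
    test_fraction: float = 0.25
    quality_threshold: float = 0.7
    alpha: float = 0.05
    min_folds: int = 3
    n_folds: int = 5
    n_permutations: int = 200
    attribution_n_evals: int = 1000
    attribution_n_segments: int = 25
    attribution_n_images: int = 4
    seed: int = 0
    out_dir: str = "audit_run"

    def __post_init__(self) -> None:
        if self.synthetic is None and self.manifest_path is None:
            self.synthetic = synth_mod.SyntheticConfig()
        self.strategies = tuple(MaskingStrategy(s).value for s in self.strategies)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            sd = dict(d["synthetic"])
            sd["shortcut_specs"] = tuple(
                synth_mod.ShortcutSpec(**s) for s in sd.get("shortcut_specs", ())
            )
            d["synthetic"] = synth_mod.SyntheticConfig(**sd)
        if d.get("training") is not None:
            td = dict(d["training"])
            td["brightness_range"] = tuple(td["brightness_range"])
            d["training"] = TrainingConfig(**td)
        for key in ("strategies", "dilation_factors"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _stack_records(records: Sequence[synth_mod.ImageRecord]):
    images = np.stack([r.image for r in records])
    masks = np.stack([r.mask for r in records])
    labels = np.stack([r.labels for r in records])
    folds = np.array([r.fold for r in records])
    metadata = pd.DataFrame([r.metadata for r in records])
    return images, masks, labels, folds, metadata


def train_strategy_models(
    images: np.ndarray,
    masks: np.ndarray,
    labels: np.ndarray,
    folds: np.ndarray,
    strategy: MaskingStrategy | str,
    config: TrainingConfig,
    class_names: Sequence[str],
    n_folds: int = 5,
) -> list[ModelHandle]:
    """Mask the training images with ``strategy`` and train one model per
    fold (the fold is held out for early stopping)."""
    strategy = MaskingStrategy(strategy)
    masked = np.stack([apply_strategy(img, msk, strategy) for img, msk in zip(images, masks)])
    return [
        clf_mod.train_image_classifier(
            masked, labels, folds, fold, config,
            strategy=strategy.value, class_names=class_names,
        )
        for fold in range(n_folds)
    ]


def shortcut_risk_verdict(
    models: dict[tuple[str, int], ModelHandle],
    images: np.ndarray,
    masks: np.ndarray,
    labels: np.ndarray,
    class_names: Sequence[str],
    strategies: Sequence[str] = ("NO_ROI", "NO_ROI_BB"),
    n_folds: int = 5,
    alpha: float = 0.05,
    min_folds: int = 3,
    n_permutations: int = 200,
    seed: int = 0,
) -> dict:
    """Flag shortcut risk from the without-ROI diagonal cells.

    For each listed strategy present in ``models`` and each class, each fold
    model's scores on the strategy-masked test set are tested against a
    label-permuted null; the fold rule (p < alpha in >= min_folds folds)
    decides significance.  Returns the verdict dict with per-cell detail.
    """
    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = labels[:, None]
    rng = np.random.default_rng(seed)
    flagged: list[dict] = []
    detail: list[dict] = []
    for strat in strategies:
        if (strat, 0) not in models:
            continue
        masked = np.stack([apply_strategy(img, msk, strat) for img, msk in zip(images, masks)])
        for c, cname in enumerate(class_names):
            p_values = []
            fold_aucs = []
            for f in range(n_folds):
                scores = models[(strat, f)].predict_proba(masked)[:, c]
                p = eval_mod.auc_permutation_pvalue(
                    scores, labels[:, c], n_permutations=n_permutations, rng=rng
                )
                p_values.append(p)
                fold_aucs.append(eval_mod.auc(scores, labels[:, c]))
            significant = eval_mod.aggregate_significance(p_values, alpha, min_folds)
            cell = {
                "strategy": strat,
                "class": cname,
                "fold_aucs": fold_aucs,
                "mean_auc": float(np.mean(fold_aucs)),
                "p_values": p_values,
                "significant": significant,
            }
            detail.append(cell)
            if significant:
                flagged.append({"strategy": strat, "class": cname, "mean_auc": cell["mean_auc"]})
    risk = len(flagged) > 0
    return {
        "risk_detected": risk,
        "verdict": "shortcut risk detected" if risk else "no shortcut risk detected",
        "flagged_cells": flagged,
        "cells": detail,
    }


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage naming contract
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_audit(config: RunConfig) -> dict:
    """Execute the full audit described by ``config``.

    Writes CSV/PNG artifacts and ``report.json`` + ``report.md`` under
    ``config.out_dir`` and returns the report dict.  Any stage failure
    raises :class:`StageError` naming the stage; artifacts written before
    the failure are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": {},
        "notes": [emb_mod.EMBEDDING_CAVEAT,
                  "No multiple-testing correction is applied to DeLong p-values."],
    }
    rng = np.random.default_rng(config.seed)

    # -- data ---------------------------------------------------------------
    @_stage("generate")
    def _generate():
        if config.manifest_path is not None:
            return synth_mod.load_dataset(config.manifest_path)
        return synth_mod.generate_dataset(config.synthetic)

    records, manifest = _generate()
    report["counts"]["generated"] = len(records)
    class_names = [synth_mod.CLASS_NAME] if records[0].labels.size == 1 else [
        f"class_{c}" for c in range(records[0].labels.size)
    ]

    @_stage("filter")
    def _filter():
        return mask_mod.filter_records(records, config.quality_threshold)

    records_kept = _filter()
    report["counts"]["after_quality_filter"] = len(records_kept)

    @_stage("split")
    def _split():
        images, masks, labels, _, metadata = _stack_records(records_kept)
        y = labels[:, 0]
        idx = np.arange(len(records_kept))
        test_idx = []
        for value in np.unique(y):
            sub = rng.permutation(idx[y == value])
            test_idx.append(sub[: max(1, int(round(config.test_fraction * sub.size)))])
        test_idx = np.sort(np.concatenate(test_idx))
        train_sel = np.setdiff1d(idx, test_idx)
        folds = clf_mod.make_folds(labels[train_sel], k=config.n_folds, seed=config.seed)
        return images, masks, labels, metadata, train_sel, test_idx, folds

    images, masks, labels, metadata, train_sel, test_idx, folds = _split()
    report["counts"]["train"] = int(train_sel.size)
    report["counts"]["test"] = int(test_idx.size)

    # -- training -----------------------------------------------------------
    @_stage("train")
    def _train():
        models: dict[tuple[str, int], ModelHandle] = {}
        for strat in config.strategies:
            handles = train_strategy_models(
                images[train_sel], masks[train_sel], labels[train_sel], folds,
                strat, config.training, class_names, config.n_folds,
            )
            for h in handles:
                models[(strat, h.fold)] = h
                clf_mod.save_model(h, out / "models", config.training)
        return models

    models = _train()

    @_stage("tabular_baseline")
    def _tabular():
        if not {"sex", "birth_year", "projection"} <= set(metadata.columns):
            return None
        _, cv_auc = clf_mod.train_tabular_baseline(
            metadata.iloc[train_sel], labels[train_sel], folds
        )
        return {cn: float(a) for cn, a in zip(class_names, cv_auc)}

    tabular_auc = _tabular()
    report["tabular_baseline_auc"] = tabular_auc

    # -- cross-masking matrix ------------------------------------------------
    @_stage("cross_matrix")
    def _matrix():
        matrix = eval_mod.cross_masking_evaluation(
            models, images[test_idx], masks[test_idx], labels[test_idx],
            class_names=class_names, strategies=config.strategies, n_folds=config.n_folds,
        )
        matrix.to_dataframe().to_csv(out / "auc_matrix.csv", index=False)
        try:
            ax = matrix.plot_heatmap(class_names[0])
            ax.figure.savefig(out / "auc_matrix.png", dpi=120, bbox_inches="tight")
            import matplotlib.pyplot as plt

            plt.close(ax.figure)
        except Exception:  # plotting is best-effort
            logger.warning("heatmap rendering failed", exc_info=True)
        return matrix

    matrix = _matrix()
    report["auc_matrix"] = {
        f"{ts}|{es}|{cn}": [float(matrix.mean[i, j, c]), float(matrix.sd[i, j, c])]
        for i, ts in enumerate(matrix.train_strategies)
        for j, es in enumerate(matrix.eval_strategies)
        for c, cn in enumerate(matrix.class_names)
    }

    # -- DeLong vs FULL ------------------------------------------------------
    @_stage("delong")
    def _delong():
        if "FULL" not in config.strategies:
            return {}
        full_imgs = images[test_idx]
        results = {}
        rows = []
        for strat in config.strategies:
            if strat == "FULL":
                continue
            masked = np.stack(
                [apply_strategy(img, msk, strat)
                 for img, msk in zip(images[test_idx], masks[test_idx])]
            )
            for c, cname in enumerate(class_names):
                aucs_a, aucs_b, ps = [], [], []
                for f in range(config.n_folds):
                    sa = models[("FULL", f)].predict_proba(full_imgs)[:, c]
                    sb = models[(strat, f)].predict_proba(masked)[:, c]
                    a_a, a_b, p = eval_mod.delong_test(sa, sb, labels[test_idx][:, c])
                    aucs_a.append(a_a)
                    aucs_b.append(a_b)
                    ps.append(p)
                cmp_ = eval_mod.DelongComparison(aucs_a, aucs_b, ps, config.alpha, config.min_folds)
                results[f"FULL_vs_{strat}|{cname}"] = cmp_.significant
                df = cmp_.to_dataframe()
                df.insert(0, "comparison", f"FULL_vs_{strat}")
                df.insert(1, "class", cname)
                rows.append(df)
        if rows:
            pd.concat(rows).to_csv(out / "delong.csv", index=False)
        return results

    report["delong_full_vs_masked_significant"] = _delong()

    # -- dilation sweeps -----------------------------------------------------
    @_stage("sweeps")
    def _sweeps():
        curves = []
        sweep_rows = []
        bases = [b for b in ("ONLY_ROI", "NO_ROI") if b in config.strategies]
        for base in bases:
            if "FULL" in config.strategies:  # where does the signal live?
                full_models = [models[("FULL", f)] for f in range(config.n_folds)]
                curve = eval_mod.dilation_sweep(
                    full_models, images[test_idx], masks[test_idx], labels[test_idx],
                    base, config.dilation_factors, "all", class_names,
                )
                curve_df = curve.to_dataframe()
                curve_df.insert(0, "trained_on", "FULL")
                sweep_rows.append(curve_df)
                curves.append(("FULL", curve))
            if config.class_conditional_sweep:  # ROI-size confound probing
                base_models = [models[(base, f)] for f in range(config.n_folds)]
                for subset in ("positives_only", "negatives_only"):
                    curve = eval_mod.dilation_sweep(
                        base_models, images[test_idx], masks[test_idx], labels[test_idx],
                        base, config.dilation_factors, subset, class_names,
                    )
                    curve_df = curve.to_dataframe()
                    curve_df.insert(0, "trained_on", base)
                    sweep_rows.append(curve_df)
                    curves.append((base, curve))
        if sweep_rows:
            pd.concat(sweep_rows).to_csv(out / "dilation_curves.csv", index=False)
        return curves

    curves = _sweeps()
    report["dilation_curves"] = [
        {
            "trained_on": trained_on,
            "base": curve.base,
            "subset": curve.subset,
            "factors": list(curve.factors),
            "mean_auc": [float(v) for v in curve.mean[:, 0]],
        }
        for trained_on, curve in curves
    ]

    # -- embeddings ----------------------------------------------------------
    @_stage("embeddings")
    def _embeddings():
        if "FULL" not in config.strategies:
            return None
        full_model = models[("FULL", 0)]
        table = emb_mod.similarity_table(
            full_model, images[test_idx], masks[test_idx], labels[test_idx],
            class_names=class_names,
            strategies=[s for s in config.strategies if s != "FULL"],
        )
        table.to_csv(out / "similarity.csv", index=False)
        # t-SNE over all strategies' embeddings of the test images
        embs, tags = [], []
        for strat in config.strategies:
            masked = np.stack(
                [apply_strategy(img, msk, strat)
                 for img, msk in zip(images[test_idx], masks[test_idx])]
            )
            embs.append(full_model.embed(masked))
            tags += [strat] * len(test_idx)
        embs = np.concatenate(embs)
        try:
            coords, kept = emb_mod.project_2d(
                embs, tags, seed=config.seed,
                perplexity=min(30.0, max(2.0, len(tags) / 10)),
            )
            kept_tags = np.asarray(tags)[kept]
            pd.DataFrame(
                {"x": coords[:, 0], "y": coords[:, 1], "strategy": kept_tags}
            ).to_csv(out / "tsne.csv", index=False)
            emb_mod.plot_projection(coords, kept_tags, out / "tsne.png")
        except ValueError as exc:
            logger.warning("projection skipped: %s", exc)
        return table

    sim_table = _embeddings()
    if sim_table is not None:
        report["similarity_all"] = {
            row["strategy"]: float(row["mean_cosine"])
            for _, row in sim_table[sim_table["class"] == "All"].iterrows()
        }

    # -- attribution ---------------------------------------------------------
    @_stage("attribution")
    def _attribution():
        if "FULL" not in config.strategies or config.attribution_n_images == 0:
            return None
        full_model = models[("FULL", 0)]
        pos_idx = test_idx[labels[test_idx][:, 0] == 1][: config.attribution_n_images]
        shares = []
        rows = []
        for k, i in enumerate(pos_idx):
            segmap = attr_mod.make_superpixels(images[i], config.attribution_n_segments)
            result = attr_mod.shapley_occlusion(
                full_model, images[i], segmap,
                n_evals=config.attribution_n_evals, seed=config.seed + k,
            )
            share = attr_mod.roi_attribution_share(result, segmap, masks[i])
            shares.append(share)
            for seg in range(result.n_segments):
                rows.append(
                    {"image_index": int(i), "segment": seg,
                     "shapley": float(result.values[seg, 0]), "roi_share": share}
                )
            if k == 0:
                attr_mod.render_attribution(
                    images[i], segmap, result.values[:, 0], out / "attribution.png"
                )
        pd.DataFrame(rows).to_csv(out / "attribution.csv", index=False)
        return {"roi_attribution_share_mean": float(np.nanmean(shares)),
                "per_image": [float(s) for s in shares]}

    attr_summary = _attribution()
    report["attribution"] = attr_summary

    # -- verdict -------------------------------------------------------------
    @_stage("verdict")
    def _verdict():
        return shortcut_risk_verdict(
            models, images[test_idx], masks[test_idx], labels[test_idx], class_names,
            strategies=[s for s in ("NO_ROI", "NO_ROI_BB") if s in config.strategies],
            n_folds=config.n_folds, alpha=config.alpha, min_folds=config.min_folds,
            n_permutations=config.n_permutations, seed=config.seed,
        )

    report["verdict"] = _verdict()

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    _render_report_md(report, out / "report.md")
    logger.info("audit complete: %s", report["verdict"]["verdict"])
    return report


def _render_report_md(report: dict, path: Path) -> None:
    lines = [
        "# Shortcut-learning audit report",
        "",
        f"Config hash: `{report['config_hash']}`; seed {report['seed']}.",
        "",
        f"**Verdict: {report['verdict']['verdict']}**",
        "",
    ]
    for cell in report["verdict"]["flagged_cells"]:
        lines.append(
            f"- flagged: {cell['strategy']} diagonal, class {cell['class']}, "
            f"mean AUC {cell['mean_auc']:.3f}"
        )
    lines += ["", "## Record counts", ""]
    for k, v in report["counts"].items():
        lines.append(f"- {k}: {v}")
    if report.get("tabular_baseline_auc"):
        lines += ["", "## Tabular baseline (metadata only)", ""]
        for k, v in report["tabular_baseline_auc"].items():
            lines.append(f"- {k}: CV AUC {v:.3f}")
    lines += ["", "## Notes", ""]
    for note in report["notes"]:
        lines.append(f"- {note}")
    path.write_text("\n".join(lines) + "\n")
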