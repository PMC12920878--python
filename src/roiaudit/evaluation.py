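"""AUC-based audit statistics: rank AUC, DeLong tests, the fold-wise
significance rule, the cross-masking AUC matrix, and dilation sweeps.

The audit's central object is the cross-masking matrix: models trained on
each masking strategy are evaluated on every masked variant of the test set.
An unbiased model should collapse to chance once the ROI is removed; a model
that stays above chance on ``NO_ROI`` images is using a shortcut.  Dilation
sweeps grow the mask (optionally only for one class) to localize where the
signal lives and to expose ROI-size confounds.

AUC is the Mann-Whitney rank statistic (probability that a random positive
outranks a random negative, half credit for ties).  Two correlated AUCs on
the same samples are compared with the DeLong test using midrank placement
values; per the audit's fold rule, a difference counts as significant when
p < 0.05 in at least three of the five folds.  Multi-label problems are
handled one-vs-rest, independently per class; no multiple-testing
correction is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .masking import MaskingStrategy, apply_strategy, dilate_mask

logger = logging.getLogger(__name__)

__all__ = [
    "auc",
    "delong_components",
    "delong_variance",
    "delong_test",
    "aggregate_significance",
    "auc_permutation_pvalue",
    "DelongComparison",
    "AUCMatrix",
    "DilationCurve",
    "cross_masking_evaluation",
    "dilation_sweep",
]


def _check_binary_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).ravel()
    uniq = np.unique(labels)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    if uniq.size < 2:
        raise ValueError("both classes must be present to compute an AUC")
    return labels.astype(int)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney rank AUC with half credit for ties.

    Equals the mean over all (positive, negative) pairs of
    ``1[s_pos > s_neg] + 0.5 * 1[s_pos == s_neg]``, computed via midranks in
    O(n log n).
    """
    labels = _check_binary_labels(labels)
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels lengths differ")
    m = int(labels.sum())
    n = labels.size - m
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - m * (m + 1) / 2) / (m * n))


def delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus DeLong structural components (midrank placements).

    Returns ``(auc, v10, v01)`` where ``v10[i]`` is the placement of positive
    ``i`` among the negatives and ``v01[j]`` the placement of negative ``j``
    among the positives; ``mean(v10) == mean(v01) == auc``.
    """
    labels = _check_binary_labels(labels)
    scores = np.asarray(scores, dtype=np.float64).ravel()
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    tz = rankdata(np.concatenate([pos, neg]))
    tx = rankdata(pos)
    ty = rankdata(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    a = float(v10.mean())
    return a, v10, v01


def delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance estimate of a single AUC."""
    _, v10, v01 = delong_components(scores, labels)
    m, n = v10.size, v01.size
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """Two-sided DeLong test for two correlated AUCs on the same samples.

    Returns ``(auc_a, auc_b, p)``.  When the variance of the difference is
    zero (e.g. identical score vectors) the p-value is 1 for equal AUCs and
    0 (with a warning) otherwise.
    """
    scores_a = np.asarray(scores_a, dtype=np.float64).ravel()
    scores_b = np.asarray(scores_b, dtype=np.float64).ravel()
    if scores_a.shape != scores_b.shape:
        raise ValueError("score vectors must have the same length (same samples)")
    a_a, v10_a, v01_a = delong_components(scores_a, labels)
    a_b, v10_b, v01_b = delong_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var_diff <= 0:
        if np.isclose(a_a, a_b):
            return a_a, a_b, 1.0
        warnings.warn("zero DeLong variance with unequal AUCs; reporting p=0")
        return a_a, a_b, 0.0
    z = (a_a - a_b) / np.sqrt(var_diff)
    p = float(2 * norm.sf(abs(z)))
    return a_a, a_b, p


def aggregate_significance(
    p_values: Sequence[float], alpha: float = 0.05, min_folds: int = 3
) -> bool:
    """Fold rule: significant iff strictly more than ``alpha`` is undercut in
    at least ``min_folds`` folds (strict ``p < alpha``)."""
    p_values = list(p_values)
    if not p_values:
        raise ValueError("empty p-value list")
    return sum(p < alpha for p in p_values) >= min_folds


def auc_permutation_pvalue(
    scores: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 200,
    rng: np.random.Generator | int | None = None,
) -> float:
    """One-sided permutation p-value for AUC > chance under a label-permuted
    null, with the add-one correction ``(1 + #{AUC_perm >= AUC_obs}) / (B + 1)``."""
    rng = np.random.default_rng(rng)
    labels = _check_binary_labels(labels)
    observed = auc(scores, labels)
    count = 0
    for _ in range(n_permutations):
        if auc(scores, rng.permutation(labels)) >= observed:
            count += 1
    return (1 + count) / (n_permutations + 1)


@dataclass
class DelongComparison:
    """Fold-wise DeLong comparison of two models, aggregated by the fold rule."""

    auc_a: list[float]
    auc_b: list[float]
    p_values: list[float]
    alpha: float = 0.05
    min_folds: int = 3
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = aggregate_significance(self.p_values, self.alpha, self.min_folds)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": range(len(self.p_values)),
                "auc_a": self.auc_a,
                "auc_b": self.auc_b,
                "p": self.p_values,
                "significant": [p < self.alpha for p in self.p_values],
            }
        )


STRATEGY_ORDER = [s.value for s in MaskingStrategy]


@dataclass
class AUCMatrix:
    """train-strategy x eval-strategy x class grid of fold-mean AUCs.

    ``mean``/``sd`` have shape (n_train, n_eval, n_classes); undefined cells
    (single-class evaluation subset) are NaN, never imputed to 0.5.
    """

    train_strategies: list[str]
    eval_strategies: list[str]
    class_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    n_folds: int

    def cell(self, train: str, eval: str, class_name: str | None = None) -> tuple[float, float]:
        i = self.train_strategies.index(str(train))
        j = self.eval_strategies.index(str(eval))
        c = 0 if class_name is None else self.class_names.index(class_name)
        return float(self.mean[i, j, c]), float(self.sd[i, j, c])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, ts in enumerate(self.train_strategies):
            for j, es in enumerate(self.eval_strategies):
                for c, cn in enumerate(self.class_names):
                    rows.append(
                        {
                            "train_strategy": ts,
                            "eval_strategy": es,
                            "class": cn,
                            "mean_auc": self.mean[i, j, c],
                            "sd_auc": self.sd[i, j, c],
                        }
                    )
        return pd.DataFrame(rows)

    def plot_heatmap(self, class_name: str | None = None, ax=None):
        """Heatmap of the matrix for one class (rows: training strategy,
        columns: evaluation strategy)."""
        import matplotlib.pyplot as plt

        c = 0 if class_name is None else self.class_names.index(class_name)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.mean[:, :, c], vmin=0.3, vmax=1.0, cmap="viridis")
        ax.set_xticks(range(len(self.eval_strategies)), self.eval_strategies, rotation=45)
        ax.set_yticks(range(len(self.train_strategies)), self.train_strategies)
        ax.set_xlabel("evaluation masking")
        ax.set_ylabel("training masking")
        for i in range(len(self.train_strategies)):
            for j in range(len(self.eval_strategies)):
                v = self.mean[i, j, c]
                if np.isfinite(v):
                    ax.text(j, i, f"{v:.2f}", ha="center", va="center", color="w", fontsize=8)
        ax.figure.colorbar(im, ax=ax, label="mean AUC")
        return ax


@dataclass
class DilationCurve:
    """Mean +/- SD AUC over folds as a function of the dilation factor."""

    factors: list[int]
    mean: np.ndarray  # (n_factors, n_classes)
    sd: np.ndarray
    base: str
    subset: str
    class_names: list[str]

    def __post_init__(self) -> None:
        if list(self.factors) != sorted(set(self.factors)):
            raise ValueError("factors must be strictly increasing")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for k, f in enumerate(self.factors):
            for c, cn in enumerate(self.class_names):
                rows.append(
                    {
                        "factor": f,
                        "subset": self.subset,
                        "base": self.base,
                        "class": cn,
                        "mean_auc": self.mean[k, c],
                        "sd_auc": self.sd[k, c],
                    }
                )
        return pd.DataFrame(rows)


def _fold_aucs(
    models: Sequence, images: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class mean/sd AUC over fold models on a fixed evaluated set."""
    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = labels[:, None]
    per_fold = np.full((len(models), labels.shape[1]), np.nan)
    for f, model in enumerate(models):
        scores = model.predict_proba(images)
        for c in range(labels.shape[1]):
            if len(np.unique(labels[:, c])) < 2:
                continue  # undefined cell, stays NaN
            per_fold[f, c] = auc(scores[:, c], labels[:, c])
    return per_fold.mean(axis=0), per_fold.std(axis=0)


def cross_masking_evaluation(
    models: Mapping[tuple[str, int], object],
    images: np.ndarray,
    masks: np.ndarray,
    labels: np.ndarray,
    class_names: Sequence[str] | None = None,
    strategies: Sequence[str] | None = None,
    n_folds: int = 5,
) -> AUCMatrix:
    """Evaluate every (train strategy, fold) model on every masked variant of
    the test set.

    ``models`` maps ``(strategy_name, fold)`` to a fitted model; a missing
    cell raises immediately.
    """
    strategies = [MaskingStrategy(s).value for s in (strategies or STRATEGY_ORDER)]
    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = labels[:, None]
    names = list(class_names) if class_names is not None else [
        f"class_{c}" for c in range(labels.shape[1])
    ]
    for ts in strategies:
        for f in range(n_folds):
            if (ts, f) not in models:
                raise KeyError(f"missing model for train strategy {ts!r}, fold {f}")
    mean = np.full((len(strategies), len(strategies), labels.shape[1]), np.nan)
    sd = np.full_like(mean, np.nan)
    for j, es in enumerate(strategies):
        masked = np.stack([apply_strategy(img, msk, es) for img, msk in zip(images, masks)])
        for i, ts in enumerate(strategies):
            fold_models = [models[(ts, f)] for f in range(n_folds)]
            mean[i, j], sd[i, j] = _fold_aucs(fold_models, masked, labels)
    return AUCMatrix(
        train_strategies=list(strategies),
        eval_strategies=list(strategies),
        class_names=names,
        mean=mean,
        sd=sd,
        n_folds=n_folds,
    )


def dilation_sweep(
    models: Sequence,
    images: np.ndarray,
    masks: np.ndarray,
    labels: np.ndarray,
    base: MaskingStrategy | str,
    factors: Sequence[int],
    subset: str = "all",
    class_names: Sequence[str] | None = None,
) -> DilationCurve:
    """AUC as a function of mask dilation at inference time.

    For each factor the masks of the selected subset (``all`` /
    ``positives_only`` / ``negatives_only``) are dilated before applying the
    base strategy (``ONLY_ROI`` or ``NO_ROI``); the models (one per fold) are
    then evaluated on the resulting images.  Two protocols are supported by
    choice of ``models``: models trained on FULL images (where does the
    signal live?) or models trained on the base strategy itself
    (ROI-size confound probing).
    """
    base = MaskingStrategy(base)
    factors = list(factors)
    if sorted(set(factors)) != factors:
        raise ValueError("factors must be sorted ascending without duplicates")
    labels_arr = np.asarray(labels)
    y_flat = labels_arr[:, 0] if labels_arr.ndim == 2 else labels_arr
    if subset == "positives_only":
        sel = y_flat == 1
    elif subset == "negatives_only":
        sel = y_flat == 0
    elif subset == "all":
        sel = np.ones(y_flat.size, dtype=bool)
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if not sel.any():
        raise ValueError(f"subset {subset!r} selects no records")
    if labels_arr.ndim == 1:
        labels_arr = labels_arr[:, None]
    names = list(class_names) if class_names is not None else [
        f"class_{c}" for c in range(labels_arr.shape[1])
    ]
    mean = np.full((len(factors), labels_arr.shape[1]), np.nan)
    sd = np.full_like(mean, np.nan)
    for k, factor in enumerate(factors):
        masked = []
        for idx, (img, msk) in enumerate(zip(images, masks)):
            m = dilate_mask(msk, factor) if sel[idx] else msk
            masked.append(apply_strategy(img, m, base))
        mean[k], sd[k] = _fold_aucs(models, np.stack(masked), labels_arr)
    return DilationCurve(
        factors=factors, mean=mean, sd=sd, base=base.value, subset=subset, class_names=names
    )
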