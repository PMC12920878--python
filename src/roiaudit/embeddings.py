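"""Representation proximity between full and masked images.

For the model trained on full images, every test image is embedded twice —
once unmasked and once under a masking strategy — and the paired cosine
similarity quantifies how far the representation moves when part of the
image is removed.  A 2-D stochastic-neighbor projection (t-SNE) gives a
global view of the same structure.

A standing caveat, printed with every similarity report: conclusions drawn
from cosine similarities and t-SNE of pre-head features are limited and
should be considered carefully — representational proximity can disagree
with the AUC ordering, because embeddings of images sharing many pixels are
close regardless of what the classification head uses.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .masking import MaskingStrategy, apply_strategy

logger = logging.getLogger(__name__)

__all__ = ["cosine_similarity", "similarity_table", "project_2d", "EMBEDDING_CAVEAT"]

EMBEDDING_CAVEAT = (
    "Note: cosine-similarity and t-SNE comparisons of pre-head embeddings are "
    "limited and should be considered carefully; representational proximity can "
    "disagree with the AUC ordering and must be completed with further analysis."
)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (||u|| ||v||); NaN (with a warning) for a zero vector."""
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        warnings.warn("cosine similarity undefined for a zero vector")
        return float("nan")
    return float(u @ v / (nu * nv))


def similarity_table(
    model,
    images: np.ndarray,
    masks: np.ndarray,
    labels: np.ndarray,
    class_names: Sequence[str] | None = None,
    strategies: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Paired cosine similarity between embeddings of full and masked images.

    One row per (strategy, class-or-'All') with the mean and SD over the
    images carrying that class label; pairing is by image identity.  The
    model should be the one trained on FULL images.  Empty class subsets are
    flagged with NaN, not dropped.
    """
    if strategies is None:
        strategies = [s.value for s in MaskingStrategy if s is not MaskingStrategy.FULL]
    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = labels[:, None]
    names = list(class_names) if class_names is not None else [
        f"class_{c}" for c in range(labels.shape[1])
    ]
    emb_full = model.embed(np.asarray(images))
    rows = []
    for strat in strategies:
        masked = np.stack(
            [apply_strategy(img, msk, strat) for img, msk in zip(images, masks)]
        )
        emb_masked = model.embed(masked)
        sims = np.array(
            [cosine_similarity(a, b) for a, b in zip(emb_full, emb_masked)]
        )
        groups: list[tuple[str, np.ndarray]] = [("All", np.ones(len(sims), dtype=bool))]
        groups += [(cn, labels[:, c] == 1) for c, cn in enumerate(names)]
        for gname, sel in groups:
            if sel.any():
                rows.append(
                    {
                        "strategy": str(strat),
                        "class": gname,
                        "mean_cosine": float(np.nanmean(sims[sel])),
                        "sd_cosine": float(np.nanstd(sims[sel])),
                        "n": int(sel.sum()),
                    }
                )
            else:
                rows.append(
                    {"strategy": str(strat), "class": gname,
                     "mean_cosine": float("nan"), "sd_cosine": float("nan"), "n": 0}
                )
    logger.info(EMBEDDING_CAVEAT)
    return pd.DataFrame(rows)


def project_2d(
    embeddings: np.ndarray,
    tags: Sequence[str] | None = None,
    seed: int = 0,
    perplexity: float = 30.0,
    max_points: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded 2-D t-SNE of embedding vectors.

    Subsamples to ``max_points`` (stratified by tag) before projecting.
    Returns ``(coords, kept_indices)``; plot separately with
    :func:`plot_projection`.
    """
    from sklearn.manifold import TSNE

    embeddings = np.asarray(embeddings, dtype=np.float64)
    n = embeddings.shape[0]
    if n < 10:
        raise ValueError("need at least 10 embeddings for a 2-D projection")
    rng = np.random.default_rng(seed)
    if n > max_points:
        if tags is not None:
            tags_arr = np.asarray(tags)
            keep: list[np.ndarray] = []
            per_tag = max_points // len(np.unique(tags_arr))
            for t in np.unique(tags_arr):
                idx = np.flatnonzero(tags_arr == t)
                keep.append(rng.choice(idx, size=min(per_tag, idx.size), replace=False))
            kept = np.sort(np.concatenate(keep))
        else:
            kept = np.sort(rng.choice(n, size=max_points, replace=False))
    else:
        kept = np.arange(n)
    if perplexity >= kept.size:
        raise ValueError(
            f"perplexity ({perplexity}) must be smaller than the number of points "
            f"({kept.size}); lower `perplexity` or pass more embeddings"
        )
    # exact gradients below the Barnes-Hut payoff point: more faithful
    # geometry (identical inputs stay coincident) at negligible cost
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca",
        method="exact" if kept.size <= 500 else "barnes_hut",
    )
    coords = tsne.fit_transform(embeddings[kept])
    return coords, kept


def plot_projection(coords: np.ndarray, tags: Sequence[str], out_path=None, ax=None):
    """Scatter of the 2-D projection, colored and marked by strategy tag."""
    import matplotlib.pyplot as plt

    tags = np.asarray(tags)
    markers = ["o", "^", "s", "*", "x", "D"]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for i, t in enumerate(np.unique(tags)):
        sel = tags == t
        ax.scatter(coords[sel, 0], coords[sel, 1], s=12, alpha=0.7,
                   marker=markers[i % len(markers)], label=str(t))
    ax.legend(fontsize=8)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
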