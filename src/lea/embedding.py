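"""Embedding preprocessing and projection exports.

Probability matrices are visualized on ``-log10`` transformed rows, which
stretches the informative low-probability tails of confident classifier
outputs.  The 2-D embedding itself is delegated to scikit-learn's
Barnes-Hut t-SNE; this module fixes the preprocessing, the Mahalanobis
metric on the transformed matrix, and deterministic seeding, and exports
gridded median overlays as plain tables so plotting stays backend-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import binned_statistic_2d

from .core import MAHALANOBIS_RIDGE

__all__ = ["EmbeddingConfig", "transform_probabilities", "embed", "project_feature"]


@dataclass
class EmbeddingConfig:
    """t-SNE settings: Mahalanobis metric, perplexity 30, exaggeration 4,
    Barnes-Hut angle theta = 0.5."""

    transform: str = "neglog10"
    metric: str = "mahalanobis"
    perplexity: float = 30.0
    exaggeration: float = 4.0
    theta: float = 0.5
    eps: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.perplexity < 2:
            raise ValueError("perplexity must be >= 2")
        if not 0.0 < self.theta <= 1.0:
            raise ValueError("theta must be in (0, 1]")


def transform_probabilities(pm, eps: float = 1e-6) -> np.ndarray:
    """Elementwise ``-log10(max(p, eps))``; shape preserved."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    values = np.asarray(pm.values if hasattr(pm, "values") else pm, dtype=float)
    return -np.log10(np.maximum(values, eps))


def embed(x: np.ndarray, config: EmbeddingConfig | None = None) -> np.ndarray:
    """2-D t-SNE of a (transformed) matrix, deterministic given the seed."""
    from sklearn.manifold import TSNE  # deferred: heavy import

    cfg = config or EmbeddingConfig()
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3 * cfg.perplexity:
        raise ValueError(
            f"need N >= 3 * perplexity = {3 * cfg.perplexity:.0f}, got {x.shape[0]}"
        )
    kwargs = {}
    if cfg.metric == "mahalanobis":
        cov = np.cov(x, rowvar=False)
        kwargs["metric_params"] = {
            "VI": np.linalg.pinv(cov + MAHALANOBIS_RIDGE * np.eye(cov.shape[0]))
        }
    try:
        tsne = TSNE(
            n_components=2,
            perplexity=cfg.perplexity,
            early_exaggeration=cfg.exaggeration,
            angle=cfg.theta,
            metric=cfg.metric,
            method="barnes_hut",
            init="pca" if cfg.metric == "euclidean" else "random",
            random_state=cfg.seed,
            **kwargs,
        )
        return np.asarray(tsne.fit_transform(x))
    except Exception as exc:
        raise RuntimeError(f"embedding backend failed with config {asdict(cfg)}") from exc


def project_feature(
    coords: np.ndarray, values, grid_size: int = 100
) -> pd.DataFrame:
    """Gridded median overlay of a per-cell feature on 2-D coordinates.

    The embedding plane is divided into ``grid_size`` x ``grid_size`` bins;
    per occupied bin, the median of the overlapping cells' values is
    exported together with the bin-center coordinates and the cell count.
    """
    coords = np.asarray(coords, dtype=float)
    vals = np.asarray(values, dtype=float)
    if len(vals) != len(coords):
        raise ValueError("values must align with coordinates")
    med, xe, ye, binnum = binned_statistic_2d(
        coords[:, 0], coords[:, 1], vals, statistic="median", bins=grid_size
    )
    cnt, _, _, _ = binned_statistic_2d(
        coords[:, 0], coords[:, 1], vals, statistic="count", bins=grid_size
    )
    gx, gy = np.nonzero(~np.isnan(med))
    return pd.DataFrame(
        {
            "grid_x": gx,
            "grid_y": gy,
            "x_center": (xe[gx] + xe[gx + 1]) / 2,
            "y_center": (ye[gy] + ye[gy + 1]) / 2,
            "median": med[gx, gy],
            "count": cnt[gx, gy].astype(int),
        }
    )
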