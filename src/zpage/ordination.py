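"""Sample ordination: PCA in gene-z space or pathway-activity space.

PCA is computed on the per-array z-scored matrix with samples as
observations: each gene is centered across samples and the centered matrix
is decomposed by SVD.  Component signs are fixed so the largest-magnitude
loading of each component is positive, making outputs reproducible.

Per-sample pathway activity is the mean z-score of a set's present members
in that sample — the single-sample analog of the PAGE mean member score —
giving a sets x samples matrix that can be ordinated the same way.

Group separation is summarized by the mean silhouette score of the age
groups in the leading components (Euclidean distance), turning the visual
"distinct separation" of a PCA plot into a number in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .containers import GeneSetCollection, ZScoreMatrix
from .page import map_sets_to_array


@dataclass
class PCAResult:
    """Sample coordinates, gene loadings and explained-variance fractions."""

    coordinates: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components, orthonormal columns
    explained_variance_ratio: np.ndarray  # nonincreasing, sums to <= 1

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


def _pca(values: pd.DataFrame, k: int) -> PCAResult:
    # values: features x samples; samples are the observations.
    x = values.to_numpy(dtype=float).T
    n_samples, n_features = x.shape
    max_k = min(n_samples - 1, n_features)
    if not (1 <= k <= max_k):
        raise ValueError(f"k must lie in [1, {max_k}], got {k}")
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # Deterministic sign: largest-|loading| entry of each component positive.
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    var = s**2 / (n_samples - 1)
    ratio = var / (centered.var(axis=0, ddof=1).sum())
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        coordinates=pd.DataFrame(
            u[:, :k] * s[:k], index=values.columns, columns=comp_names
        ),
        loadings=pd.DataFrame(vt[:k].T, index=values.index, columns=comp_names),
        explained_variance_ratio=ratio[:k],
    )


def pca_samples(z: ZScoreMatrix, k: int = 2) -> PCAResult:
    """PCA of samples in gene-z space (gene-wise centering, then SVD)."""
    return _pca(z.values, k)


def pathway_activity(
    z: ZScoreMatrix, collection: GeneSetCollection, min_set_size: int = 1
) -> pd.DataFrame:
    """Per-sample per-set activity: mean z of the set's present members.

    Returns a sets x samples DataFrame; sets with fewer than
    ``min_set_size`` members on the array are dropped.
    """
    mapped, _ = map_sets_to_array(collection, z.values.index, min_set_size)
    rows = {
        name: z.values.loc[list(mapped.members(name))].mean(axis=0)
        for name in mapped.names
    }
    return pd.DataFrame(rows).T


def pca_pathways(
    z: ZScoreMatrix, collection: GeneSetCollection, k: int = 2
) -> PCAResult:
    """PCA of samples in pathway-activity space."""
    return _pca(pathway_activity(z, collection), k)


def group_separation(coordinates: pd.DataFrame, labels: pd.Series | dict) -> float:
    """Mean silhouette score of labelled samples in the given coordinates.

    Euclidean distance; requires at least two distinct labels.  Higher is
    better; values near 0 indicate no separation beyond chance.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    labels = labels.reindex(coordinates.index)
    if labels.isna().any():
        raise ValueError("every sample needs a label")
    if labels.nunique() < 2:
        raise ValueError("need at least 2 distinct labels for a silhouette score")
    return float(silhouette_score(coordinates.to_numpy(), labels.to_numpy()))
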