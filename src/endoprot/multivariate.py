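"""Unsupervised structure: PCA by SVD and hierarchical clustering.

PCA treats samples as observations and proteins as variables, centers each
protein (column) and decomposes by singular value decomposition; explained
variance fractions are the normalized squared singular values.  Hierarchical
clustering uses Euclidean distance (the metric the source analysis names)
with average linkage (UPGMA) by default; cutting into ``k`` groups removes
the ``k-1`` highest merges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from .errors import ValidationError
from .preprocess import ExpressionMatrix

LINKAGE_METHODS = ("single", "complete", "average", "ward")


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # proteins x components
    explained_variance_ratio: np.ndarray


@dataclass
class ClusteringResult:
    linkage: np.ndarray  # scipy linkage matrix (merge members + heights)
    items: list[str]
    axis: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.items[i] for i in hierarchy.leaves_list(self.linkage)]


def pca(m: ExpressionMatrix, center: bool = True, n_components: int | None = None
        ) -> PcaResult:
    """Principal components of the samples-by-proteins matrix via SVD.

    Component sign is fixed by making the largest-magnitude loading positive,
    so results are fully deterministic.
    """
    if not m.is_complete:
        raise ValidationError("PCA requires a complete matrix; impute first")
    if len(m.samples) < 2:
        raise ValidationError("PCA requires >=2 samples")
    X = m.values.T.to_numpy(dtype=float)  # samples x proteins
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    total = (s**2).sum()
    evr = s**2 / total if total > 0 else np.zeros_like(s)
    k = n_components or len(s)
    comps = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        scores=pd.DataFrame(U[:, :k] * s[:k], index=m.samples, columns=comps),
        loadings=pd.DataFrame(Vt[:k].T, index=m.values.index, columns=comps),
        explained_variance_ratio=evr[:k],
    )


def hierarchical_cluster(
    m: ExpressionMatrix, axis: str = "proteins", linkage: str = "average"
) -> ClusteringResult:
    """Agglomerative clustering under Euclidean distance.

    ``axis='proteins'`` clusters rows, ``axis='samples'`` clusters columns.
    """
    if linkage not in LINKAGE_METHODS:
        raise ValidationError(f"linkage must be one of {LINKAGE_METHODS}")
    if not m.is_complete:
        raise ValidationError("clustering requires a complete matrix")
    if axis == "proteins":
        data = m.values.to_numpy(dtype=float)
        items = list(m.values.index)
    elif axis == "samples":
        data = m.values.T.to_numpy(dtype=float)
        items = list(m.values.columns)
    else:
        raise ValidationError("axis must be 'proteins' or 'samples'")
    if len(items) < 2:
        raise ValidationError("need >=2 items to cluster")
    Z = hierarchy.linkage(data, method=linkage, metric="euclidean")
    return ClusteringResult(linkage=Z, items=items, axis=axis)


def cut_clusters(c: ClusteringResult, k: int) -> pd.Series:
    """Partition into ``k`` groups by removing the ``k-1`` highest merges."""
    n = len(c.items)
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    labels = hierarchy.cut_tree(c.linkage, n_clusters=k).ravel()
    return pd.Series(labels + 1, index=c.items, name="cluster")


def label_agreement(assignments: Sequence, labels: Sequence) -> float:
    """Adjusted Rand index between a clustering and external labels."""
    if len(assignments) != len(labels):
        raise ValidationError("assignments and labels must have equal length")
    return float(adjusted_rand_score(list(labels), list(assignments)))
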