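"""Hierarchical clustering of samples over selected genes.

Genes are standardized to equal variance (mean 0, sample variance 1 with
the n-1 denominator), samples are agglomerated under Euclidean distance
(average linkage by default), and cohort segregation is assessed by
cutting the tree and cross-tabulating clusters against cohort labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import ExpressionMatrix

LINKAGES = ("average", "complete", "single", "ward")


def scale_genes(matrix_log: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Center each gene to mean 0 and scale to sample variance 1 (ddof=1).

    Zero-variance genes become all-zero rows and are returned as flags.
    """
    vals = matrix_log.values.astype(float)
    if vals.shape[1] < 2:
        raise ValueError("gene scaling requires >= 2 samples")
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    flagged = list(vals.index[sd == 0])
    safe_sd = sd.replace(0.0, 1.0)
    scaled = vals.sub(mu, axis=0).div(safe_sd, axis=0)
    scaled.loc[flagged] = 0.0
    return matrix_log.with_values(scaled), flagged


@dataclass
class Dendrogram:
    """Agglomeration result: scipy linkage matrix plus leaf labels."""

    linkage_matrix: np.ndarray  # (n-1, 4): merged ids, height, cluster size
    labels: list[str]
    metric: str = "euclidean"
    method: str = "average"

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[str]:
        order = hierarchy.dendrogram(self.linkage_matrix, no_plot=True)["leaves"]
        return [self.labels[i] for i in order]


def hierarchical_cluster(matrix: ExpressionMatrix, axis: str = "samples",
                         linkage: str = "average") -> Dendrogram:
    """Agglomerative Euclidean clustering of samples (default) or genes."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    if axis not in ("samples", "genes"):
        raise ValueError("axis must be 'samples' or 'genes'")
    vals = matrix.values.astype(float)
    data = vals.T if axis == "samples" else vals
    labels = list(data.index)
    if len(labels) < 2:
        raise ValueError("clustering requires >= 2 items")
    arr = np.asarray(data, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("clustering input contains non-finite values")
    z = hierarchy.linkage(pdist(arr, metric="euclidean"), method=linkage)
    return Dendrogram(linkage_matrix=z, labels=labels, method=linkage)


def evaluate_segregation(dendrogram: Dendrogram, labels: pd.Series, k: int = 2
                         ) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    """Cut the tree into ``k`` clusters and cross-tabulate against labels.

    Outliers are samples whose cluster's majority label differs from their
    own label.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > dendrogram.n_leaves:
        raise ValueError(f"k={k} exceeds leaf count {dendrogram.n_leaves}")
    labels = pd.Series(labels).reindex(dendrogram.labels)
    if labels.isna().any():
        missing = labels.index[labels.isna()]
        raise ValueError(f"labels missing for leaves: {list(missing[:5])}")
    assignment = pd.Series(
        hierarchy.fcluster(dendrogram.linkage_matrix, t=k, criterion="maxclust"),
        index=dendrogram.labels, name="cluster",
    )
    crosstab = pd.crosstab(assignment, labels)
    majority = crosstab.idxmax(axis=1)
    outliers = [s for s in assignment.index
                if labels[s] != majority[assignment[s]]]
    return assignment, crosstab, outliers
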