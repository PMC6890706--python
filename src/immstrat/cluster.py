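"""Discovery clustering of the sample-sample correlation matrix.

The discovery procedure: compute Pearson correlations between samples
over the immune-panel genes, hierarchically cluster the correlation
matrix (correlation distance between its rows, unsquared Ward linkage by
default), cut the dendrogram into k groups, select k by the mean
silhouette width of k-means partitions, and name the k = 3 clusters
A/B/C by ascending median lymphoid infiltration score.

Linkage semantics follow the R hclust conventions: ``ward_d`` applies the
Lance-Williams Ward update to the raw dissimilarities, ``ward_d2`` to the
squared ones.  scipy's 'ward' implements the squared variant; the raw
variant is obtained by feeding it sqrt-transformed dissimilarities (a
monotone transform of the recurrence, so merge order and cuts coincide)
and squaring the merge heights back.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io import ExpressionMatrix, ImmstratError

__all__ = [
    "SampleCorrelationMatrix",
    "ClusterAssignment",
    "sample_correlation_matrix",
    "hierarchical_clusters",
    "select_k_silhouette",
    "order_clusters_by_infiltration",
]

logger = logging.getLogger(__name__)


@dataclass
class SampleCorrelationMatrix:
    """Symmetric sample-sample Pearson correlation matrix (unit diagonal)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.data.to_numpy()
        if v.shape[0] != v.shape[1] or list(self.data.index) != list(self.data.columns):
            raise ImmstratError("correlation matrix must be square with matching labels")
        if np.abs(v - v.T).max() > 1e-10:
            raise ImmstratError("correlation matrix must be symmetric")
        if np.abs(np.diag(v) - 1.0).max() > 1e-10:
            raise ImmstratError("correlation matrix diagonal must be 1")
        if v.min() < -1 - 1e-10 or v.max() > 1 + 1e-10:
            raise ImmstratError("correlations must lie in [-1, 1]")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class ClusterAssignment:
    """Per-sample cluster labels plus provenance.

    ``source`` records whether labels came from unsupervised clustering or
    from the single-sample classifier.  ``merge_tree`` holds the scipy
    linkage matrix when available.
    """

    labels: pd.Series
    k: int
    source: str = "clustered"
    merge_tree: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        used = self.labels.unique()
        if len(used) != self.k:
            raise ImmstratError(
                f"assignment uses {len(used)} labels but declares k={self.k}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.labels.index)

    def groups(self) -> dict[str, list[str]]:
        return {lab: list(idx) for lab, idx in self.labels.groupby(self.labels).groups.items()}


def sample_correlation_matrix(matrix: ExpressionMatrix) -> SampleCorrelationMatrix:
    """Pearson correlation between every pair of samples' gene vectors."""
    if matrix.shape[1] < 3:
        raise ImmstratError("need at least 3 samples for a correlation matrix")
    values = matrix.values
    sd = values.std(axis=0)
    if (sd == 0).any():
        bad = [s for s, z in zip(matrix.samples, sd == 0) if z]
        raise ImmstratError(f"zero-variance sample(s): {bad[:5]}")
    corr = np.corrcoef(values.T)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    return SampleCorrelationMatrix(
        pd.DataFrame(corr, index=matrix.samples, columns=matrix.samples)
    )


def _row_dissimilarity(values: np.ndarray, distance: str) -> np.ndarray:
    """Pairwise dissimilarity between rows of a feature matrix."""
    if distance == "correlation":
        # 1 - Pearson correlation of the rows (the heatmap-tool semantics).
        d = 1.0 - np.corrcoef(values)
        np.fill_diagonal(d, 0.0)
        d = np.maximum((d + d.T) / 2.0, 0.0)
    elif distance == "direct":
        # For a correlation matrix: d(i, j) = 1 - corr(i, j) directly.
        d = 1.0 - values
        np.fill_diagonal(d, 0.0)
        d = np.maximum((d + d.T) / 2.0, 0.0)
    elif distance == "maximum":
        d = np.max(np.abs(values[:, None, :] - values[None, :, :]), axis=2)
    elif distance == "euclidean":
        diff = values[:, None, :] - values[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
    else:
        raise ImmstratError(f"unknown distance {distance!r}")
    return d


def linkage_from_dissimilarity(d: np.ndarray, method: str) -> np.ndarray:
    """scipy linkage matrix for a square dissimilarity under hclust semantics."""
    condensed = squareform(d, checks=False)
    if method == "ward_d":
        z = linkage(np.sqrt(condensed), method="ward")
        z = z.copy()
        z[:, 2] = z[:, 2] ** 2  # back to raw-dissimilarity Ward heights
    elif method == "ward_d2":
        z = linkage(condensed, method="ward")
    elif method == "complete":
        z = linkage(condensed, method="complete")
    else:
        raise ImmstratError(f"unknown linkage {method!r}")
    return z


def hierarchical_clusters(
    corr: SampleCorrelationMatrix,
    k: int,
    linkage_method: str = "ward_d",
    distance: str = "correlation",
) -> ClusterAssignment:
    """Agglomerative clustering of the correlation matrix, cut into k groups.

    ``distance='correlation'`` treats each sample's row of correlations as
    its feature vector and uses 1 - Pearson correlation between rows;
    ``'direct'`` uses 1 - corr(i, j) itself.
    """
    n = len(corr.samples)
    if not 2 <= k <= n:
        raise ImmstratError(f"k={k} outside [2, {n}]")
    d = _row_dissimilarity(corr.values, distance)
    z = linkage_from_dissimilarity(d, linkage_method)
    flat = fcluster(z, t=k, criterion="maxclust")
    if len(np.unique(flat)) != k:
        raise ImmstratError(f"dendrogram cut produced {len(np.unique(flat))} != {k} groups")
    labels = pd.Series([str(c) for c in flat], index=corr.samples, name="cluster")
    return ClusterAssignment(labels=labels, k=k, source="clustered", merge_tree=z)


def select_k_silhouette(
    corr: SampleCorrelationMatrix,
    k_range=range(3, 11),
    n_restarts: int = 25,
    seed: int = 0,
) -> tuple[int, pd.Series]:
    """Choose k by mean silhouette width of k-means on the correlation rows.

    Returns the argmax k and the per-k mean silhouette widths (Euclidean
    distance, k-means++ initialization with ``n_restarts`` restarts).
    """
    values = corr.values
    n = values.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ImmstratError(f"k_range must lie within [2, {n - 1}]")
    if np.allclose(values, values[0]):
        raise ImmstratError("all samples identical; silhouette analysis is undefined")
    widths = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        part = km.fit_predict(values)
        if len(np.unique(part)) < 2:
            raise ImmstratError(f"k-means collapsed to one cluster at k={k}")
        widths[k] = float(silhouette_score(values, part, metric="euclidean"))
    widths = pd.Series(widths, name="mean_silhouette_width")
    return int(widths.idxmax()), widths


def order_clusters_by_infiltration(
    assignment: ClusterAssignment, lymphoid_scores: pd.Series
) -> ClusterAssignment:
    """Rename three clusters A/B/C by ascending median lymphoid score.

    A = lowest infiltration, C = highest, matching the discovery naming.
    Tied medians are broken by cluster size (larger first) with a warning.
    """
    if assignment.k != 3:
        raise ImmstratError("infiltration ordering is defined for k=3")
    missing = set(assignment.samples) - set(lymphoid_scores.index)
    if missing:
        raise ImmstratError(f"lymphoid scores missing for {sorted(missing)[:5]}")
    stats = []
    for lab, members in assignment.groups().items():
        stats.append((lab, float(lymphoid_scores.loc[members].median()), len(members)))
    medians = [s[1] for s in stats]
    if len(set(medians)) < len(medians):
        logger.warning("tied median lymphoid scores; breaking ties by cluster size")
    stats.sort(key=lambda s: (s[1], -s[2]))
    rename = {lab: new for (lab, _, _), new in zip(stats, ["A", "B", "C"])}
    labels = assignment.labels.map(rename)
    labels.name = "cluster"
    return ClusterAssignment(
        labels=labels, k=3, source=assignment.source, merge_tree=assignment.merge_tree
    )
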