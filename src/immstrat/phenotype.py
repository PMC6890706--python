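"""Cluster-B phenotype: differential expression, enrichment, B1/B2 split.

Genes overexpressed in the poor-prognosis cluster are defined by Welch
t-tests of B against A and against C separately, each Bonferroni-corrected
over the genes tested, at a strict corrected threshold (default 1e-4);
a gene is "up in B" only when both comparisons pass and the B mean is
higher in both.  Over-representation of such genes in curated sets is
assessed by an inclusive upper-tail hypergeometric test.  Cluster B is
finally split into B1 (EMT-like) and B2 (proliferative) by hierarchical
clustering of its gene-set score profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster

from .cluster import ClusterAssignment, linkage_from_dissimilarity, _row_dissimilarity
from .io import ExpressionMatrix, GeneSetCollection, ImmstratError
from .microenv import GeneSetScores

__all__ = [
    "DifferentialResult",
    "EnrichmentResult",
    "differential_genes_b",
    "hypergeometric_enrichment",
    "subcluster_b",
]


@dataclass
class DifferentialResult:
    """Per-gene t statistics and Bonferroni-corrected p for B-vs-A, B-vs-C."""

    table: pd.DataFrame
    alpha: float

    def up_in_b(self) -> list[str]:
        return list(self.table.index[self.table["up_in_B"]])


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # set, overlap, set_size, query_size, universe_size, p

    def __post_init__(self) -> None:
        t = self.table
        if (t["overlap"] > np.minimum(t["set_size"], t["query_size"])).any():
            raise ImmstratError("overlap exceeds set or query size")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            raise ImmstratError("hypergeometric p must lie in (0, 1]")


def differential_genes_b(
    matrix: ExpressionMatrix,
    clusters: ClusterAssignment,
    alpha: float = 1e-4,
    bonferroni_scope: str = "genes",
) -> DifferentialResult:
    """Welch t-tests of Cluster B against A and C with Bonferroni control.

    ``bonferroni_scope='genes'`` multiplies each raw p by the number of
    genes tested within its comparison (default); ``'genes_x_comparisons'``
    additionally doubles the factor.
    """
    labels = clusters.labels.loc[matrix.samples]
    groups = {c: matrix.data.loc[:, labels.index[labels == c]] for c in ("A", "B", "C")}
    for c, g in groups.items():
        if g.shape[1] < 3:
            raise ImmstratError(f"cluster {c} has {g.shape[1]} samples; need >= 3")
    n_genes = matrix.shape[0]
    factor = n_genes * (2 if bonferroni_scope == "genes_x_comparisons" else 1)
    if bonferroni_scope not in ("genes", "genes_x_comparisons"):
        raise ImmstratError(f"unknown bonferroni_scope {bonferroni_scope!r}")

    out = {}
    for other in ("A", "C"):
        b, o = groups["B"].to_numpy(), groups[other].to_numpy()
        zero_var = (b.std(axis=1) == 0) & (o.std(axis=1) == 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(b, o, axis=1, equal_var=False)
        t = np.where(zero_var, 0.0, t)
        p = np.where(zero_var, 1.0, p)
        out[f"t_B_vs_{other}"] = t
        out[f"p_B_vs_{other}"] = p
        out[f"p_adj_B_vs_{other}"] = np.minimum(1.0, p * factor)
        out[f"mean_diff_B_vs_{other}"] = b.mean(axis=1) - o.mean(axis=1)
        out[f"zero_variance_vs_{other}"] = zero_var
    table = pd.DataFrame(out, index=matrix.genes)
    table["up_in_B"] = (
        (table["mean_diff_B_vs_A"] > 0)
        & (table["mean_diff_B_vs_C"] > 0)
        & (table["p_adj_B_vs_A"] < alpha)
        & (table["p_adj_B_vs_C"] < alpha)
    )
    return DifferentialResult(table=table, alpha=alpha)


def hypergeometric_enrichment(
    query: list[str], sets: GeneSetCollection, universe: list[str]
) -> EnrichmentResult:
    """Upper-tail (inclusive) hypergeometric over-representation test.

    p = P(X >= overlap) with X ~ Hypergeom(N=|universe|, K=|set in
    universe|, n=|query|).  The query must be a subset of the universe;
    each set is intersected with the universe first.
    """
    universe_set = set(universe)
    query_set = set(query)
    if not universe_set or not query_set:
        raise ImmstratError("query and universe must be non-empty")
    if not query_set <= universe_set:
        raise ImmstratError("query genes must be a subset of the universe")
    N, n = len(universe_set), len(query_set)
    rows = []
    for name, genes in sets.sets.items():
        in_univ = set(genes) & universe_set
        K = len(in_univ)
        k = len(in_univ & query_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p": min(p, 1.0),
            }
        )
    return EnrichmentResult(table=pd.DataFrame(rows).set_index("set"))


def subcluster_b(
    scores: GeneSetScores,
    emt_set: str = "emt_program",
    linkage_method: str = "ward_d",
    distance: str = "correlation",
) -> ClusterAssignment:
    """Split Cluster B samples into B1 (EMT-like) and B2 (proliferative).

    ``scores`` must already be restricted to Cluster B samples.  Samples
    are hierarchically clustered on their gene-set score profiles
    (correlation distance, unsquared Ward linkage) and cut at k=2; the
    sub-cluster with the higher median score for ``emt_set`` is B1.
    """
    s = scores.scores.dropna(axis=1, how="all")
    if s.shape[0] < 4:
        raise ImmstratError("B sub-clustering needs at least 4 samples")
    if s.shape[1] < 2:
        raise ImmstratError("B sub-clustering needs at least 2 gene sets")
    if emt_set not in s.columns:
        raise ImmstratError(f"EMT-designated set {emt_set!r} not among the scores")
    values = s.to_numpy()
    if np.unique(values, axis=0).shape[0] < 2:
        raise ImmstratError("fewer than 2 distinct score profiles; cannot split")
    z = linkage_from_dissimilarity(_row_dissimilarity(values, distance), linkage_method)
    flat = fcluster(z, t=2, criterion="maxclust")
    med = {c: float(np.median(s[emt_set].to_numpy()[flat == c])) for c in np.unique(flat)}
    b1 = max(med, key=med.get)
    labels = pd.Series(
        np.where(flat == b1, "B1", "B2"), index=s.index, name="cluster"
    )
    return ClusterAssignment(labels=labels, k=2, source="clustered", merge_tree=z)
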