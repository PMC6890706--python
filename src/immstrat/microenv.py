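"""Microenvironment dissection: deconvolution, gene-set scores, explainers.

Cell-type proportions are inferred per sample by constrained linear
deconvolution: non-negative least squares of the (linear-scale) bulk
profile on the cell-type signature matrix, with both sides standardized
per gene using the signature-row statistics.  This is a self-contained,
exactly testable stand-in for reference-based deconvolution tools that
use nu-support-vector regression.

Single-sample gene-set activity is the mean of cohort-standardized gene
z-scores over the set's measured genes — a deterministic score with the
same ordering intent as rank-based single-sample enrichment methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from statsmodels.api import GLM, add_constant, families
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterAssignment, linkage_from_dissimilarity, _row_dissimilarity
from .io import ExpressionMatrix, GeneSetCollection, ImmstratError
from .simulate import CellTypeSignatureMatrix

__all__ = [
    "CellTypeProportions",
    "GeneSetScores",
    "ExplainerResult",
    "deconvolve",
    "geneset_score",
    "celltype_median_map",
    "logistic_explainers",
    "correlate_scores_proportions",
]

logger = logging.getLogger(__name__)


@dataclass
class CellTypeProportions:
    """Samples x cell types: non-negative absolute scores and, where the
    absolute scores have positive sum, relative fractions (rows sum to 1)."""

    absolute: pd.DataFrame
    relative: pd.DataFrame
    undefined: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.absolute.to_numpy() < -1e-12).any():
            raise ImmstratError("absolute cell-type scores must be non-negative")
        rel = self.relative.dropna()
        if len(rel) and np.abs(rel.sum(axis=1) - 1.0).max() > 1e-9:
            raise ImmstratError("relative fractions must sum to 1 per sample")


@dataclass
class GeneSetScores:
    scores: pd.DataFrame  # samples x sets
    flagged: dict[str, int] = field(default_factory=dict)  # sets with <2 measured genes


@dataclass
class ExplainerResult:
    """Per-feature logistic regression summary (Wald inference, BH FDR)."""

    table: pd.DataFrame  # feature, estimate, se, ci_lo, ci_hi, p, fdr_p, unreliable

    def __post_init__(self) -> None:
        t = self.table
        ok = (t["ci_lo"] <= t["estimate"] + 1e-12) & (t["estimate"] <= t["ci_hi"] + 1e-12)
        if not ok.all():
            raise ImmstratError("confidence interval does not contain the estimate")
        if ((t["fdr_p"] + 1e-12) < t["p"]).any():
            raise ImmstratError("FDR-adjusted p below raw p")


def deconvolve(
    bulk: ExpressionMatrix, signature: CellTypeSignatureMatrix
) -> CellTypeProportions:
    """Non-negative least-squares deconvolution of each bulk sample.

    The bulk matrix is log2 expression; it is returned to linear scale
    (2^x - 1, floored at 0) and restricted to the signature genes.  Both
    sides are scaled per gene by the signature row's standard deviation so
    every gene contributes comparably, then each sample solves
    min ||S w - b||_2 subject to w >= 0.  (Rows are scaled, not centered:
    row-centering would put the all-ones direction in the null space of S
    and make the weights unidentifiable.)
    """
    sig_genes = [g for g in signature.genes if g in set(bulk.genes)]
    n_types = len(signature.celltypes)
    if len(sig_genes) < 2 * n_types:
        raise ImmstratError(
            f"only {len(sig_genes)} signature genes in bulk; need >= {2 * n_types}"
        )
    S = signature.data.loc[sig_genes].to_numpy(dtype=float)
    mu = S.mean(axis=1)
    sd = S.std(axis=1)
    if (sd < 1e-12).any():
        bad = [g for g, s in zip(sig_genes, sd) if s < 1e-12]
        raise ImmstratError(f"signature rows with zero variance: {bad[:5]}")
    Sz = S / sd[:, None]
    if np.linalg.matrix_rank(Sz) < n_types:
        raise ImmstratError("signature matrix is collinear; deconvolution is ill-posed")
    B = np.maximum(2.0 ** bulk.data.loc[sig_genes].to_numpy(dtype=float) - 1.0, 0.0)
    Bz = B / sd[:, None]

    W = np.empty((bulk.shape[1], n_types))
    for i in range(bulk.shape[1]):
        W[i], _ = nnls(Sz, Bz[:, i])
    absolute = pd.DataFrame(W, index=bulk.samples, columns=signature.celltypes)
    sums = absolute.sum(axis=1)
    undefined = list(absolute.index[sums <= 0])
    if undefined:
        logger.warning("%d samples have all-zero weights; relative fractions undefined", len(undefined))
    relative = absolute.div(sums.where(sums > 0), axis=0)
    return CellTypeProportions(absolute=absolute, relative=relative, undefined=undefined)


def geneset_score(matrix: ExpressionMatrix, sets: GeneSetCollection) -> GeneSetScores:
    """Mean-z single-sample score per gene set.

    Each gene is z-scored across samples (zero-variance genes dropped with
    a warning); a sample's score for a set is the mean z over the set's
    measured genes.  Sets with no measured genes get NaN scores and are
    flagged, never silently zero.
    """
    if matrix.shape[1] < 2:
        raise ImmstratError("gene-set scoring needs at least 2 samples")
    values = matrix.values
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance genes from scoring", int((~keep).sum()))
    z = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    zdf = pd.DataFrame(z, index=np.array(matrix.genes)[keep], columns=matrix.samples)
    cols = {}
    flagged = {}
    for name, genes in sets.sets.items():
        measured = [g for g in genes if g in zdf.index]
        if len(measured) == 0:
            logger.warning("gene set %r has no measured genes; score undefined", name)
            cols[name] = pd.Series(np.nan, index=matrix.samples)
            flagged[name] = 0
            continue
        if len(measured) < 2:
            flagged[name] = len(measured)
        cols[name] = zdf.loc[measured].mean(axis=0)
    return GeneSetScores(scores=pd.DataFrame(cols), flagged=flagged)


def celltype_median_map(
    proportions: CellTypeProportions,
    clusters: ClusterAssignment,
    cohort_labels: pd.Series | None = None,
    linkage_method: str = "ward_d2",
    distance: str = "maximum",
):
    """Median absolute score per cell type per (cohort x cluster) stratum.

    Returns the median table (strata x cell types) plus row and column
    linkage trees computed with maximum (Chebyshev) distance and
    unsquared-input Ward ('ward_d2') linkage by default.
    """
    samples = proportions.absolute.index
    if cohort_labels is None:
        cohort_labels = pd.Series("cohort", index=samples)
    strata = pd.DataFrame(
        {"cohort": cohort_labels.loc[samples], "cluster": clusters.labels.loc[samples]}
    )
    rows = {}
    for (cohort, cluster), members in strata.groupby(["cohort", "cluster"]).groups.items():
        rows[f"{cohort}|{cluster}"] = proportions.absolute.loc[members].median(axis=0)
    table = pd.DataFrame(rows).T
    table.index.name = "stratum"
    row_z = col_z = None
    if table.shape[0] >= 3:
        row_z = linkage_from_dissimilarity(
            _row_dissimilarity(table.to_numpy(), distance), linkage_method
        )
    if table.shape[1] >= 3:
        col_z = linkage_from_dissimilarity(
            _row_dissimilarity(table.to_numpy().T, distance), linkage_method
        )
    return table, row_z, col_z


def logistic_explainers(
    features: pd.DataFrame,
    target: pd.Series,
    mode: str = "multivariable",
    separation_threshold: float = 20.0,
) -> ExplainerResult:
    """Which features explain a binary target (e.g. Cluster B membership)?

    Features are standardized internally; the fit is unpenalized maximum
    likelihood (Newton-Raphson).  ``mode='multivariable'`` fits one model
    with all features; ``'univariate'`` fits one model per feature.  Wald
    95% CIs and Benjamini-Hochberg FDR across features.  Coefficients
    diverging beyond ``separation_threshold`` after standardization are
    flagged unreliable (perfect-separation symptom).
    """
    y = target.loc[features.index].astype(bool).astype(float)
    if y.min() == y.max():
        raise ImmstratError("both target classes must be present")
    sd = features.std(axis=0, ddof=0)
    if (sd < 1e-12).any():
        raise ImmstratError(f"constant feature(s): {list(sd.index[sd < 1e-12])[:5]}")
    Xz = (features - features.mean(axis=0)) / sd
    if mode not in ("multivariable", "univariate"):
        raise ImmstratError(f"unknown mode {mode!r}")

    def _fit(cols: list[str]) -> pd.DataFrame:
        X = add_constant(Xz[cols].to_numpy(), has_constant="add")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ImmstratError("rank-deficient feature matrix (collinear features)")
        model = GLM(y.to_numpy(), X, family=families.Binomial())
        res = model.fit(maxiter=200, tol=1e-8)
        est = res.params[1:]
        se = res.bse[1:]
        return pd.DataFrame(
            {
                "feature": cols,
                "estimate": est,
                "se": se,
                "ci_lo": est - 1.959963984540054 * se,
                "ci_hi": est + 1.959963984540054 * se,
                "p": 2.0 * stats.norm.sf(np.abs(est / se)),
            }
        )

    if mode == "multivariable":
        table = _fit(list(Xz.columns))
    else:
        table = pd.concat([_fit([c]) for c in Xz.columns], ignore_index=True)
    table["unreliable"] = np.abs(table["estimate"]) > separation_threshold
    if table["unreliable"].any():
        logger.warning(
            "possible separation: %s", list(table.loc[table["unreliable"], "feature"])
        )
    table["fdr_p"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["fdr_p"] = np.maximum(table["fdr_p"], table["p"])
    return ExplainerResult(table=table)


def correlate_scores_proportions(
    scores: GeneSetScores, proportions: CellTypeProportions, fdr_level: float = 0.05
):
    """Spearman rho between every (gene set, cell type) pair, with BH FDR.

    Returns (rho, fdr_p, mask) DataFrames indexed set x cell type; the
    mask is True where FDR p < ``fdr_level``.  Constant columns yield
    undefined rho and are masked out with a warning.
    """
    s = scores.scores
    p = proportions.absolute.loc[s.index]
    if len(s) < 10:
        raise ImmstratError("need at least 10 samples for the correlation map")
    rho = pd.DataFrame(index=s.columns, columns=p.columns, dtype=float)
    pval = rho.copy()
    for a in s.columns:
        for b in p.columns:
            x, yv = s[a].to_numpy(), p[b].to_numpy()
            if np.std(x) == 0 or np.std(yv) == 0 or np.isnan(x).all():
                logger.warning("constant column in pair (%s, %s); rho undefined", a, b)
                continue
            r, pv = stats.spearmanr(x, yv)
            rho.at[a, b], pval.at[a, b] = r, pv
    flat = pval.to_numpy().ravel()
    defined = ~np.isnan(flat)
    adj = np.full_like(flat, np.nan)
    if defined.any():
        adj[defined] = multipletests(flat[defined], method="fdr_bh")[1]
    fdr = pd.DataFrame(adj.reshape(pval.shape), index=pval.index, columns=pval.columns)
    mask = fdr < fdr_level
    return rho, fdr, mask
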