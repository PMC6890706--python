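"""Infiltration scores, ER-status inference, PAM50 subtyping and ROR.

Lymphoid/myeloid infiltration is scored as the arithmetic mean of marker
gene expression per sample.  ER status is inferred from a single gene's
expression (ESR1 by default) with a two-component univariate Gaussian
mixture fitted by EM; the higher-mean component is called ER-positive.
PAM50 subtype is the nearest centroid by rank correlation; the
risk-of-recurrence (ROR) score is the published linear combination of the
four tumor-centroid correlations:

    ROR = 0.05*Basal + 0.12*Her2 - 0.34*LumA + 0.23*LumB
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GenePanel, ImmstratError

__all__ = [
    "MarkerScore",
    "ErCall",
    "SubtypeCorrelations",
    "ROR_WEIGHTS",
    "marker_score",
    "infer_er_status",
    "assign_pam50",
    "ror_score",
]

ROR_WEIGHTS = {"basal": 0.05, "her2": 0.12, "luma": -0.34, "lumb": 0.23}
SUBTYPE_ORDER = ["basal", "her2", "luma", "lumb", "normal"]


@dataclass
class MarkerScore:
    scores: pd.Series
    markers_used: list[str]
    missing: list[str]

    @property
    def n_markers_found(self) -> int:
        return len(self.markers_used)


@dataclass
class ErCall:
    """Per-sample ER calls with mixture diagnostics.

    ``labels`` is 'pos'/'neg'; ``posterior`` is P(ER-positive component);
    ``means``/``sds``/``weight`` are the fitted mixture parameters
    (ER-negative component first); ``loglik_trace`` the EM log-likelihood
    per iteration.
    """

    labels: pd.Series
    posterior: pd.Series
    means: tuple[float, float]
    sds: tuple[float, float]
    weight: float
    loglik_trace: list[float]


@dataclass
class SubtypeCorrelations:
    correlations: pd.DataFrame  # samples x 5 subtypes
    assigned: pd.Series

    def __post_init__(self) -> None:
        # ties are broken by fixed subtype order; argmax equality must hold
        vals = self.correlations.to_numpy()
        assigned_vals = np.array(
            [self.correlations.at[s, a] for s, a in self.assigned.items()]
        )
        if np.abs(vals.max(axis=1) - assigned_vals).max() > 1e-12:
            raise ImmstratError("assigned subtype is not the argmax correlation")


def marker_score(matrix: ExpressionMatrix, markers: GenePanel) -> MarkerScore:
    """Mean expression of the found marker genes, per sample."""
    found = [g for g in matrix.genes if g in markers.genes]
    missing = sorted(markers.genes - set(found))
    if not found:
        raise ImmstratError(f"no markers from panel {markers.name!r} found in matrix")
    scores = matrix.data.loc[found].mean(axis=0)
    scores.name = markers.name
    return MarkerScore(scores=scores, markers_used=found, missing=missing)


def _em_gaussian2(x: np.ndarray, tol: float, max_iter: int, init_means=None):
    """One EM run for a 1-D two-component Gaussian mixture.

    Deterministic start unless ``init_means`` is given: means at the
    25th/75th percentiles, pooled sd, equal weights.  Returns
    (params, loglik_trace) or raises on variance collapse.
    """
    if init_means is None:
        m = np.percentile(x, [25.0, 75.0]).astype(float)
    else:
        m = np.asarray(init_means, dtype=float)
    if m[0] == m[1]:
        m = m + np.array([-1e-3, 1e-3])
    s = np.array([x.std(), x.std()])
    if s[0] < 1e-8:
        raise _VarianceCollapse()
    w = 0.5
    trace: list[float] = []
    for _ in range(max_iter):
        p0 = (1 - w) * stats.norm.pdf(x, m[0], s[0])
        p1 = w * stats.norm.pdf(x, m[1], s[1])
        total = p0 + p1
        total = np.where(total <= 0, 1e-300, total)
        ll = float(np.log(total).sum())
        trace.append(ll)
        r = p1 / total
        w = float(r.mean())
        if w <= 0 or w >= 1:
            raise _VarianceCollapse()
        m = np.array(
            [np.average(x, weights=(1 - r)), np.average(x, weights=r)]
        )
        s = np.sqrt(
            np.array(
                [
                    np.average((x - m[0]) ** 2, weights=(1 - r)),
                    np.average((x - m[1]) ** 2, weights=r),
                ]
            )
        )
        if (s**2 < 1e-6).any():
            raise _VarianceCollapse()
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            return (m, s, w), trace
    raise ImmstratError(
        f"EM did not converge in {max_iter} iterations (last loglik {trace[-1]:.4f})"
    )


class _VarianceCollapse(Exception):
    pass


def infer_er_status(
    values: pd.Series, tol: float = 1e-8, max_iter: int = 500, seed: int = 0
) -> ErCall:
    """Infer binary ER status from one gene's expression by a 2-Gaussian EM.

    The component with the higher fitted mean is ER-positive; a sample is
    labeled 'pos' when its posterior for that component exceeds 0.5.  On
    variance collapse the fit restarts from a random initialization, up to
    5 times.
    """
    if len(values) < 10:
        raise ImmstratError("ER inference needs at least 10 samples")
    x = values.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for attempt in range(6):
        try:
            if attempt == 0:
                (m, s, w), trace = _em_gaussian2(x, tol, max_iter)
            else:
                init = rng.choice(x, size=2, replace=False)
                (m, s, w), trace = _em_gaussian2(x, tol, max_iter, init_means=init)
            break
        except _VarianceCollapse as err:
            last_err = err
    else:
        raise ImmstratError("EM variance collapsed in all restarts") from last_err
    # orient: component 1 = higher mean = ER-positive
    if m[1] < m[0]:
        m = m[::-1]
        s = s[::-1]
        w = 1.0 - w
    p_neg = (1 - w) * stats.norm.pdf(x, m[0], s[0])
    p_pos = w * stats.norm.pdf(x, m[1], s[1])
    posterior = p_pos / np.where(p_neg + p_pos <= 0, 1e-300, p_neg + p_pos)
    labels = pd.Series(
        np.where(posterior > 0.5, "pos", "neg"), index=values.index, name="er_call"
    )
    return ErCall(
        labels=labels,
        posterior=pd.Series(posterior, index=values.index, name="er_posterior"),
        means=(float(m[0]), float(m[1])),
        sds=(float(s[0]), float(s[1])),
        weight=float(w),
        loglik_trace=trace,
    )


def assign_pam50(
    matrix: ExpressionMatrix, centroids: pd.DataFrame, method: str = "spearman"
) -> SubtypeCorrelations:
    """Correlate each sample to the five PAM50 centroids and assign argmax.

    ``centroids`` is a 50-gene x 5-subtype table (columns basal, her2,
    luma, lumb, normal).  Spearman correlation by default; ties in the
    argmax are broken by the fixed subtype order.
    """
    cols = [c.lower() for c in centroids.columns]
    if sorted(cols) != sorted(SUBTYPE_ORDER):
        raise ImmstratError(f"centroid columns must be {SUBTYPE_ORDER}")
    centroids = centroids.copy()
    centroids.columns = cols
    centroids = centroids[SUBTYPE_ORDER]
    shared = [g for g in centroids.index if g in set(matrix.genes)]
    if len(shared) < 10:
        raise ImmstratError(f"only {len(shared)} centroid genes found; need >= 10")
    sub = matrix.data.loc[shared]
    cen = centroids.loc[shared].to_numpy()
    if method == "spearman":
        x = stats.rankdata(sub.to_numpy(), axis=0)
        c = stats.rankdata(cen, axis=0)
    elif method == "pearson":
        x, c = sub.to_numpy(), cen
    else:
        raise ImmstratError(f"unknown correlation method {method!r}")
    xz = (x - x.mean(axis=0)) / x.std(axis=0)
    cz = (c - c.mean(axis=0)) / c.std(axis=0)
    corr = (xz.T @ cz) / x.shape[0]
    corr_df = pd.DataFrame(corr, index=matrix.samples, columns=SUBTYPE_ORDER)
    assigned = corr_df.idxmax(axis=1)  # first max in fixed column order
    assigned.name = "subtype"
    return SubtypeCorrelations(correlations=corr_df, assigned=assigned)


def ror_score(corr: SubtypeCorrelations) -> pd.Series:
    """Risk-of-recurrence score from the four tumor-centroid correlations."""
    c = corr.correlations
    score = sum(w * c[name] for name, w in ROR_WEIGHTS.items())
    score.name = "ror"
    return score
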