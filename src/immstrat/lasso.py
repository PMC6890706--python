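"""L1-penalized binomial classifier and the single-sample cluster index.

The single-sample predictor is a lasso-penalized logistic regression
trained on mean-centered expression to separate the poor-prognosis
cluster (B) from the rest.  At prediction time only the linear index

    Index_i = sum_g beta_g * X_gi

is needed: a sample is called Cluster B when its index exceeds the
published intercept threshold.  The model intercept beta_0 is folded into
that threshold (threshold = -beta_0), so Index_i > threshold is exactly
beta_0 + sum_g beta_g X_gi > 0.

The solver minimizes

    (1/n) * sum_i [log(1 + exp(eta_i)) - y_i eta_i] + lambda * ||beta||_1

by iteratively reweighted least squares with cyclic coordinate descent
(soft-thresholding, active-set sweeps, warm starts along a decreasing
lambda path), with lambda chosen by stratified cross-validated binomial
deviance (minimum-deviance rule).  The analytic zero-solution boundary is
lambda_max = max_g |<x_g, y - ybar>| / n, and the returned solution is
checked against the Karush-Kuhn-Tucker conditions of the objective.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cluster import ClusterAssignment
from .io import ExpressionMatrix, ImmstratError

__all__ = [
    "SignatureWeights",
    "IndexScore",
    "fit_l1_logistic",
    "index_score",
    "predict_three_clusters",
    "roc_auc",
    "lambda_max",
    "kkt_residual",
]

logger = logging.getLogger(__name__)


@dataclass
class SignatureWeights:
    """Nonzero lasso coefficients plus the decision threshold.

    ``intercept`` follows the published index convention: a sample is in
    the positive class when sum_g beta_g X_gi exceeds it (strictly).
    """

    coefficients: pd.Series
    intercept: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.intercept):
            raise ImmstratError("intercept must be finite")

    @property
    def n_targets(self) -> int:
        return int((self.coefficients != 0.0).sum())

    def to_files(self, tsv_path: str, json_path: str | None = None) -> None:
        df = pd.DataFrame(
            {"gene": self.coefficients.index, "coefficient": self.coefficients.to_numpy()}
        )
        df.to_csv(tsv_path, sep="\t", index=False)
        if json_path is None:
            json_path = os.path.splitext(tsv_path)[0] + ".json"
        with open(json_path, "w") as fh:
            json.dump({"intercept": self.intercept, **self.meta}, fh, indent=2, default=str)

    @classmethod
    def from_files(cls, tsv_path: str, json_path: str | None = None) -> "SignatureWeights":
        df = pd.read_csv(tsv_path, sep="\t")
        gene_col, coef_col = df.columns[0], df.columns[1]
        coef = pd.Series(df[coef_col].to_numpy(dtype=float), index=df[gene_col].astype(str))
        if json_path is None:
            json_path = os.path.splitext(tsv_path)[0] + ".json"
        with open(json_path) as fh:
            meta = json.load(fh)
        intercept = float(meta.pop("intercept"))
        return cls(coefficients=coef, intercept=intercept, meta=meta)


@dataclass
class IndexScore:
    index: pd.Series
    is_positive: pd.Series  # True where index > intercept

    @property
    def is_cluster_b(self) -> pd.Series:
        return self.is_positive


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda at which all penalized coefficients are zero."""
    n = X.shape[0]
    return float(np.abs(X.T @ (y - y.mean())).max() / n)


def _soft(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def kkt_residual(X: np.ndarray, y: np.ndarray, beta0: float, beta: np.ndarray, lam: float) -> float:
    """Max violation of the stationarity conditions at (beta0, beta)."""
    p = expit(beta0 + X @ beta)
    grad = X.T @ (p - y) / X.shape[0]
    res = abs(float(np.mean(p - y)))
    nz = beta != 0
    if nz.any():
        res = max(res, float(np.abs(grad[nz] + lam * np.sign(beta[nz])).max()))
    if (~nz).any():
        res = max(res, float(np.maximum(np.abs(grad[~nz]) - lam, 0.0).max()))
    return res


def _fit_at_lambda(X, y, lam, beta0, beta, candidates=None, max_outer=100, kkt_tol=1e-6):
    """IRLS + coordinate descent at one lambda, warm-started in place.

    ``candidates`` restricts coordinate updates to a screened index set
    (strong rule); the caller is responsible for checking full KKT and
    re-entering with an enlarged set if the screen was too aggressive.
    """
    n, p = X.shape
    cols = np.ascontiguousarray(X.T)
    idx = np.arange(p) if candidates is None else np.flatnonzero(candidates)
    for _ in range(max_outer):
        eta = beta0 + X @ beta
        prob = expit(eta)
        w = np.clip(prob * (1.0 - prob), 1e-5, None)
        z = eta + (y - prob) / w
        wx2 = (w[None, :] * cols[idx] ** 2).mean(axis=1)
        r = z - eta
        # inner weighted-lasso CD: one full sweep, then active-set sweeps
        for sweep in range(200):
            active_only = sweep % 10 != 0 and sweep > 0
            max_delta = 0.0
            for jj, j in enumerate(idx):
                if active_only and beta[j] == 0.0:
                    continue
                xj = cols[j]
                bj = beta[j]
                rho = float((w * xj * r).mean()) + wx2[jj] * bj
                new = _soft(rho, lam) / wx2[jj]
                if new != bj:
                    r += xj * (bj - new)
                    beta[j] = new
                    max_delta = max(max_delta, abs(new - bj) * np.sqrt(wx2[jj]))
            shift = float((w * r).mean() / w.mean())
            if shift != 0.0:
                beta0 += shift
                r -= shift
                max_delta = max(max_delta, abs(shift))
            if max_delta < 1e-10:
                break
        grad = cols[idx] @ (expit(beta0 + X @ beta) - y) / n
        res = abs(float(np.mean(expit(beta0 + X @ beta) - y)))
        nz = beta[idx] != 0
        if nz.any():
            res = max(res, float(np.abs(grad[nz] + lam * np.sign(beta[idx][nz])).max()))
        if (~nz).any():
            res = max(res, float(np.maximum(np.abs(grad[~nz]) - lam, 0.0).max()))
        if res < kkt_tol:
            break
    return beta0, beta


def _path_fit(X, y, path, kkt_tol=1e-6):
    """Warm-started solutions along a decreasing lambda path.

    Uses the sequential strong rule |grad_j| >= 2*lam_k - lam_{k-1} to
    screen candidates, then verifies full KKT and re-solves with any
    violators added.  Yields (lam, beta0, beta) per path point.
    """
    n, p = X.shape
    beta = np.zeros(p)
    beta0 = float(np.log(y.mean() / (1.0 - y.mean())))
    prev_lam = float(path[0])
    for lam in path:
        grad = X.T @ (expit(beta0 + X @ beta) - y) / n
        candidates = (np.abs(grad) >= 2.0 * lam - prev_lam - 1e-12) | (beta != 0.0)
        while True:
            beta0, beta = _fit_at_lambda(
                X, y, lam, beta0, beta, candidates=candidates, kkt_tol=kkt_tol
            )
            grad = X.T @ (expit(beta0 + X @ beta) - y) / n
            violators = (np.abs(grad) > lam + kkt_tol) & ~candidates
            if violators.any():
                candidates |= violators
            else:
                break
        prev_lam = float(lam)
        yield float(lam), beta0, beta


def _lambda_path(lmax: float, n_lambda: int, ratio: float) -> np.ndarray:
    return np.exp(np.linspace(np.log(lmax), np.log(lmax * ratio), n_lambda))


def _deviance(X, y, beta0, beta) -> float:
    eta = beta0 + X @ beta
    # -2 * loglik, numerically stable via logaddexp
    return float(2.0 * (np.logaddexp(0.0, eta) - y * eta).sum())


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    fold = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def fit_l1_logistic(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    n_folds: int = 5,
    seed: int = 0,
    n_lambda: int = 30,
    lambda_min_ratio: float | None = None,
    centering_tol: float = 1e-6,
) -> SignatureWeights:
    """Train the lasso-penalized binomial model on a mean-centered matrix.

    ``labels`` is boolean per sample (True = positive class, e.g. Cluster
    B).  lambda is chosen on a log-spaced path below the analytic
    lambda_max by ``n_folds``-fold stratified cross-validated binomial
    deviance (minimum rule), then the model is refit on all samples.
    """
    y = labels.loc[matrix.samples].astype(bool).to_numpy().astype(float)
    if y.min() == y.max():
        raise ImmstratError("both classes must be present to train the classifier")
    row_means = matrix.data.mean(axis=1).abs()
    if row_means.max() > centering_tol:
        raise ImmstratError(
            f"matrix is not mean-centered (max |gene mean| = {row_means.max():.3g}); "
            "apply mean_center first"
        )
    X = np.ascontiguousarray(matrix.values.T)  # samples x genes
    n, p = X.shape
    lmax = lambda_max(X, y)
    if lambda_min_ratio is None:
        lambda_min_ratio = 1e-4 if n > p else 1e-3
    path = _lambda_path(lmax * 0.999, n_lambda, lambda_min_ratio)

    rng = np.random.default_rng(seed)
    fold = _stratified_folds(y, n_folds, rng)
    cv_dev = np.zeros(len(path))
    for f in range(n_folds):
        tr, te = fold != f, fold == f
        for li, (_, beta0, beta) in enumerate(_path_fit(X[tr], y[tr], path, kkt_tol=1e-5)):
            cv_dev[li] += _deviance(X[te], y[te], beta0, beta)
    cv_dev /= n
    best = int(np.argmin(cv_dev))

    solutions = []
    for lam, beta0, beta in _path_fit(X, y, path, kkt_tol=1e-6):
        solutions.append((lam, beta0, beta.copy()))
        if len(solutions) == len(path):
            break
    chosen = best
    _, final_b0, final_b = solutions[best]
    if not np.any(final_b != 0.0):
        logger.warning("no lambda on the path kept nonzero coefficients; returning densest model")
        for li in range(len(solutions)):
            if np.any(solutions[li][2] != 0.0) or li == len(solutions) - 1:
                chosen = li
                _, final_b0, final_b = solutions[li]
                break

    coef = pd.Series(final_b, index=matrix.genes)
    coef = coef[coef != 0.0]
    return SignatureWeights(
        coefficients=coef,
        intercept=-final_b0,
        meta={
            "lambda": float(path[chosen]),
            "lambda_max": lmax,
            "cv_deviance": cv_dev.tolist(),
            "lambda_path": path.tolist(),
            "n_folds": n_folds,
            "seed": seed,
            "n_samples": n,
            "kkt_residual": kkt_residual(X, y, final_b0, final_b, float(path[chosen])),
        },
    )


def index_score(matrix: ExpressionMatrix, weights: SignatureWeights) -> IndexScore:
    """Apply the linear index to every sample and threshold it.

    Weight genes absent from the matrix contribute zero (warned); if none
    of the weight genes are present the index is undefined and an error is
    raised.
    """
    found = [g for g in weights.coefficients.index if g in set(matrix.genes)]
    if not found:
        raise ImmstratError("no weight genes present in the expression matrix")
    missing = [g for g in weights.coefficients.index if g not in set(matrix.genes)]
    if missing:
        logger.warning("%d weight genes missing from matrix; treated as zero", len(missing))
    beta = weights.coefficients.loc[found].to_numpy()
    idx = pd.Series(beta @ matrix.data.loc[found].to_numpy(), index=matrix.samples, name="index")
    return IndexScore(index=idx, is_positive=idx > weights.intercept)


def predict_three_clusters(
    matrix: ExpressionMatrix,
    model_b: SignatureWeights,
    model_ac: SignatureWeights,
    ac_positive: str = "C",
) -> ClusterAssignment:
    """Two-stage single-sample assignment: B first, then A vs C.

    Samples above ``model_b``'s threshold are Cluster B regardless of the
    second model; the rest are split by ``model_ac``'s index rule, whose
    positive side is labeled ``ac_positive``.
    """
    stage1 = index_score(matrix, model_b)
    stage2 = index_score(matrix, model_ac)
    neg = "A" if ac_positive == "C" else "C"
    labels = pd.Series(
        np.where(stage1.is_positive, "B", np.where(stage2.is_positive, ac_positive, neg)),
        index=matrix.samples,
        name="cluster",
    )
    return ClusterAssignment(labels=labels, k=int(labels.nunique()), source="predicted")


def roc_auc(scores: pd.Series, labels: pd.Series) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores contribute 1/2."""
    y = labels.loc[scores.index].astype(bool).to_numpy()
    if y.all() or not y.any():
        raise ImmstratError("AUC needs both classes")
    from scipy.stats import rankdata

    r = rankdata(scores.to_numpy())
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))
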