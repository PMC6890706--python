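"""Survival association: Kaplan-Meier, log-rank, Cox, AIC backward selection.

Estimation is delegated to lifelines (Kaplan-Meier product-limit, Cox
partial likelihood with Efron tie handling) and scipy (chi-square); this
module defines the pipeline-facing contracts: input validation, the AIC
convention (2 * n_parameters - 2 * log partial likelihood, no intercept),
the backward-selection rule (drop the covariate with the weakest Wald p,
accept only if the AIC does not increase), and a null-Cox score statistic
used as a cross-check against the log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .io import ImmstratError

__all__ = [
    "SurvivalData",
    "CoxModel",
    "kaplan_meier",
    "logrank_test",
    "cox_fit",
    "aic_backward_select",
    "chisq_association",
    "cox_null_score_statistic",
]

logger = logging.getLogger(__name__)


@dataclass
class SurvivalData:
    """Right-censored times with optional covariates.

    ``table`` must contain columns ``time`` (positive) and ``event``
    (0/1); any further columns are covariates.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not {"time", "event"} <= set(self.table.columns):
            raise ImmstratError("survival table needs 'time' and 'event' columns")
        if (self.table["time"].to_numpy(dtype=float) <= 0).any():
            raise ImmstratError("survival times must be positive")
        ev = set(pd.unique(self.table["event"]))
        if not ev <= {0, 1}:
            raise ImmstratError(f"event must be 0/1, got {sorted(ev)[:5]}")

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("time", "event")]


@dataclass
class CoxModel:
    """Fitted Cox proportional-hazards summary.

    ``summary`` has one row per covariate: coef (log HR), hr, ci_lo,
    ci_hi (HR scale), se, p.  AIC = 2 * n_covariates - 2 * log partial
    likelihood (the partial likelihood has no intercept).
    """

    summary: pd.DataFrame
    log_likelihood: float
    aic: float
    n_events: int

    def __post_init__(self) -> None:
        expected = 2.0 * len(self.summary) - 2.0 * self.log_likelihood
        if abs(self.aic - expected) > 1e-6:
            raise ImmstratError("AIC inconsistent with log partial likelihood")
        s = self.summary
        if len(s) and (((s["hr"] < s["ci_lo"]) | (s["hr"] > s["ci_hi"])).any()):
            raise ImmstratError("hazard-ratio CI does not contain the estimate")


def kaplan_meier(data: SurvivalData, groups: pd.Series) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per group.

    Returns, per group label, a table (time, survival, at_risk) — a
    right-continuous non-increasing step function starting at 1.
    """
    t = data.table
    out = {}
    for label, members in groups.groupby(groups).groups.items():
        sub = t.loc[members]
        if len(sub) == 0:
            continue
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"])
        ev = km.event_table
        curve = pd.DataFrame(
            {
                "time": km.survival_function_.index.to_numpy(),
                "survival": km.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": ev["at_risk"].reindex(km.survival_function_.index).to_numpy(),
            }
        )
        out[str(label)] = curve
    return out


def logrank_test(data: SurvivalData, groups: pd.Series) -> tuple[float, int, float]:
    """Log-rank test across >= 2 groups: (chi-square, df, p)."""
    g = groups.loc[data.table.index]
    if g.nunique() < 2:
        raise ImmstratError("log-rank test needs at least 2 groups")
    if int(data.table["event"].sum()) < 1:
        raise ImmstratError("log-rank test needs at least one event")
    res = multivariate_logrank_test(
        data.table["time"], g, data.table["event"]
    )
    return float(res.test_statistic), int(g.nunique() - 1), float(res.p_value)


def cox_fit(
    data: SurvivalData,
    covariates: list[str] | None = None,
    ties: str = "efron",
) -> CoxModel:
    """Cox proportional-hazards fit by partial-likelihood maximization.

    Categorical covariates are expanded to treatment-coded dummies.
    Efron tie handling by default; ``ties='breslow'`` selectable.
    """
    if covariates is None:
        covariates = data.covariates
    if not covariates:
        raise ImmstratError("no covariates to fit")
    if int(data.table["event"].sum()) < 1:
        raise ImmstratError("Cox fit needs at least one event")
    df = data.table[["time", "event", *covariates]].copy()
    df = pd.get_dummies(df, columns=[c for c in covariates if not pd.api.types.is_numeric_dtype(df[c])], drop_first=True)
    df = df.astype(float)
    X = df.drop(columns=["time", "event"]).to_numpy(dtype=float)
    if X.shape[1] and np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ImmstratError("collinear covariates in Cox model")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as err:  # lifelines raises ConvergenceError and warnings
        raise ImmstratError(f"Cox fit failed: {err}") from err
    coefs = cph.params_
    if np.abs(coefs.to_numpy()).max() > 20:
        logger.warning("very large Cox coefficient; possible monotone likelihood")
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lo": s["exp(coef) lower 95%"],
            "ci_hi": s["exp(coef) upper 95%"],
            "se": s["se(coef)"],
            "p": s["p"],
        }
    )
    ll = float(cph.log_likelihood_)
    return CoxModel(
        summary=summary,
        log_likelihood=ll,
        aic=2.0 * len(summary) - 2.0 * ll,
        n_events=int(data.table["event"].sum()),
    )


def aic_backward_select(
    data: SurvivalData, covariates: list[str] | None = None
) -> tuple[list[str], CoxModel, pd.DataFrame]:
    """Backward selection: drop the weakest covariate while AIC allows.

    At each step the covariate with the largest Wald p in the current fit
    is tentatively removed; the removal is accepted only if the AIC of the
    reduced model does not exceed the current AIC.  Returns the retained
    covariates, the final model and the removal trace.
    """
    if covariates is None:
        covariates = data.covariates
    current = list(covariates)
    model = cox_fit(data, current)
    trace_rows = [{"step": 0, "action": "full", "covariate": None, "aic": model.aic}]
    step = 0
    while len(current) > 1:
        # weakest original covariate = the one whose dummy terms have the
        # largest minimum Wald significance
        worst, worst_p = None, -np.inf
        for cov in current:
            terms = [t for t in model.summary.index if t == cov or str(t).startswith(f"{cov}_")]
            p = float(model.summary.loc[terms, "p"].min()) if terms else 1.0
            if p > worst_p:
                worst, worst_p = cov, p
        reduced = [c for c in current if c != worst]
        candidate = cox_fit(data, reduced)
        step += 1
        if candidate.aic <= model.aic:
            current, model = reduced, candidate
            trace_rows.append(
                {"step": step, "action": "dropped", "covariate": worst, "aic": candidate.aic}
            )
        else:
            trace_rows.append(
                {"step": step, "action": "kept (AIC would rise)", "covariate": worst, "aic": model.aic}
            )
            break
    return current, model, pd.DataFrame(trace_rows)


def chisq_association(table: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on a 2-way count table (no continuity correction)."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ImmstratError("degenerate contingency table (zero margin)")
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(dof), float(p)


def cox_null_score_statistic(data: SurvivalData, group_indicator: pd.Series) -> float:
    """Squared score of a null Cox fit on a binary group indicator.

    U(0)^2 / I(0) with Breslow risk sets; without tied event times this
    equals the two-group log-rank chi-square, which the tests use as a
    cross-module consistency check.
    """
    x = group_indicator.loc[data.table.index].to_numpy(dtype=float)
    t = data.table["time"].to_numpy(dtype=float)
    e = data.table["event"].to_numpy(dtype=int)
    order = np.argsort(t)
    t, e, x = t[order], e[order], x[order]
    u = 0.0
    info = 0.0
    for i in np.where(e == 1)[0]:
        risk = t >= t[i]
        xr = x[risk]
        xbar = xr.mean()
        u += x[i] - xbar
        info += ((xr - xbar) ** 2).mean()
    if info <= 0:
        raise ImmstratError("zero information; group indicator constant in risk sets")
    return float(u**2 / info)
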