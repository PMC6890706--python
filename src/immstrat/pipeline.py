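"""End-to-end orchestration of discovery and single-sample prediction.

``run_discovery`` executes the full analysis in fixed order — correlation
clustering, infiltration scoring, cluster naming, classifier training,
microenvironment dissection, phenotype analysis, survival association —
writing each stage's result as plain TSV/JSON into the output directory
plus a reproducibility manifest (parameters, seeds, input checksums,
package version).  Partial outputs are preserved when a stage fails, and
the failing stage is named in the error.

``run_predict`` applies trained weight files to any expression matrix,
including a single-sample one, without re-clustering.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import platform
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (
    hierarchical_clusters,
    order_clusters_by_infiltration,
    sample_correlation_matrix,
    select_k_silhouette,
)
from .io import (
    ExpressionMatrix,
    GenePanel,
    GeneSetCollection,
    ImmstratError,
    intersect_panel,
    mean_center,
)
from .lasso import SignatureWeights, fit_l1_logistic, index_score, predict_three_clusters, roc_auc
from .microenv import (
    celltype_median_map,
    correlate_scores_proportions,
    deconvolve,
    geneset_score,
    logistic_explainers,
)
from .phenotype import differential_genes_b, hypergeometric_enrichment, subcluster_b
from .scores import assign_pam50, infer_er_status, marker_score, ror_score
from .simulate import CellTypeSignatureMatrix, SyntheticCohort
from .survival import SurvivalData, aic_backward_select, chisq_association, kaplan_meier, logrank_test

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Stage parameters for the discovery pipeline."""

    k: int = 3
    k_range: tuple[int, int] = (3, 10)
    linkage: str = "ward_d"
    distance: str = "correlation"
    n_restarts: int = 25
    run_silhouette: bool = True
    n_folds: int = 5
    n_lambda: int = 30
    de_alpha: float = 1e-4
    fdr_level: float = 0.05
    emt_set: str = "emt_program"
    er_gene: str = "ESR1"
    run_survival: bool = True
    run_deconvolution: bool = True
    seed: int = 0


@dataclass
class DiscoveryResult:
    assignment: Any
    predicted: Any
    weights_b: SignatureWeights
    weights_ac: SignatureWeights
    outputs: dict[str, str] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _StageRunner:
    def __init__(self, out_dir: str):
        self.out_dir = out_dir
        self.outputs: dict[str, str] = {}

    def write(self, name: str, df: pd.DataFrame, index_label: str = "sample") -> str:
        path = os.path.join(self.out_dir, name)
        df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")
        self.outputs[name] = path
        return path

    def write_json(self, name: str, obj: dict) -> str:
        path = os.path.join(self.out_dir, name)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, default=str, sort_keys=True)
        self.outputs[name] = path
        return path


def run_discovery(
    cohort: SyntheticCohort | dict,
    out_dir: str,
    params: PipelineParams | None = None,
    clinical: pd.DataFrame | None = None,
    input_paths: dict[str, str] | None = None,
) -> DiscoveryResult:
    """Run the full discovery workflow on a cohort bundle.

    ``cohort`` is a :class:`SyntheticCohort` or a dict with the same field
    names (expression, panel, lymphoid_markers, myeloid_markers,
    signature, gene_sets, centroids).  ``clinical`` (sample, time, event,
    optional pcr/covariates) defaults to the synthetic truth table when
    available.
    """
    params = params or PipelineParams()
    os.makedirs(out_dir, exist_ok=True)
    runner = _StageRunner(out_dir)
    if isinstance(cohort, dict):
        cohort = SyntheticCohort(**{**dict.fromkeys(
            ("expression", "truth", "signature", "panel", "gene_sets", "centroids"), None
        ), **cohort})

    stage = "setup"
    try:
        expr: ExpressionMatrix = cohort.expression
        panel: GenePanel = cohort.panel
        if clinical is None and cohort.truth is not None:
            clinical = cohort.truth.table

        stage = "clustering"
        panel_expr, missing = intersect_panel(expr, panel)
        logger.info("clustering: %d panel genes (%d missing), %d samples",
                    panel_expr.shape[0], len(missing), panel_expr.shape[1])
        corr = sample_correlation_matrix(panel_expr)
        if params.run_silhouette:
            lo, hi = params.k_range
            k_best, widths = select_k_silhouette(
                corr, range(lo, hi + 1), n_restarts=params.n_restarts, seed=params.seed
            )
            runner.write("silhouette.tsv", widths.to_frame(), index_label="k")
        else:
            k_best = params.k
        raw_assignment = hierarchical_clusters(
            corr, k=params.k, linkage_method=params.linkage, distance=params.distance
        )

        stage = "infiltration_scores"
        lymphoid = marker_score(expr, cohort.lymphoid_markers)
        myeloid = marker_score(expr, cohort.myeloid_markers)
        er = infer_er_status(expr.data.loc[params.er_gene], seed=params.seed) \
            if params.er_gene in set(expr.genes) else None
        pam = assign_pam50(expr, cohort.centroids) if cohort.centroids is not None else None
        score_table = pd.DataFrame(
            {"lymphoid": lymphoid.scores, "myeloid": myeloid.scores}
        )
        if er is not None:
            score_table["er_call"] = er.labels
            score_table["er_posterior"] = er.posterior
        if pam is not None:
            score_table["subtype"] = pam.assigned
            score_table["ror"] = ror_score(pam)
        runner.write("sample_scores.tsv", score_table)

        stage = "cluster_naming"
        assignment = order_clusters_by_infiltration(raw_assignment, lymphoid.scores)
        runner.write("cluster_labels.tsv", assignment.labels.to_frame())

        stage = "classifier_training"
        centered = mean_center(panel_expr)
        is_b = assignment.labels == "B"
        weights_b = fit_l1_logistic(
            centered, is_b, n_folds=params.n_folds, seed=params.seed, n_lambda=params.n_lambda
        )
        ac_samples = assignment.labels.index[~is_b]
        weights_ac = fit_l1_logistic(
            mean_center(panel_expr.subset_samples(ac_samples)),
            (assignment.labels.loc[ac_samples] == "C"),
            n_folds=params.n_folds,
            seed=params.seed + 1,
            n_lambda=params.n_lambda,
        )
        weights_b.to_files(os.path.join(out_dir, "weights_b.tsv"))
        weights_ac.to_files(os.path.join(out_dir, "weights_ac.tsv"))
        runner.outputs["weights_b.tsv"] = os.path.join(out_dir, "weights_b.tsv")
        runner.outputs["weights_ac.tsv"] = os.path.join(out_dir, "weights_ac.tsv")
        predicted = predict_three_clusters(centered, weights_b, weights_ac)
        runner.write("predicted_labels.tsv", predicted.labels.to_frame())
        auc_b = roc_auc(index_score(centered, weights_b).index, is_b)

        stage = "dissection"
        proportions = None
        if params.run_deconvolution and cohort.signature is not None:
            proportions = deconvolve(expr, cohort.signature)
            runner.write("celltype_absolute.tsv", proportions.absolute)
            runner.write("celltype_relative.tsv", proportions.relative)
            median_map, _, _ = celltype_median_map(proportions, predicted)
            runner.write("celltype_median_map.tsv", median_map, index_label="stratum")
            is_b_pred = predicted.labels == "B"
            if is_b_pred.nunique() == 2:
                explainers = logistic_explainers(
                    proportions.absolute, is_b_pred, mode="multivariable"
                )
                runner.write("celltype_explainers.tsv",
                             explainers.table.set_index("feature"), index_label="feature")
            else:
                logger.warning("predicted labels contain a single B class; explainers skipped")

        stage = "phenotype"
        sets: GeneSetCollection = cohort.gene_sets
        counts = predicted.labels.value_counts()
        if all(counts.get(c, 0) >= 3 for c in "ABC"):
            de = differential_genes_b(expr, predicted, alpha=params.de_alpha)
            runner.write("differential_expression.tsv", de.table, index_label="gene")
            if de.up_in_b():
                enrichment = hypergeometric_enrichment(de.up_in_b(), sets, list(expr.genes))
                runner.write("enrichment.tsv", enrichment.table, index_label="set")
        else:
            logger.warning("a predicted cluster has <3 samples; differential stage skipped")
        gs_scores = geneset_score(expr, sets)
        runner.write("geneset_scores.tsv", gs_scores.scores)
        if (predicted.labels == "B").nunique() == 2:
            univariate = logistic_explainers(
                gs_scores.scores, predicted.labels == "B", mode="univariate"
            )
            runner.write("geneset_explainers.tsv", univariate.table.set_index("feature"),
                         index_label="feature")
        b_samples = predicted.labels.index[predicted.labels == "B"]
        sub = None
        if len(b_samples) >= 4:
            from .microenv import GeneSetScores

            sub = subcluster_b(
                GeneSetScores(scores=gs_scores.scores.loc[b_samples]),
                emt_set=params.emt_set,
            )
            runner.write("b_subclusters.tsv", sub.labels.to_frame())
        if proportions is not None:
            rho, fdr, mask = correlate_scores_proportions(
                gs_scores, proportions, fdr_level=params.fdr_level
            )
            runner.write("score_proportion_rho.tsv", rho, index_label="set")
            runner.write("score_proportion_fdr.tsv", fdr, index_label="set")

        stage = "survival"
        if params.run_survival and clinical is not None and "time" in clinical.columns:
            surv = SurvivalData(table=clinical[["time", "event"]].copy())
            km = kaplan_meier(surv, predicted.labels)
            for lab, curve in km.items():
                runner.write(f"km_cluster_{lab}.tsv", curve, index_label="row")
            stat, df_, p = logrank_test(surv, predicted.labels)
            cox_table = clinical[["time", "event"]].copy()
            cox_table["cluster_b"] = (predicted.labels == "B").astype(float)
            model = None
            try:
                from .survival import cox_fit

                model = cox_fit(SurvivalData(table=cox_table))
                runner.write("cox_summary.tsv", model.summary, index_label="covariate")
            except ImmstratError as err:
                logger.warning("Cox stage skipped: %s", err)
            surv_json = {"logrank_statistic": stat, "logrank_df": df_, "logrank_p": p}
            if "pcr" in clinical.columns:
                counts = pd.crosstab(predicted.labels, clinical["pcr"])
                if counts.shape == (counts.shape[0], 2) and (counts.to_numpy().sum(axis=0) > 0).all():
                    c_stat, c_df, c_p = chisq_association(counts)
                    surv_json.update({"pcr_chisq": c_stat, "pcr_df": c_df, "pcr_p": c_p})
                    runner.write("pcr_by_cluster.tsv", counts, index_label="cluster")
            runner.write_json("survival_tests.json", surv_json)

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "python": platform.python_version(),
            "params": asdict(params),
            "stage1_auc_training": auc_b,
            "n_samples": expr.shape[1],
            "n_genes": expr.shape[0],
            "outputs": sorted(runner.outputs),
            "input_checksums": {
                k: _sha256(v) for k, v in (input_paths or {}).items() if os.path.exists(v)
            },
        }
        runner.write_json("manifest.json", manifest)
    except ImmstratError as err:
        raise ImmstratError(f"stage {stage!r} failed: {err}") from err

    return DiscoveryResult(
        assignment=assignment,
        predicted=predicted,
        weights_b=weights_b,
        weights_ac=weights_ac,
        outputs=runner.outputs,
        manifest=manifest,
    )


def run_predict(
    matrix: ExpressionMatrix,
    weights_b: SignatureWeights,
    weights_ac: SignatureWeights,
    out_path: str | None = None,
) -> pd.DataFrame:
    """Assign A/B/C to every sample (single samples included) from weights.

    Returns a report with the two index values and the final label per
    sample; optionally writes it as TSV.
    """
    assignment = predict_three_clusters(matrix, weights_b, weights_ac)
    report = pd.DataFrame(
        {
            "index_b": index_score(matrix, weights_b).index,
            "index_ac": index_score(matrix, weights_ac).index,
            "cluster": assignment.labels,
        }
    )
    if out_path:
        report.to_csv(out_path, sep="\t", index_label="sample", float_format="%.10g")
    return report
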