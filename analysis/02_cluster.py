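"""Discover the immune clusters in the discovery cohort.

Correlation matrix over the immune panel, unsquared-Ward clustering,
silhouette scan for the number of clusters, and naming by ascending
median lymphoid score.  Reports agreement with the generator's truth.
"""

import os

import pandas as pd
from sklearn.metrics import adjusted_rand_score

import immstrat as im

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 11


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    cohort = im.generate_cohort(im.SyntheticConfig(seed=SEED))
    panel_expr, missing = im.intersect_panel(cohort.expression, cohort.panel)
    corr = im.sample_correlation_matrix(panel_expr)

    k_best, widths = im.select_k_silhouette(corr, range(3, 11), n_restarts=25, seed=0)
    widths.to_frame().to_csv(os.path.join(RESULTS, "02_silhouette.tsv"),
                             sep="\t", index_label="k", float_format="%.4f")
    print(f"silhouette scan: best k = {k_best}")
    print(widths.round(3).to_string())

    assignment = im.hierarchical_clusters(corr, k=3)
    lymphoid = im.marker_score(cohort.expression, cohort.lymphoid_markers).scores
    assignment = im.order_clusters_by_infiltration(assignment, lymphoid)
    assignment.labels.to_frame().to_csv(
        os.path.join(RESULTS, "02_cluster_labels.tsv"), sep="\t", index_label="sample")

    truth = cohort.truth.table["true_cluster"]
    ari = adjusted_rand_score(truth, assignment.labels.loc[truth.index])
    print(f"\ncluster sizes: {assignment.labels.value_counts().to_dict()}")
    print(f"adjusted Rand index vs generator truth: {ari:.3f}")
    print(pd.crosstab(assignment.labels.rename("assigned"), truth).to_string())


if __name__ == "__main__":
    main()
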