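# immstrat

Immune-cluster stratification of bulk breast-cancer transcriptomes.

Breast tumors differ sharply in how much, and what kind of, immune
infiltrate they carry, and that contexture carries prognostic and
treatment-response information that the intrinsic molecular subtypes do
not. `immstrat` implements, as a tested and reusable pipeline, a
stratification framework for bulk expression cohorts:

1. **Discovery clustering** — Pearson correlation between samples over an
   immune gene panel, hierarchical clustering of the correlation matrix
   (unsquared Ward linkage, correlation distance), silhouette-based
   selection of the number of clusters, and naming of the three clusters
   A/B/C by ascending median lymphoid infiltration. Cluster B — the
   intermediate-infiltration cluster with a pro-tumorigenic composition —
   is the poor-prognosis group.
2. **Single-sample classifier** — an L1-penalized binomial logistic model
   on mean-centered expression. At prediction time only the linear index

   `Index_i = Σ_g β_g · X_gi`

   is needed: a sample is called Cluster B when its index exceeds the
   trained intercept threshold, so the rule applies to one patient at a
   time without re-clustering. A second model splits A from C. The lasso
   path solver (IRLS + cyclic coordinate descent with strong-rule
   screening, cross-validated deviance for λ) is implemented in-house and
   cross-checked against glmnet in the test suite.
3. **Microenvironment dissection** — non-negative least-squares
   deconvolution of bulk profiles against a cell-type signature matrix,
   per-cluster median composition maps, and logistic models asking which
   cell types explain Cluster B (M2-like macrophages, resting mast-like
   and resting memory-T-like cells, in the synthetic ground truth).
4. **Phenotype analysis** — Welch t-tests with Bonferroni control for
   genes up in Cluster B, hypergeometric gene-set enrichment, mean-z
   single-sample gene-set scores, and the split of Cluster B into B1
   (EMT-like) and B2 (proliferative) sub-clusters.
5. **Survival and response** — Kaplan–Meier curves, log-rank tests, Cox
   proportional-hazards models with AIC-guided backward selection, and
   chi-square association between clusters and pathological complete
   response (pCR).

Because the cohorts this kind of analysis is usually run on are large and
partly controlled-access, the package ships a **synthetic cohort
generator** (`immstrat.simulate`) that emulates the statistical structure
the analysis assumes — three clusters with gradual immune infiltration,
linear-scale mixing of tumor and cell-type profiles, mutually exclusive
EMT and proliferation tumor programs, cluster-dependent survival hazards
and pCR rates — with full ground truth, so every stage is testable
end-to-end without any download. See `docs/methods.md` for the model and
its deliberate simplifications.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts and write their tables to `results/`. For example:

```
$ python analysis/02_cluster.py
silhouette scan: best k = 3
...
cluster sizes: {'A': 223, 'C': 216, 'B': 161}
adjusted Rand index vs generator truth: 0.977
```

The silhouette scan picks three clusters, and the full discovery chain
(correlation matrix → Ward → cut → infiltration ordering) recovers the
generator's clusters almost exactly (ARI 0.977; 5 of 600 samples
misassigned). Training the classifier and validating it on an
independently drawn cohort (`analysis/03_classify.py`) gives a stage-1
AUC of about 0.98 and a three-cluster ARI above 0.8. Downstream
(`analysis/04_dissect.py` – `06_survival.py`):

```
cell types explaining Cluster B (FDR < 0.05):
       mast_resting     0.999 ...
   t_memory_resting     0.765 ...
      macrophage_m2     0.590 ...

Cluster B split: B1 (EMT-like) fraction = 0.71, B2 = 0.29
EMT vs proliferation score correlation within B: rho = -0.46

AIC backward selection kept: ['cluster_b']
cluster_b  hr 1.876 (CI 1.521-2.312)
pCR responder rate per cluster (%): {'A': 11.7, 'B': 13.0, 'C': 35.7}
```

i.e. the pipeline re-discovers exactly what the generator planted: the
pro-tumorigenic cell types explain Cluster B, B splits into an EMT-like
majority and a proliferative minority with anti-correlated program
scores, cluster B carries roughly the configured 2-fold hazard, and the
high-infiltration cluster C has by far the highest chemotherapy response
rate.

A `immstrat` console command exposes each stage
(`simulate`, `cluster`, `score`, `train`, `predict`, `dissect`,
`phenotype`, `survival`, `run-discovery`) for file-based use; the
`run-discovery` subcommand executes everything and writes a
reproducibility manifest.

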