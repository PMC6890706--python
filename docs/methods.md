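# Methods

This note documents the models and procedures `immstrat` implements, the
synthetic data they are exercised on, the numerical choices, and the
limits of what the tests show.

## Discovery clustering

Samples are compared by the Pearson correlation of their log2 expression
vectors over the immune gene panel. The resulting sample × sample
correlation matrix is itself clustered: each sample's *row of
correlations* is its feature vector, and pairwise dissimilarity is
1 − Pearson correlation of those rows (correlation-of-correlation
profiles, the semantics of the common heatmap tools). The simpler
`d(i,j) = 1 − corr(i,j)` is available as `distance="direct"`.

Agglomeration follows the R `hclust` conventions. `ward_d` applies the
Lance–Williams Ward update to the raw dissimilarities; `ward_d2` to the
squared ones. scipy's `'ward'` implements the squared variant, so the raw
variant is obtained by passing the square roots of the dissimilarities
(the recurrence is then applied to the original values; merge order and
cuts are identical because the square root is monotone) and squaring the
returned heights. A four-point hand-executed recurrence in the test suite
pins this equivalence down.

The number of clusters is chosen by the mean silhouette width of k-means
partitions (k-means++ with 25 restarts, fixed seed, Euclidean distance on
the correlation-matrix rows) over k = 3…10. Whether the original
silhouette analysis ran on the correlation matrix or on raw expression is
a design choice here, not an established fact; the correlation-matrix
choice keeps the silhouette and the hierarchical clustering in the same
geometry. With k = 3, clusters are named A/B/C by ascending median
lymphoid score (mean expression of the lymphoid marker genes), so A is
always the immune-cold and C the immune-hot cluster; ties are broken by
cluster size with a logged warning.

## Single-sample classifier

The classifier is a binomial logistic regression penalized by the lasso,

    min over (β₀, β) of (1/n) Σ_i [log(1 + e^{η_i}) − y_i η_i] + λ‖β‖₁,
    η_i = β₀ + Σ_g β_g X_gi,

fitted on gene-wise mean-centered log2 expression (centering is checked,
tolerance 1e-6). The solver is glmnet-style: outer iteratively reweighted
least squares, inner cyclic coordinate descent with soft-thresholding,
active-set sweeps, warm starts along a log-spaced λ path below the
analytic λ_max = max_g |⟨x_g, y − ȳ⟩| / n, and sequential strong-rule
screening with full KKT verification (violators re-entered). λ is chosen
by stratified k-fold (default 5) cross-validated binomial deviance,
minimum-deviance rule; the one-standard-error rule is not used because
the procedure being reproduced reports a dense model. Solutions satisfy
the KKT conditions of the objective to 1e-6 by construction of the
stopping rule; an independent glmnet fit at fixed λ agrees to ~1e-4 in
the test suite.

At prediction time the model is the published index convention: the
per-sample index is the weighted sum Σ_g β_g X_gi *without* the model
intercept, and the decision threshold is the negated intercept
(threshold = −β₀), so `index > threshold ⇔ β₀ + Σ β_g X_gi > 0`. The
comparison is strict. Genes missing from a matrix contribute zero with a
warning; an all-zero weight vector yields index 0 (not an error), and a
weight file whose genes are entirely absent is an error. Three-cluster
assignment is two-stage: the B-vs-rest model takes precedence; remaining
samples are split by the A-vs-C model.

## Microenvironment dissection

Cell-type proportions are estimated per sample by constrained linear
deconvolution: the bulk profile is returned to linear scale (2^x − 1,
floored at 0), restricted to the signature genes, and both the signature
matrix and the bulk vector are scaled per gene by the signature row's
standard deviation before solving `min ‖S w − b‖₂ s.t. w ≥ 0`
(scipy NNLS). Rows are *scaled, not centered*: row-centering places the
all-ones vector in the null space of the signature (every centered row
sums to zero across cell types), which makes the weights unidentifiable.
This stage deliberately replaces reference-based nu-support-vector
deconvolution with a self-contained, exactly testable solver; "absolute
score" means the raw non-negative weights in this scaled space, and
relative fractions are `w / Σw` where the sum is positive.

Single-sample gene-set activity is the mean of cohort-standardized gene
z-scores over the set's measured genes — a deterministic stand-in for
rank-based single-sample enrichment scoring with the same intended
ordering semantics. Zero-variance genes are dropped with a warning; a set
with no measured genes scores NaN and is flagged, never silently zero.
The score is invariant to per-gene affine transforms of the input.

Which features explain Cluster B is asked with unpenalized
maximum-likelihood logistic regression (statsmodels GLM/Newton,
internally standardized features), Wald 95% intervals, and
Benjamini–Hochberg FDR across features; coefficients beyond 20 after
standardization are flagged as separation symptoms. Gene-set scores vs
cell-type proportions are related by Spearman correlation with BH FDR
across all pairs.

## Phenotype analysis

Genes overexpressed in Cluster B are defined by Welch (unequal-variance)
two-sample t-tests of B against A and against C separately, each
Bonferroni-corrected over the genes tested within its comparison
(a genes × comparisons factor is selectable), at corrected p < 1e-4; a
gene is "up in B" only if both comparisons pass *and* the B mean exceeds
both other means. Enrichment of such genes in curated sets is the
inclusive upper tail of the hypergeometric distribution,
p = P(X ≥ overlap), with the measured genes as the default universe; the
test suite checks it against exhaustive enumeration of all draws for
universes up to size 12.

Cluster B is split by hierarchically clustering its samples on the
gene-set score profiles (correlation distance, unsquared Ward), cutting
at k = 2, and naming the sub-cluster with the higher median score of the
EMT-designated set B1 (the other B2). Anchoring the naming to a
configured set keeps labels stable across runs.

## Survival and response

Kaplan–Meier estimation, the log-rank test and Cox partial-likelihood
fitting are delegated to lifelines (Efron tie handling, Newton
optimization); this module owns the contracts: positive times, binary
events, collinearity rejection, the AIC convention
AIC = 2·(number of β) − 2·log partial likelihood (no intercept exists in
a partial likelihood), and a null-Cox score statistic (U(0)²/I(0),
Breslow risk sets) that the tests verify equals the two-group log-rank
chi-square on tie-free data. Backward selection drops, at each step, the
covariate with the weakest Wald significance, accepting the drop only if
the model AIC does not increase; the trace is returned. Ordering drops by
p-value with an AIC acceptance gate is one reading of "remove the weakest
predictor only if this does not weaken the model"; pure-AIC drop ordering
would be a one-line change. Cluster–pCR association is a Pearson
chi-square without continuity correction.

ER status is inferred from a single gene's expression (ESR1 by default)
with a two-component univariate Gaussian mixture fitted by EM:
deterministic initialization at the 25th/75th percentiles with pooled sd
and equal weights, convergence when the log-likelihood changes by less
than 1e-8, variance collapse (< 1e-6) triggering up to five re-starts
from random pairs of observations. The higher-mean component is
ER-positive; labels are posterior > 0.5. PAM50 subtype is the argmax
Spearman correlation of a sample's 50 centroid-gene values against the
five centroid columns (Pearson selectable; ties broken by the fixed
subtype order basal, her2, luma, lumb, normal), and the
risk-of-recurrence score is the published linear combination
ROR = 0.05·Basal + 0.12·Her2 − 0.34·LumA + 0.23·LumB (the normal-like
correlation does not enter).

## The synthetic cohort generator

The generator is first-class, tested code: it defines the population the
pipeline is validated against.

**Structure.** Each cohort has `n_samples` (default 600) assigned to
clusters A/B/C with fractions (0.40, 0.25, 0.35) — B smallest, as in the
motivating cohorts. A sample's bulk linear expression is

    bulk = (1 − f) · tumor_profile + f · (immune_profiles × mix),

followed by log2(x + 1) and i.i.d. Gaussian noise (sd 0.3 log2 units).
The immune fraction f is the cluster's infiltration level (0.05, 0.20,
0.40 for A, B, C) times a lognormal factor (sd 0.15 in log); the
multiplicative spread keeps f positive without a clipping atom near zero.
The within-immune mix is Dirichlet over 8 cell types (base concentration
8); in Cluster B the three designated pro-tumorigenic types (M2-like
macrophages, resting mast-like, resting memory-T-like) have their
concentration multiplied by 1 + `protumor_shift` (default 2.5×), tilting
B's composition while leaving its total infiltration intermediate.

**Genes.** The immune panel (default 509 genes) contains the signature
genes — 6 exclusive markers per cell type (own-type signal ≥ 4× any other
type) plus 72 shared immune genes — and broad immune genes whose
per-type loadings are lognormal (sd 0.8), so composition shapes the whole
panel. Tumor cells express panel genes at comparable magnitude
(lognormal around 20, sd 1.0 in log), which keeps the tumor/immune
balance shifting profile shape across the entire infiltration range
instead of saturating once immune content dominates. The background
compartment holds the EMT and proliferation programs (60 genes each,
shifted by `phenotype_effect` = 1 log2 unit in carriers), 50
subtype-centroid genes, ESR1 (bimodal by ER status, 75% ER-positive),
and unstructured genes. B samples carry the EMT program with probability
0.65 (else proliferation); C samples are proliferative; A samples
quiescent — so EMT and proliferation are mutually exclusive by
construction and their score anti-correlation within B is a designed
property, not an empirical discovery.

**Outcomes.** Survival is exponential with baseline hazard 0.05 and a
multiplicative hazard ratio 2.0 for Cluster B (proportional hazards holds
by construction, matching the Cox model's assumption), censored by an
independent exponential clock calibrated to ~30%. pCR is Bernoulli per
cluster with rates (0.13, 0.18, 0.42) for (A, B, C) — the published
per-cluster responder percentages — drawn independently of survival,
since neoadjuvant-response cohorts and survival cohorts are distinct
populations in practice.

**Randomness.** The seed is split into named streams (architecture,
per-sample draws, measurement noise, outcomes). The gene architecture —
signature matrix, loadings, programs, centroids — is governed by a
separate `architecture_seed` (default fixed), so cohorts generated with
different seeds are independent samples *from the same population*;
that is precisely what training a classifier on one cohort and
validating it on another presumes. Same (seed, architecture_seed) gives
bit-identical output.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: gene–gene correlation beyond the programs and
cell-type structure, platform and batch effects, probe-level noise,
non-proportional hazards, informative censoring, subtype–survival
interactions, and any misspecification of the signature matrix relative
to the truth (the deconvolution tests use the generator's own signature).
Real-cohort headline numbers (e.g. an AUC of 85.8% across ten cohorts)
are not reproducible from synthetic data and are treated as reference
context, not test targets.

## Problem sizes

The validation suite and the acceptance script run the discovery chain on
twenty 600-sample cohorts, classifier transfer between two 600-sample
cohorts, deconvolution on 200 pure mixtures (log2 noise sd 0.5),
ER-mixture calling on 500 draws, survival recovery on 1000 samples with
30% censoring plus twenty 400-sample log-rank replicates, differential
expression with 100 planted and 2000 null genes, and byte-identity of two
150-sample pipeline reruns — sizes chosen so the whole battery completes
on a single CPU in minutes while keeping every check comfortably powered.

## Known limitations

- The deconvolution stage is ordinary NNLS; it has no outlier-robust loss
  and no per-sample significance, and its "absolute score" units are tied
  to the sd-scaled signature space.
- The mean-z gene-set score is not rank-based; heavy-tailed genes weigh
  more than they would under a rank statistic.
- Breslow tie handling for the Cox model is exposed only through the
  internal null-score helper; full fits use Efron ties.
- The EM ER-caller assumes exactly two Gaussian components; skewed or
  trimodal expression will produce confident but wrong splits.
- Single-sample prediction applies trained weights to the expression
  values as given; the training convention is mean-centered data, so a
  lone sample should be centered against a reference cohort's gene means
  for calibrated thresholds.
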