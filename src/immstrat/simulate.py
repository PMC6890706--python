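"""Synthetic bulk breast-cancer cohorts with known immune structure.

The generator emulates the statistical structure the downstream analysis
assumes: three patient clusters (A, B, C) with gradually increasing immune
infiltration, bulk expression formed by mixing a tumor profile with
cell-type signature profiles in linear space, a pro-tumorigenic tilt of
Cluster B's immune composition (M2-like macrophages, resting mast-like
cells, resting memory T-like cells), two mutually exclusive tumor programs
(EMT vs proliferation), cluster-dependent survival hazards, and
cluster-dependent pathological-complete-response probabilities.

Mixing is additive in linear expression units; the observed matrix is
log2(x + 1) of the mixture plus Gaussian noise, matching the convention
that bulk deconvolution operates in linear space while clustering and
scoring operate in log space.

Randomness is split into named streams (gene architecture, per-sample
draws, measurement noise, clinical outcomes) spawned deterministically
from the single seed, so the gene architecture does not change when the
cohort size does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenePanel, GeneSetCollection, ImmstratError

__all__ = [
    "SyntheticConfig",
    "CohortTruth",
    "CellTypeSignatureMatrix",
    "SyntheticCohort",
    "generate_signature_matrix",
    "generate_cohort",
]

CANONICAL_CELLTYPES = [
    "t_cd8",
    "t_helper_follicular",
    "nk_cells",
    "b_cells",
    "macrophage_m1",
    "macrophage_m2",
    "mast_resting",
    "t_memory_resting",
]
PROTUMOR_TYPES = {"macrophage_m2", "mast_resting", "t_memory_resting"}
LYMPHOID_TYPES = {"t_cd8", "t_helper_follicular", "nk_cells", "b_cells", "t_memory_resting"}
MYELOID_TYPES = {"macrophage_m1", "macrophage_m2", "mast_resting"}

SUBTYPES = ["basal", "her2", "luma", "lumb", "normal"]


@dataclass
class SyntheticConfig:
    """Cohort generator settings; defaults are the study conditions.

    ``pcr_rates`` defaults to the reported per-cluster responder rates
    (13%, 18%, 42% for A, B, C) and ``b_emt_fraction`` to the reported
    65% EMT share of Cluster B.
    """

    n_samples: int = 600
    cluster_fractions: tuple[float, float, float] = (0.40, 0.25, 0.35)
    n_panel_genes: int = 509
    n_background_genes: int = 1500
    n_celltypes: int = 8
    infiltration_levels: tuple[float, float, float] = (0.05, 0.20, 0.40)
    infiltration_log_sd: float = 0.15
    protumor_shift: float = 1.5
    phenotype_effect: float = 1.0
    b_emt_fraction: float = 0.65
    noise_sd: float = 0.3
    baseline_hazard: float = 0.05
    hazard_ratio_b: float = 2.0
    censoring_rate: float = 0.3
    pcr_rates: tuple[float, float, float] = (0.13, 0.18, 0.42)
    er_pos_rate: float = 0.75
    dirichlet_alpha: float = 8.0
    markers_per_type: int = 6
    n_shared_immune_genes: int = 72
    n_program_genes: int = 60
    seed: int = 0
    # the gene architecture (signatures, loadings, centroids, programs) is
    # the shared biology: cohorts drawn with different `seed` but the same
    # `architecture_seed` are independent samples of the same population,
    # which is what train-on-one-cohort / test-on-another presumes
    architecture_seed: int = 42

    def validate(self) -> None:
        if abs(sum(self.cluster_fractions) - 1.0) > 1e-9:
            raise ImmstratError("cluster_fractions must sum to 1")
        lv = self.infiltration_levels
        if not (lv[0] < lv[1] < lv[2]):
            raise ImmstratError("infiltration_levels must be strictly increasing")
        if lv[2] >= 1.0 or lv[0] <= 0.0:
            raise ImmstratError("infiltration levels must lie in (0, 1)")
        if not all(0.0 <= p <= 1.0 for p in self.pcr_rates):
            raise ImmstratError("pcr_rates must lie in [0, 1]")
        if not 0.0 <= self.b_emt_fraction <= 1.0:
            raise ImmstratError("b_emt_fraction must lie in [0, 1]")
        if self.n_celltypes < 2:
            raise ImmstratError("need at least 2 cell types")
        if self.noise_sd < 0:
            raise ImmstratError("noise_sd must be non-negative")
        n_sig = self.n_celltypes * self.markers_per_type + self.n_shared_immune_genes
        if self.n_panel_genes < n_sig:
            raise ImmstratError(
                f"n_panel_genes={self.n_panel_genes} smaller than the "
                f"{n_sig} signature genes implied by the cell-type layout"
            )
        if self.n_background_genes < 2 * self.n_program_genes + 51:
            raise ImmstratError("n_background_genes too small for programs + PAM50 + ESR1")


def _celltype_names(n: int) -> list[str]:
    names = CANONICAL_CELLTYPES[:n]
    names += [f"celltype_{i:02d}" for i in range(len(names), n)]
    return names


@dataclass
class CellTypeSignatureMatrix:
    """Linear-scale reference profiles, genes x cell types.

    ``markers`` maps each cell type to its exclusive marker genes; each
    exclusive marker's signal in its own type is at least 4x its value in
    every other type (validated).
    """

    data: pd.DataFrame
    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ImmstratError("signature matrix must be non-negative")
        for ct, genes in self.markers.items():
            if ct not in self.data.columns:
                raise ImmstratError(f"marker map names unknown cell type {ct!r}")
            ok = False
            for g in genes:
                row = self.data.loc[g]
                others = row.drop(ct)
                if len(others) == 0 or row[ct] >= 4.0 * others.max():
                    ok = True
                    break
            if not ok:
                raise ImmstratError(f"cell type {ct!r} has no 4x exclusive marker")

    @property
    def celltypes(self) -> list[str]:
        return list(self.data.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)


@dataclass
class CohortTruth:
    """Ground truth for a synthetic cohort.

    ``table`` holds per-sample scalars (true_cluster, true_phenotype,
    er_status, immune_fraction, time, event, pcr); ``fractions`` holds the
    within-immune cell-type simplex, samples x cell types.
    """

    table: pd.DataFrame
    fractions: pd.DataFrame

    def __post_init__(self) -> None:
        fr = self.fractions.to_numpy()
        if (fr < -1e-12).any() or np.abs(fr.sum(axis=1) - 1.0).max() > 1e-9:
            raise ImmstratError("true fractions must be a simplex per sample")
        if (self.table["time"].to_numpy() <= 0).any():
            raise ImmstratError("survival times must be positive")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    truth: CohortTruth
    signature: CellTypeSignatureMatrix
    panel: GenePanel
    gene_sets: GeneSetCollection
    centroids: pd.DataFrame
    lymphoid_markers: GenePanel = None
    myeloid_markers: GenePanel = None
    immune_profiles: pd.DataFrame = field(default=None, repr=False)


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_signature_matrix(config: SyntheticConfig) -> CellTypeSignatureMatrix:
    """Build the linear-scale cell-type signature matrix for ``config``.

    Each cell type receives ``markers_per_type`` exclusive markers (high in
    the owning type, at most 1/8 of that value elsewhere) plus a block of
    shared immune genes with independent lognormal levels per type.
    """
    config.validate()
    arch_rng = np.random.default_rng(config.architecture_seed)
    return _signature_from_rng(config, arch_rng)[0]


def _signature_from_rng(config, rng):
    types = _celltype_names(config.n_celltypes)
    rows: list[np.ndarray] = []
    genes: list[str] = []
    markers: dict[str, list[str]] = {t: [] for t in types}
    for t_idx, t in enumerate(types):
        for m in range(config.markers_per_type):
            own = rng.lognormal(mean=np.log(200.0), sigma=0.3)
            row = rng.uniform(0.0, own / 8.0, size=len(types))
            row[t_idx] = own
            gene = f"MK_{t}_{m:02d}"
            genes.append(gene)
            markers[t].append(gene)
            rows.append(row)
    for s in range(config.n_shared_immune_genes):
        row = rng.lognormal(mean=np.log(50.0), sigma=0.5, size=len(types))
        genes.append(f"IMMSH{s:04d}")
        rows.append(row)
    data = pd.DataFrame(np.array(rows), index=genes, columns=types)
    return CellTypeSignatureMatrix(data=data, markers=markers), rng


def _gene_architecture(config: SyntheticConfig, rng: np.random.Generator):
    """Draw everything that does not depend on the number of samples."""
    signature, rng = _signature_from_rng(config, rng)
    types = signature.celltypes

    n_broad = config.n_panel_genes - len(signature.genes)
    broad_genes = [f"IMMG{i:04d}" for i in range(n_broad)]
    broad_base = rng.lognormal(np.log(30.0), 0.6, size=n_broad)
    # wide per-type loadings so immune composition shapes the whole panel
    broad_profile = broad_base[:, None] * rng.lognormal(0.0, 0.8, size=(n_broad, len(types)))

    npg = config.n_program_genes
    emt_genes = [f"EMTG{i:03d}" for i in range(npg)]
    prolif_genes = [f"PRLF{i:03d}" for i in range(npg)]
    pam_genes = [f"PAM{i:03d}" for i in range(50)]
    n_plain = config.n_background_genes - 2 * npg - 50 - 1
    plain_genes = [f"BGG{i:04d}" for i in range(n_plain)]
    background_genes = emt_genes + prolif_genes + pam_genes + plain_genes + ["ESR1"]

    bg_base = rng.lognormal(np.log(80.0), 0.8, size=len(background_genes))
    bg_base[-1] = 1.0  # ESR1 tumor level is set per sample by ER status
    bg_immune = bg_base[:, None] * 0.3 * rng.lognormal(0.0, 0.3, size=(len(background_genes), len(types)))

    # tumor cells express panel genes at comparable magnitude, so the
    # tumor/immune balance keeps shifting profile shape across the whole
    # infiltration range instead of saturating early
    panel_tumor = rng.lognormal(np.log(20.0), 1.0, size=config.n_panel_genes)

    centroids = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(50, len(SUBTYPES))), index=pam_genes, columns=SUBTYPES
    )

    all_genes = list(signature.genes) + broad_genes + background_genes
    immune_profiles = pd.DataFrame(
        np.vstack([signature.data.to_numpy(), broad_profile, bg_immune]),
        index=all_genes,
        columns=types,
    )
    tumor_base = pd.Series(
        np.concatenate([panel_tumor, bg_base]),
        index=list(signature.genes) + broad_genes + background_genes,
    )
    panel_genes = list(signature.genes) + broad_genes
    return {
        "signature": signature,
        "immune_profiles": immune_profiles,
        "tumor_base": tumor_base,
        "panel_genes": panel_genes,
        "emt_genes": emt_genes,
        "prolif_genes": prolif_genes,
        "pam_genes": pam_genes,
        "centroids": centroids,
        "all_genes": all_genes,
    }


def _draw_subtype(rng, er_pos: bool, phenotype: str) -> str:
    if not er_pos:
        return rng.choice(["basal", "her2"], p=[0.8, 0.2])
    if phenotype == "proliferative":
        return rng.choice(["lumb", "her2", "luma"], p=[0.7, 0.1, 0.2])
    if phenotype == "EMT":
        return rng.choice(["normal", "basal", "luma"], p=[0.5, 0.2, 0.3])
    return rng.choice(["luma", "normal"], p=[0.8, 0.2])


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config``.

    Per sample: bulk linear expression = (1 - f) * tumor profile +
    f * (immune profiles x within-immune mix), where f is drawn around the
    cluster's infiltration level; Cluster B's mix up-weights the designated
    pro-tumorigenic cell types.  B samples carry the EMT program with
    probability ``b_emt_fraction`` (else proliferation); C samples are
    proliferative; A samples quiescent.  The observed matrix is
    log2(x + 1) plus Gaussian noise.
    """
    config.validate()
    _, sample_rng, noise_rng, outcome_rng = _spawn_rngs(config.seed, 4)
    arch_rng = np.random.default_rng(config.architecture_seed)
    arch = _gene_architecture(config, arch_rng)
    signature: CellTypeSignatureMatrix = arch["signature"]
    types = signature.celltypes
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    clusters = sample_rng.choice(["A", "B", "C"], size=n, p=list(config.cluster_fractions))
    phenotype = np.where(clusters == "C", "proliferative", "quiescent").astype(object)
    b_mask = clusters == "B"
    emt_draw = sample_rng.random(n) < config.b_emt_fraction
    phenotype[b_mask & emt_draw] = "EMT"
    phenotype[b_mask & ~emt_draw] = "proliferative"

    er_pos = sample_rng.random(n) < config.er_pos_rate
    subtype = np.array(
        [_draw_subtype(sample_rng, er_pos[i], phenotype[i]) for i in range(n)], dtype=object
    )

    level = {"A": config.infiltration_levels[0], "B": config.infiltration_levels[1], "C": config.infiltration_levels[2]}
    # multiplicative spread keeps f positive and atom-free near zero
    f = np.array([level[c] for c in clusters]) * sample_rng.lognormal(
        0.0, config.infiltration_log_sd, n
    )
    f = np.clip(f, 1e-4, 0.95)

    alpha = np.full(len(types), config.dirichlet_alpha)
    alpha_b = alpha.copy()
    for i, t in enumerate(types):
        if t in PROTUMOR_TYPES:
            alpha_b[i] *= 1.0 + config.protumor_shift
    if not any(t in PROTUMOR_TYPES for t in types):
        alpha_b[-1] *= 1.0 + config.protumor_shift
    mix = np.empty((n, len(types)))
    for i in range(n):
        mix[i] = sample_rng.dirichlet(alpha_b if clusters[i] == "B" else alpha)

    # Tumor profiles: base, phenotype program, subtype centroid tilt, ESR1.
    tumor_base = arch["tumor_base"].to_numpy()
    gene_index = pd.Index(arch["all_genes"])
    emt_idx = gene_index.get_indexer(arch["emt_genes"])
    prolif_idx = gene_index.get_indexer(arch["prolif_genes"])
    pam_idx = gene_index.get_indexer(arch["pam_genes"])
    esr1_idx = gene_index.get_loc("ESR1")
    centroids = arch["centroids"]

    tumor = np.tile(tumor_base[:, None], (1, n))
    eff = 2.0 ** config.phenotype_effect
    for i in range(n):
        if phenotype[i] == "EMT":
            tumor[emt_idx, i] *= eff
        elif phenotype[i] == "proliferative":
            tumor[prolif_idx, i] *= eff
        tumor[pam_idx, i] *= 2.0 ** centroids[subtype[i]].to_numpy()
        tumor[esr1_idx, i] = 300.0 if er_pos[i] else 6.0

    immune = arch["immune_profiles"].to_numpy() @ mix.T
    bulk = (1.0 - f)[None, :] * tumor + f[None, :] * immune
    logged = np.log2(bulk + 1.0)
    if config.noise_sd > 0:
        logged = logged + noise_rng.normal(0.0, config.noise_sd, size=logged.shape)

    expression = ExpressionMatrix(pd.DataFrame(logged, index=list(gene_index), columns=samples))

    # Clinical outcomes: exponential survival with a Cluster-B hazard
    # multiplier, independent exponential censoring, per-cluster pCR.
    hazard = config.baseline_hazard * np.where(clusters == "B", config.hazard_ratio_b, 1.0)
    t_event = outcome_rng.exponential(1.0 / hazard)
    c_rate = config.baseline_hazard * config.censoring_rate / max(1e-12, 1.0 - config.censoring_rate)
    t_cens = outcome_rng.exponential(1.0 / c_rate, size=n) if c_rate > 0 else np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    pcr_rate = {"A": config.pcr_rates[0], "B": config.pcr_rates[1], "C": config.pcr_rates[2]}
    pcr = (outcome_rng.random(n) < np.array([pcr_rate[c] for c in clusters])).astype(int)

    truth = CohortTruth(
        table=pd.DataFrame(
            {
                "true_cluster": clusters,
                "true_phenotype": phenotype,
                "er_status": np.where(er_pos, "pos", "neg"),
                "subtype": subtype,
                "immune_fraction": f,
                "time": time,
                "event": event,
                "pcr": pcr,
            },
            index=samples,
        ),
        fractions=pd.DataFrame(mix, index=samples, columns=types),
    )

    npg = config.n_program_genes
    gene_sets = GeneSetCollection(
        sets={
            "emt_program": list(arch["emt_genes"]),
            "proliferation_program": list(arch["prolif_genes"]),
            "emt_partial": list(arch["emt_genes"][: npg // 2]),
            "proliferation_partial": list(arch["prolif_genes"][: npg // 2]),
        }
    )
    lymphoid = [g for t in types if t in LYMPHOID_TYPES for g in signature.markers[t]]
    myeloid = [g for t in types if t in MYELOID_TYPES for g in signature.markers[t]]
    if not lymphoid:
        lymphoid = signature.markers[types[0]]
    if not myeloid:
        myeloid = signature.markers[types[-1]]

    return SyntheticCohort(
        expression=expression,
        truth=truth,
        signature=signature,
        panel=GenePanel(name="synthetic_immune_panel", genes=frozenset(arch["panel_genes"])),
        gene_sets=gene_sets,
        centroids=centroids,
        lymphoid_markers=GenePanel(name="lymphoid_markers", genes=frozenset(lymphoid)),
        myeloid_markers=GenePanel(name="myeloid_markers", genes=frozenset(myeloid)),
        immune_profiles=arch["immune_profiles"],
    )
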