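"""Synthetic cohorts, models, and perturbation profiles with planted truth.

Every input the pipeline consumes can be generated here: a block-correlated
genotype panel, per-gene per-tissue eQTL weight models, a sparse nonnegative
latent model whose LV member genes coincide with LD blocks, phenotypes with
planted LV-level effects, drug perturbation profiles with planted signature
reversals, and trait-by-LV matrices with planted cluster structure.  All
generators are pure functions of their parameters and a seed.

Three named scenarios bundle the generators into the study designs the
package is validated on:

* ``scenario_regression`` — calibration and power of the competitive GLS
  test, with one LV's member genes in tight LD so that ignoring their
  correlation visibly inflates the test;
* ``scenario_drug_reversal`` — one compound whose perturbation profile is
  the negated trait signature plus noise;
* ``scenario_trait_clusters`` — well-separated trait clusters driven by
  disjoint sets of discriminative LVs (or matched structureless noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LabelledMatrix, LatentModel, TwasResultSet, top_lv_genes
from .twas import (GenotypePanel, PredictionModelSet, predict_expression,
                   reduce_pcs, smultixcan_batch, spredixcan_z)

__all__ = [
    "SyntheticTruth",
    "PhenotypeSet",
    "generate_panel",
    "generate_models",
    "generate_latent_model",
    "generate_twas",
    "generate_drug_profiles",
    "generate_trait_clusters",
    "scenario_regression",
    "scenario_drug_reversal",
    "scenario_trait_clusters",
]


@dataclass
class SyntheticTruth:
    """Ground truth planted into a synthetic dataset."""

    lv_effects: list[tuple[str, str, float]] = field(default_factory=list)
    reversal_compounds: list[tuple[str, str, float]] = field(default_factory=list)
    cluster_labels: dict[str, int] = field(default_factory=dict)
    cluster_lvs: dict[int, list[str]] = field(default_factory=dict)
    gwas_sample_size: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        for _, _, effect in self.lv_effects:
            if effect <= 0:
                raise ValueError("planted effect sizes must be positive")


@dataclass
class PhenotypeSet:
    """Centered individuals-by-traits phenotype matrix."""

    y: np.ndarray
    trait_ids: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.y = self.y - self.y.mean(axis=0)


def generate_panel(n_individuals: int, n_snps: int, n_blocks: int,
                   within_block_r: float, maf_range: tuple[float, float],
                   seed: int) -> GenotypePanel:
    """Block-correlated dosage panel.

    Per haplotype, a latent Gaussian with equicorrelation ``within_block_r``
    inside each block is thresholded at the per-SNP minor-allele-frequency
    quantile; the dosage is the sum of two independent haplotypes.  Realized
    dosage correlations are attenuated relative to the latent value (binary
    thresholding loses correlation), which the generators compensate for by
    using fairly high latent values.
    """
    if not (0 <= within_block_r < 1):
        raise ValueError("within_block_r must be in [0, 1)")
    lo, hi = maf_range
    if not (0 < lo <= hi < 0.5):
        raise ValueError("MAF range must satisfy 0 < lo <= hi < 0.5")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=n_snps)
    cut = stats.norm.isf(maf)  # latent > cut -> minor allele
    block_of = np.arange(n_snps) % n_blocks
    dosage = np.zeros((n_individuals, n_snps))
    for _hap in range(2):
        shared = rng.standard_normal((n_individuals, n_blocks))
        noise = rng.standard_normal((n_individuals, n_snps))
        latent = (np.sqrt(within_block_r) * shared[:, block_of]
                  + np.sqrt(1 - within_block_r) * noise)
        dosage += (latent > cut[None, :]).astype(float)
    snp_ids = [f"rs{i}" for i in range(n_snps)]
    blocks = [[snp_ids[i] for i in np.flatnonzero(block_of == b)]
              for b in range(n_blocks)]
    return GenotypePanel(dosages=dosage, snp_ids=snp_ids, snp_blocks=blocks)


def generate_models(panel: GenotypePanel, n_genes: int, tissues_per_gene: int,
                    snps_per_model: int, seed: int,
                    genes_per_block: int = 1) -> PredictionModelSet:
    """Per-gene eQTL weight models with SNPs drawn inside one LD block.

    Gene ``i`` is assigned to block ``(i // genes_per_block) % n_blocks``, so
    genes sharing a block have correlated predicted expression while genes in
    different blocks are nearly independent.  Weights are standard normal.
    ``tissues_per_gene`` is an upper bound: each gene has models in between
    one (or two, when the bound allows) and that many tissues, mirroring the
    uneven tissue coverage of real prediction-model sets.
    """
    if panel.snp_blocks is None:
        raise ValueError("panel lacks block structure")
    rng = np.random.default_rng(seed)
    n_blocks = len(panel.snp_blocks)
    rows = []
    for i in range(n_genes):
        block = panel.snp_blocks[(i // genes_per_block) % n_blocks]
        lo = 2 if tissues_per_gene >= 2 else 1
        n_tissues = int(rng.integers(lo, tissues_per_gene + 1))
        for t in range(n_tissues):
            replace = snps_per_model > len(block)
            snps = rng.choice(block, size=snps_per_model, replace=replace)
            w = rng.standard_normal(snps_per_model)
            while np.all(w == 0):  # vanishly rare; keep models nonzero
                w = rng.standard_normal(snps_per_model)
            for s, wv in zip(snps, w):
                rows.append({"gene": f"g{i}", "tissue": f"t{t}",
                             "snp_id": s, "weight": wv})
    return PredictionModelSet(pd.DataFrame(rows))


def generate_latent_model(n_genes: int, n_lvs: int, members_per_lv: int,
                          loading_scale: float = 1.0, lambda2: float = 0.4,
                          seed: int = 0, background_scale: float = 0.01,
                          with_b: bool = False) -> LatentModel:
    """Sparse nonnegative loading matrix with designated member blocks.

    LV ``j`` has high loadings on the contiguous gene block
    ``[j * members_per_lv, (j + 1) * members_per_lv)`` (wrapping around) on
    top of a small uniform background, so member loadings clearly exceed the
    background distribution.
    """
    rng = np.random.default_rng(seed)
    Z = rng.uniform(0, background_scale, size=(n_genes, n_lvs))
    for j in range(n_lvs):
        idx = (np.arange(j * members_per_lv, (j + 1) * members_per_lv)) % n_genes
        Z[idx, j] += loading_scale * rng.uniform(0.5, 1.0, size=members_per_lv)
    B = sample_ids = None
    if with_b:
        B = rng.standard_normal((n_lvs, 2 * n_lvs))
        sample_ids = [f"s{i}" for i in range(2 * n_lvs)]
    return LatentModel(Z=Z, lambda2=lambda2,
                       gene_ids=[f"g{i}" for i in range(n_genes)],
                       lv_ids=[f"LV{j}" for j in range(n_lvs)],
                       B=B, sample_ids=sample_ids)


def _gwas_summary(y: np.ndarray, panel: GenotypePanel) -> pd.DataFrame:
    """Marginal per-SNP effect estimates and standard errors."""
    X = panel.dosages
    n = X.shape[0]
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sxx = (Xc ** 2).sum(axis=0)
    sxx = np.where(sxx > 0, sxx, np.nan)
    beta = Xc.T @ yc / sxx
    rss = (yc @ yc) - beta ** 2 * sxx
    se = np.sqrt(np.clip(rss, 0, None) / (n - 2) / sxx)
    df = pd.DataFrame({"snp_id": panel.snp_ids, "beta": beta, "se": se})
    return df.dropna()


def _trait_phenotypes(panel: GenotypePanel, models: PredictionModelSet,
                      latent_model: LatentModel, truth: SyntheticTruth,
                      trait_ids: list[str], fraction: float,
                      rng: np.random.Generator) -> PhenotypeSet:
    n = panel.n_individuals
    effects = {trait: (lv, h2) for lv, trait, h2 in truth.lv_effects}
    Y = rng.standard_normal((n, len(trait_ids)))
    for j, trait in enumerate(trait_ids):
        if trait not in effects:
            continue
        lv, h2 = effects[trait]
        if not (0 < h2 < 1):
            raise ValueError("planted effect must be a variance fraction in (0,1)")
        members = top_lv_genes(latent_model, lv, fraction)
        lv_col = latent_model.lv_ids.index(lv)
        signal = np.zeros(n)
        for g in members:
            pe = predict_expression(panel, models, g)
            loading = latent_model.Z[latent_model.gene_ids.index(g), lv_col]
            signal += loading * pe.T.mean(axis=1)
        signal = (signal - signal.mean()) / signal.std(ddof=1)
        Y[:, j] = np.sqrt(h2) * signal + np.sqrt(1 - h2) * Y[:, j]
    return PhenotypeSet(y=Y, trait_ids=trait_ids)


def generate_twas(panel: GenotypePanel, models: PredictionModelSet,
                  truth: SyntheticTruth, latent_model: LatentModel, seed: int,
                  n_null_traits: int = 20, fraction: float = 0.1,
                  pc_condition_threshold: float = 30.0,
                  with_tissue_z: bool = False) -> TwasResultSet:
    """Run the full individual-level TWAS pipeline on synthetic phenotypes.

    Null traits are independent of genotype; traits named in the planted
    truth receive an LV-mediated genetic signal whose variance fraction is
    the planted effect size.  Returns the cross-tissue p-value matrix with
    per-gene (k, p) metadata and, optionally, per-tissue signed z matrices
    computed from GWAS summary statistics.
    """
    rng = np.random.default_rng(seed)
    trait_ids = [t for _, t, _ in truth.lv_effects]
    trait_ids += [f"null{i}" for i in range(n_null_traits)]
    phen = _trait_phenotypes(panel, models, latent_model, truth, trait_ids,
                             fraction, rng)
    genes = [g for g in models.genes]
    pes = []
    for g in genes:
        pe = reduce_pcs(predict_expression(panel, models, g),
                        pc_condition_threshold)
        pes.append(pe)
    pvals = smultixcan_batch(phen.y, pes)
    meta = pd.DataFrame({"k": [pe.k for pe in pes],
                         "p": [pe.p for pe in pes]},
                        index=[pe.gene_id for pe in pes])
    pmat = LabelledMatrix(pvals, [pe.gene_id for pe in pes], trait_ids,
                          orientation="rows=genes")
    tissue_z: dict[str, LabelledMatrix] = {}
    if with_tissue_z:
        tissues = sorted({t for g in genes for t in models.tissues(g)})
        store = {t: np.zeros((len(genes), len(trait_ids))) for t in tissues}
        for j, trait in enumerate(trait_ids):
            gwas = _gwas_summary(phen.y[:, j], panel).set_index("snp_id")
            for i, g in enumerate(genes):
                for t in models.tissues(g):
                    z = spredixcan_z(gwas, models, panel, g, t)
                    store[t][i, j] = 0.0 if z is None else z
        tissue_z = {t: LabelledMatrix(v, list(genes), trait_ids,
                                      orientation="rows=genes")
                    for t, v in store.items()}
    for trait in trait_ids:
        truth.gwas_sample_size.setdefault(trait, float(panel.n_individuals))
    return TwasResultSet(pvalues=pmat, tissue_z=tissue_z, gene_meta=meta)


def generate_drug_profiles(latent_model: LatentModel, truth: SyntheticTruth,
                           n_compounds: int, noise_sd: float, seed: int,
                           signatures: LabelledMatrix | None = None
                           ) -> LabelledMatrix:
    """Compound perturbation z-scores (genes as rows, compounds as columns).

    Compounds named in the planted truth get the negated, standardized trait
    signature (a column of ``signatures``) plus Gaussian noise of standard
    deviation ``noise_sd``; remaining compounds are pure standard normal.
    At the default ``noise_sd=1`` the planted compound correlates with its
    trait signature at about -0.7.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(latent_model.gene_ids)
    planted = {c: t for c, t, _ in truth.reversal_compounds}
    if planted and signatures is None:
        raise ValueError("planted reversals require trait signatures")
    comp_ids = []
    cols = np.empty((len(gene_ids), n_compounds))
    # planted compounds first, then fillers
    ordered = list(planted) + [f"cmp{i}" for i in range(n_compounds - len(planted))]
    for j, comp in enumerate(ordered[:n_compounds]):
        if comp in planted:
            sig = signatures.col(planted[comp])
            if signatures.row_ids != gene_ids:
                pos = {g: i for i, g in enumerate(signatures.row_ids)}
                sig = np.array([sig[pos[g]] if g in pos else 0.0 for g in gene_ids])
            sig = (sig - sig.mean()) / sig.std(ddof=1)
            cols[:, j] = -sig + noise_sd * rng.standard_normal(len(gene_ids))
        else:
            cols[:, j] = rng.standard_normal(len(gene_ids))
        comp_ids.append(comp)
    return LabelledMatrix(cols, gene_ids, comp_ids, orientation="rows=genes")


def generate_trait_clusters(latent_model: LatentModel, n_traits: int,
                            n_clusters: int, lvs_per_cluster: int,
                            separation: float, seed: int
                            ) -> tuple[LabelledMatrix, SyntheticTruth]:
    """Traits-by-LV matrix with planted cluster structure.

    Each cluster elevates a disjoint set of ``lvs_per_cluster`` LVs by
    ``separation`` (in units of the unit within-cluster noise).  With
    ``separation=0`` the output is pure isotropic noise (the matched
    null-structure control).
    """
    n_lvs = latent_model.n_lvs
    if n_clusters * lvs_per_cluster > n_lvs:
        raise ValueError("not enough LVs for disjoint discriminative sets")
    rng = np.random.default_rng(seed)
    labels = np.arange(n_traits) % n_clusters
    values = rng.standard_normal((n_traits, n_lvs))
    cluster_lvs: dict[int, list[str]] = {}
    for c in range(n_clusters):
        lv_idx = np.arange(c * lvs_per_cluster, (c + 1) * lvs_per_cluster)
        cluster_lvs[c] = [latent_model.lv_ids[i] for i in lv_idx]
        if separation > 0:
            values[np.ix_(labels == c, lv_idx)] += separation
    trait_ids = [f"trait{i}" for i in range(n_traits)]
    mhat = LabelledMatrix(values, trait_ids, list(latent_model.lv_ids),
                          orientation="rows=traits")
    truth = SyntheticTruth(cluster_labels=dict(zip(trait_ids, labels.tolist())),
                           cluster_lvs=cluster_lvs if separation > 0 else {},
                           seed=seed)
    return mhat, truth


# ---------------------------------------------------------------------------
# named scenarios


@dataclass
class RegressionScenario:
    panel: GenotypePanel
    models: PredictionModelSet
    latent_model: LatentModel
    truth: SyntheticTruth
    twas: TwasResultSet
    fraction: float


def scenario_regression(seed: int, n_individuals: int = 2000,
                        n_genes: int = 2400, n_lvs: int = 10,
                        genes_per_block: int = 4, tissues_per_gene: int = 3,
                        snps_per_model: int = 2, within_block_r: float = 0.8,
                        effect_size: float = 0.1, n_null_traits: int = 20,
                        with_tissue_z: bool = False) -> RegressionScenario:
    """Study design for GLS calibration and power.

    2400 genes in LD blocks of four (so every LV's 240 member genes contain
    sixty correlated quartets with pairwise association-statistic
    correlation around 0.4), ten LVs of 240 members each — the desk-scale
    counterpart of the few-hundred-gene member sets the method uses at full
    scale, where the competitive test is approximately calibrated — and one
    planted LV-trait effect explaining ``effect_size`` of phenotypic
    variance.
    """
    rng = np.random.default_rng(seed)
    s = lambda: int(rng.integers(0, 2 ** 31 - 1))
    members_per_lv = n_genes // n_lvs
    n_blocks = n_genes // genes_per_block
    snps_per_block = max(4 * snps_per_model, 4)
    panel = generate_panel(n_individuals, n_blocks * snps_per_block, n_blocks,
                           within_block_r, (0.1, 0.4), s())
    models = generate_models(panel, n_genes, tissues_per_gene, snps_per_model,
                             s(), genes_per_block=genes_per_block)
    latent = generate_latent_model(n_genes, n_lvs, members_per_lv, seed=s())
    truth = SyntheticTruth(lv_effects=[("LV0", "trait_effect", effect_size)],
                           seed=seed)
    fraction = members_per_lv / n_genes
    twas = generate_twas(panel, models, truth, latent, s(),
                         n_null_traits=n_null_traits, fraction=fraction,
                         with_tissue_z=with_tissue_z)
    return RegressionScenario(panel=panel, models=models, latent_model=latent,
                              truth=truth, twas=twas, fraction=fraction)


@dataclass
class DrugScenario:
    panel: GenotypePanel
    models: PredictionModelSet
    latent_model: LatentModel
    truth: SyntheticTruth
    twas: TwasResultSet
    profiles: LabelledMatrix
    fraction: float


def scenario_drug_reversal(seed: int, n_individuals: int = 1000,
                           n_genes: int = 150, n_lvs: int = 10,
                           tissues_per_gene: int = 2, n_compounds: int = 20,
                           noise_sd: float = 1.0,
                           effect_size: float = 0.3,
                           n_null_traits: int = 4) -> DrugScenario:
    """Study design for signature-reversal recovery.

    One trait carries a strong LV-mediated genetic signal; one of twenty
    compounds gets the negated trait signature (tissue-0 z-scores) plus
    unit noise.  Scoring should rank that compound first for that trait in
    both gene and LV space.
    """
    rng = np.random.default_rng(seed)
    s = lambda: int(rng.integers(0, 2 ** 31 - 1))
    genes_per_block = 3
    members_per_lv = n_genes // n_lvs
    n_blocks = n_genes // genes_per_block
    panel = generate_panel(n_individuals, n_blocks * 4, n_blocks, 0.8,
                           (0.1, 0.4), s())
    models = generate_models(panel, n_genes, tissues_per_gene, 2, s(),
                             genes_per_block=genes_per_block)
    latent = generate_latent_model(n_genes, n_lvs, members_per_lv, seed=s())
    truth = SyntheticTruth(
        lv_effects=[("LV0", "trait_effect", effect_size)],
        reversal_compounds=[("drug_rev", "trait_effect", noise_sd)],
        seed=seed)
    fraction = members_per_lv / n_genes
    twas = generate_twas(panel, models, truth, latent, s(),
                         n_null_traits=n_null_traits, fraction=fraction,
                         with_tissue_z=True)
    signature = twas.tissue_z["t0"]
    profiles = generate_drug_profiles(latent, truth, n_compounds, noise_sd,
                                      s(), signatures=signature)
    return DrugScenario(panel=panel, models=models, latent_model=latent,
                        truth=truth, twas=twas, profiles=profiles,
                        fraction=fraction)


def scenario_trait_clusters(seed: int, n_traits: int = 50, n_lvs: int = 30,
                            n_clusters: int = 3, lvs_per_cluster: int = 3,
                            separation: float = 4.0,
                            structured: bool = True
                            ) -> tuple[LabelledMatrix, SyntheticTruth, LatentModel]:
    """Study design for consensus clustering and LV interpretation.

    Fifty traits in three equally sized clusters over thirty LVs; each
    cluster elevates three dedicated LVs by four noise standard deviations.
    ``structured=False`` yields the matched no-structure control.
    """
    latent = generate_latent_model(n_genes=5 * n_lvs, n_lvs=n_lvs,
                                   members_per_lv=5, seed=seed)
    mhat, truth = generate_trait_clusters(
        latent, n_traits, n_clusters, lvs_per_cluster,
        separation if structured else 0.0, seed)
    return mhat, truth, latent
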