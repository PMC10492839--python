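# Methods

`lvlink` integrates three data types on a shared coordinate system of gene
modules (latent variables, LVs): gene–trait associations from
transcriptome-wide association studies (TWAS), gene–drug associations from
perturbation screens, and a trained nonnegative gene×LV loading matrix
**Z**. This note documents the models implemented, the choices made where
the design was open, and what the synthetic validation does and does not
show.

## TWAS primitives

The predicted expression of gene *i* in tissue *l* is the dosage-weighted
sum over the eQTL model's SNPs, t̃_l = Σ_a w_a X_a, standardized per
column. The summary-level per-tissue association z-score is

    z_l ≈ Σ_a w_a (σ_a / σ_l) (β̂_a / se(β̂_a)),

with σ_a the reference-panel SNP standard deviation and
σ_l² = wᵀΓw the model's predicted-expression variance from the panel SNP
covariance Γ (computed with ddof=1, so the identity between σ_l² and the
realized column variance is exact, not asymptotic). Only SNPs present in
both the model and the GWAS are used.

The cross-tissue test eigendecomposes the tissue correlation matrix of the
standardized prediction matrix **T**, keeps eigenvalues with
max(λ)/λ < 30 (strict, matching the printed condition-number rule; ties at
the boundary are excluded), and forms standardized PC scores **P**. The
statistic is the sum of squared per-PC marginal association statistics —
algebraically the quadratic form ẑᵀCor(T)⁺ẑ restricted to the retained
PCs — and is referred to a χ² with k = retained-PC degrees of freedom.
Marginal statistics use a no-intercept regression on centered data
(residual df = n−1); at desk-scale cohort sizes (n = 2000) the difference
from df = n−2 is negligible and the null law holds to KS precision.
Zero-variance predicted-expression columns are dropped with a log entry.

## Projection

A genes-as-rows matrix **M** is projected into module space as

    M̂ = (ZᵀZ + λ₂ I)⁻¹ Zᵀ M,

solved by Cholesky factorization (never an explicit inverse). λ₂ is the
ridge penalty stored with the trained model; it may be overridden for
sensitivity analysis, including λ₂=0 when **Z** has full column rank.
Missing genes are zero-filled by default (a zero z-score is neutral in the
dot products); an `intersect` policy subsets **Z** instead. Inputs are
projected as given; any standardization is the caller's responsibility.

## Gene–gene correlation of association statistics

Under no association, each gene's cross-tissue statistic is ‖Pᵀy‖², whose
pairwise correlation across genes is

    R_ij = 2·Tr(C_ij C_ijᵀ) / (√(2k_i)·√(2k_j)),

where C_ij = diag(λ_i)^(−1/2) V_iᵀ Cor(T_i, T_j) V_j diag(λ_j)^(−1/2) is
the PC cross-correlation and Cor(T_i, T_j) comes entirely from prediction
weights and Γ. Because Γ is the realized panel covariance, the analytic
per-pair values equal their individual-level counterparts exactly; the
Monte-Carlo check (20 000 null phenotype draws) verifies the statistic-level
correlation to ±0.02.

Two properties of this construction matter downstream:

* R is nonnegative by design, so truly independent gene pairs receive a
  small positive sampling floor of order k/n (≈0.001 at n=2000). Over
  hundreds of member genes this floor makes the GLS slightly conservative.
* R is a null-hypothesis approximation for the summary-level statistic;
  the realized correlation of −log₁₀ p values tracks it closely (observed
  agreement ~0.002 at desk scale).

The regression consumes only the submatrix R_ℓ over an LV's member genes —
the top ceil(fraction·m) loadings, ties broken by larger loading then
lexicographic gene id. If R_ℓ is numerically indefinite it is shrunk
toward the identity, (1−δ)R_ℓ + δI, with the smallest
δ ∈ {1e-4, 1e-3, 1e-2, 1e-1} restoring a minimum eigenvalue of 1e-8; δ is
reported as `repair_delta` so users can exclude badly conditioned modules.

## Competitive module–trait regression

For one trait, m = −log₁₀(p) per gene (p clamped at 1e-300) is regressed
on an intercept, the binary member indicator s, and two technical
covariates — gene size (retained PCs k) and gene density (k over available
tissues) — with errors ε ~ MVN(0, σ²Σ), where Σ is R_ℓ on member genes,
identity elsewhere, zero cross-block. Estimation whitens the member block
by its Cholesky factor and solves ordinary least squares by QR; the
membership coefficient is tested one-sided (β_s > 0) against a Student-t
with df = genes − parameters, since σ² is estimated. Covariates are
standardized (β_s inference is unaffected); covariates that add no rank
(e.g. density proportional to size when every gene has the same tissue
count) are dropped with a log entry. Benjamini–Hochberg adjustment is
applied over all (LV, trait) tests by default, or per trait by
configuration.

### Calibration at desk scale

The −log₁₀ p errors are exponential, not Gaussian, so the one-sided test
carries a small positive skew bias that shrinks with the effective member
count; the sampling floor of R pushes the other way. The regression
scenario is sized so the two nearly cancel: 2400 genes in LD quartets
(latent correlation 0.8), ten LVs of 240 members (top fraction 0.1 — the
desk-scale counterpart of percent-level member sets over a full
transcriptome), 2000 individuals. At that size the measured type-I error
at α=0.05 is ≈0.050–0.056 over 5000 replicates, while replacing R_ℓ with
the identity on the correlated members inflates it to ≈0.13–0.16 — the
failure mode the correlation model exists to prevent. Replicates are drawn
across five independent scenario instances so the rate is not conditioned
on one realized panel.

## Drug repurposing by signature reversal

Raw score of a (compound, trait) pair in tissue t: the negative dot
product of the trait's signed z-profile and the compound's perturbation
profile over the shared gene (or LV) axis, after restricting each trait to
its k strongest associations (|z|, ties by larger |z| then lexicographic
gene id). Per tissue, raw scores are converted to within-trait compound
midranks, averaged over k ∈ {all, 50, 100, 250, 500} (genes) or
{all, 5, 10, 25, 50} (LVs), and the final matrix takes the per-pair
maximum over tissues — rank-average first, tissue-max second. Ranks are
computed within tissue across compounds per trait; this reading of the
aggregation order is recorded in the score provenance. Per-LV
contributions −(l̂·m̂) decompose the k=all LV-space raw score exactly.
Evaluation reports midrank AUROC and step-integrated average precision
against a user-supplied gold standard, with a permuted-score baseline
(mean and 2.5/97.5 percentiles over 100 permutations).

## Consensus clustering of traits

Preprocessing of the cross-tissue p-value matrix: probit transform
z = Φ⁻¹(1−p/2); optional Stouffer combination of duplicate traits,
Σw_i z_i / √(Σw_i²), with weights w = √(GWAS sample size) — the weight's
functional form is not pinned down externally, so √n is the default and n
is available; per-trait division by the column sum to damp highly
polygenic traits (combine first, then normalize, as given); then
projection into LV space.

Ensemble generation uses three representations — raw, PCA, UMAP, each
capped at min(50, n−1, d) components (UMAP seeded, which also forces a
single-threaded, reproducible layout) — and five algorithm families:
k-means, spectral clustering, Gaussian mixtures (each: k ∈ [2, ⌊√n⌋],
five seeded runs per k), agglomerative clustering (four linkages per k),
and DBSCAN over minPts ∈ {2,3,5,8,13,21,34,55,89,125} (a Fibonacci-style
subsample of 2..125 to bound runtime; values ≥ n are skipped) with ε at
the {10,30,50,70,90}th percentiles of the mean minPts-nearest-neighbor
distance — a deterministic rule standing in for "inspect the
distribution". DBSCAN noise points become singleton clusters (preserving
pairwise-disagreement semantics); partitions with one cluster or all
noise are dropped; DBSCAN partitions are resampled with replacement to the
mean count of the other four families per representation.

The ensemble is condensed into the disagreement matrix D (exact fraction
of partitions splitting each pair). For each k and each RBF bandwidth
γ ∈ {0.5, 1, 2, 5} / median(offdiagonal D²) (the reference implementation's
four empirical values are unpublished, so a scale-free grid is used),
spectral clustering of exp(−γD²) yields a candidate; the winner per k
maximizes the median adjusted Rand index against the whole ensemble.
Solutions whose agreement does not strictly exceed the 75th percentile
across k are discarded ("larger than" read strictly), and trait flows
between consecutive retained resolutions form the clustering-tree edges.

## Cluster interpretation

Per cluster, a depth-1 decision tree (impurity-based, classes weighted
inversely to frequency so small clusters can win the root) is fit on the
raw trait×LV matrix with cluster-vs-rest labels. The root LV and split
threshold are recorded; the LV is *selected* iff the threshold is positive
and exceeds one standard deviation (ddof=1) of that LV across all traits
— "one standard deviation" is read as the spread of the LV column, and
the matrix is used unstandardized. The root LV is removed regardless and
the fit repeats (20 iterations by default), so the root sequence is
duplicate-free. Only the root split is consumed, so capping depth at 1 is
behavior-identical to training a full tree and reading its root.

## Synthetic data

Generators are pure functions of (parameters, seed). Dosages come from
block-equicorrelated latent Gaussians thresholded at per-SNP MAF quantiles
(two haplotypes summed); the stated block correlation is the latent value
and realized dosage correlations are attenuated. Gene models draw SNPs
inside a single LD block, so block assignment controls cross-gene
correlation; weights are standard normal and tissue counts vary per gene.
Planted trait effects route through an LV: the phenotype is a
loading-weighted sum of member-gene predicted expression scaled to a
stated variance fraction (0.1 in the regression scenario, 0.3 in the drug
scenario) plus Gaussian noise. Planted reversal compounds get the negated,
standardized trait signature plus unit-variance noise (signature
correlation ≈ −0.7). Trait clusters elevate disjoint triplets of LVs by
four noise standard deviations across fifty traits.

What passing these studies shows: the algebra and the statistical
machinery behave as designed under their own assumptions at realistic
desk-scale sizes. What it does not show: robustness to real-data features
the generators omit — population structure, linkage beyond block
equicorrelation, non-Gaussian phenotypes, uneven GWAS power across traits,
assay artifacts in perturbation profiles, and ontology-mapping noise in
gold standards.

## Numerical choices

* Condition-number threshold 30 (strict); eigenvalues at numerical zero
  never retained.
* p-values clamped at 1e-300 before −log₁₀ (finite designs).
* SPD repair grid {1e-4, 1e-3, 1e-2, 1e-1}; minimum-eigenvalue tolerance 1e-8.
* Deterministic tie-breaks everywhere: larger value first, then
  lexicographic id (membership, top-k restriction); midranks in score
  ranking and AUROC.
* Text output at %.17g, so read∘write round-trips float64 exactly.
* All stochastic stages consume a `numpy` Generator seeded from the
  caller; derived seeds stay below 2³¹.

## Problem sizes used in the validation studies

Chosen as desk-scale counterparts of the method's operating regime: GLS
oracle, 100 random instances of 50–300 genes; calibration, 5000 null
replicates over five scenario instances (2400 genes each); correlation
check, 8 genes × 20 000 draws; null-law check, 2000 replicates; drug
recovery, 100 replicates of 150 genes × 20 compounds; consensus and
interpretation, 50 replicates of 50 traits × 30 LVs with matched
structureless controls.
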