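"""End-to-end validation studies on the synthetic scenarios.

Each function runs one self-contained study — generating its inputs from a
seed, executing the relevant pipeline stage, and measuring the outcome —
and returns a dict of plain numbers.  They are the single source of truth
for both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .containers import LabelledMatrix, RunConfig, top_lv_genes
from .correlation import build_correlation_matrix, lv_submatrix
from .clustering import (consensus, eac_distance, generate_ensemble,
                         make_representations)
from .interpretation import discriminative_lvs
from .projection import project
from .regression import (RegressionInput, _design_matrix, _member_indices,
                         gls_fit_batch)
from .repurposing import GENE_K_GRID, LV_K_GRID, score_pairs
from .simulate import (generate_panel, generate_models, scenario_drug_reversal,
                       scenario_regression, scenario_trait_clusters)
from .twas import predict_expression, reduce_pcs, smultixcan_batch, smultixcan_p

__all__ = [
    "gls_oracle_study",
    "null_calibration_study",
    "correlation_validity_study",
    "smultixcan_null_study",
    "projection_correctness_study",
    "drug_recovery_study",
    "consensus_study",
    "brute_force_rank_scores",
]


# ---------------------------------------------------------------------------
# GLS vs dense-covariance oracle

def _dense_gls_oracle(X: np.ndarray, y: np.ndarray, member_idx: np.ndarray,
                      R_l: np.ndarray) -> tuple[float, float]:
    """Closed-form GLS with the full dense block covariance (independent
    implementation: explicit inverse, no whitening)."""
    n, p = X.shape
    sigma = np.eye(n)
    sigma[np.ix_(member_idx, member_idx)] = R_l
    si = linalg.inv(sigma)
    A = linalg.inv(X.T @ si @ X)
    beta = A @ X.T @ si @ y
    r = y - X @ beta
    s2 = float(r @ si @ r) / (n - p)
    return float(beta[1]), float(np.sqrt(s2 * A[1, 1]))


def _random_spd_correlation(m: int, rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((m, m + 5))
    S = A @ A.T / (m + 5)
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def gls_oracle_study(seed: int, n_instances: int = 100) -> dict:
    """Whitened GLS vs an explicit-inverse oracle on random instances
    (50-300 genes, random SPD member correlation)."""
    rng = np.random.default_rng(seed)
    max_beta = max_se = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(50, 301))
        m = int(rng.integers(5, max(6, n // 5)))
        R_l = _random_spd_correlation(m, rng)
        member_idx = rng.choice(n, size=m, replace=False)
        s = np.zeros(n)
        s[member_idx] = 1.0
        cov = pd.DataFrame({"gene_size": rng.integers(1, 6, n).astype(float),
                            "gene_density": rng.uniform(0.2, 1.0, n)},
                           index=[f"g{i}" for i in range(n)])
        y = rng.standard_normal(n) + 0.3 * s
        inp = RegressionInput(m=y, s=s, covariates=cov,
                              gene_ids=list(cov.index), trait_id="t", lv_id="lv")
        X, names = _design_matrix(inp)
        res = gls_fit_batch(X, y[:, None], member_idx, R_l, names)
        beta_o, se_o = _dense_gls_oracle(X, y, member_idx, R_l)
        max_beta = max(max_beta, abs(float(res["beta_s"][0]) - beta_o))
        max_se = max(max_se, abs(float(res["se"][0]) - se_o))
    return {"max_abs_beta_diff": max_beta, "max_abs_se_diff": max_se,
            "n_instances": n_instances}


# ---------------------------------------------------------------------------
# null calibration of the competitive test

def null_calibration_study(seed: int, n_replicates: int = 5000,
                           n_instances: int = 5, alpha: float = 0.05) -> dict:
    """Type-I error of the one-sided competitive test on null phenotypes.

    The replicates are split over independent draws of the regression
    scenario (panel, models, loadings), so the rejection rate averages over
    instance-level variability as well as phenotype noise.  The same
    replicates are refit with the member correlation replaced by the
    identity, which reintroduces the inflation the correlation model
    prevents.
    """
    rng = np.random.default_rng(seed)
    per = n_replicates // n_instances
    rej_gls: list[np.ndarray] = []
    rej_id: list[np.ndarray] = []
    for _ in range(n_instances):
        sc = scenario_regression(int(rng.integers(0, 2 ** 31 - 1)),
                                 n_null_traits=0)
        members = top_lv_genes(sc.latent_model, "LV0", sc.fraction)
        corr = build_correlation_matrix(sc.models, sc.panel, None, members)
        sub = lv_submatrix(corr, sc.latent_model, "LV0", sc.fraction)
        pes = [reduce_pcs(predict_expression(sc.panel, sc.models, g))
               for g in sc.models.genes]
        Y = rng.standard_normal((sc.panel.n_individuals, per))
        pvals = smultixcan_batch(Y, pes)
        M = -np.log10(np.clip(pvals, 1e-300, None))
        gene_order = [pe.gene_id for pe in pes]
        meta = pd.DataFrame({"k": [pe.k for pe in pes],
                             "p": [pe.p for pe in pes]}, index=gene_order)
        from .regression import build_design
        inp = build_design(pd.Series(pvals[:, 0], index=gene_order),
                           sc.latent_model, "LV0", meta, fraction=sc.fraction)
        X, names = _design_matrix(inp)
        idx = _member_indices(inp, sub)
        rows = [gene_order.index(g) for g in inp.gene_ids]
        res = gls_fit_batch(X, M[rows, :], idx, sub.R, names)
        res_id = gls_fit_batch(X, M[rows, :], idx, np.eye(len(idx)), names)
        rej_gls.append(res["p_one_sided"] < alpha)
        rej_id.append(res_id["p_one_sided"] < alpha)
    return {"rejection_gls": float(np.concatenate(rej_gls).mean()),
            "rejection_identity": float(np.concatenate(rej_id).mean()),
            "n_replicates": per * n_instances, "alpha": alpha}


# ---------------------------------------------------------------------------
# analytic correlation vs Monte-Carlo statistics

def correlation_validity_study(seed: int, n_genes: int = 8,
                               n_draws: int = 20000) -> dict:
    """Analytic gene-gene correlation vs Monte-Carlo association statistics,
    plus the exactness of the weight-quadratic-form variance identity."""
    rng = np.random.default_rng(seed)
    panel = generate_panel(2000, 40, 10, 0.8, (0.1, 0.4),
                           int(rng.integers(0, 2 ** 31 - 1)))
    models = generate_models(panel, n_genes, 3, 2,
                             int(rng.integers(0, 2 ** 31 - 1)),
                             genes_per_block=2)
    genes = [f"g{i}" for i in range(n_genes)]
    corr = build_correlation_matrix(models, panel, None, genes)
    pes = [reduce_pcs(predict_expression(panel, models, g))
           for g in corr.gene_ids]
    Y = rng.standard_normal((panel.n_individuals, n_draws))
    Yc = Y - Y.mean(axis=0)
    ssm = np.stack([((pe.P.T @ Yc) ** 2).sum(axis=0) for pe in pes])
    R_mc = np.corrcoef(ssm)
    max_err = float(np.abs(corr.R - R_mc).max())
    # variance identity: realized column variance vs w' Gamma w
    gamma = panel.covariance
    var_err = 0.0
    for g in genes:
        for t in models.tissues(g):
            snps, w = models.weights(g, t)
            idx = panel.snp_index(snps)
            analytic = float(w @ gamma[np.ix_(idx, idx)] @ w)
            realized = float(np.var(panel.dosages[:, idx] @ w, ddof=1))
            var_err = max(var_err, abs(analytic - realized))
    return {"max_abs_R_error": max_err, "max_var_identity_error": var_err,
            "n_draws": n_draws, "n_genes": len(corr.gene_ids)}


# ---------------------------------------------------------------------------
# cross-tissue statistic null law

def smultixcan_null_study(seed: int, n_replicates: int = 2000) -> dict:
    """KS test of the cross-tissue association statistic against its
    chi-square null law with k = retained-PC degrees of freedom."""
    rng = np.random.default_rng(seed)
    panel = generate_panel(2000, 16, 4, 0.5, (0.1, 0.4),
                           int(rng.integers(0, 2 ** 31 - 1)))
    models = generate_models(panel, 1, 4, 2, int(rng.integers(0, 2 ** 31 - 1)),
                             genes_per_block=4)
    pe = reduce_pcs(predict_expression(panel, models, "g0"))
    stats_out = np.empty(n_replicates)
    for i in range(n_replicates):
        y = rng.standard_normal(panel.n_individuals)
        stat, k, _ = smultixcan_p(y, pe)
        stats_out[i] = stat
    ks = stats.kstest(stats_out, stats.chi2(pe.k).cdf)
    return {"ks_pvalue": float(ks.pvalue), "k": int(pe.k),
            "n_replicates": n_replicates}


# ---------------------------------------------------------------------------
# projection

def projection_correctness_study(seed: int) -> dict:
    """Normal-equation residual of the ridge projection plus the two exact
    special cases (identity loadings, orthonormal columns)."""
    rng = np.random.default_rng(seed)
    from .containers import LatentModel

    Z = np.abs(rng.standard_normal((40, 5))) + 0.05
    M = LabelledMatrix(rng.standard_normal((40, 7)),
                       [f"g{i}" for i in range(40)],
                       [f"t{j}" for j in range(7)])
    lam = 0.3
    model = LatentModel(Z, lam, [f"g{i}" for i in range(40)],
                        [f"LV{j}" for j in range(5)])
    proj = project(M, model)
    lhs = (Z.T @ Z + lam * np.eye(5)) @ proj.values
    rhs = Z.T @ M.values
    residual = float(np.abs(lhs - rhs).max())
    # identity loadings with the ridge overridden to zero: projection = input
    n = 6
    I_model = LatentModel(np.eye(n), 1.0, [f"g{i}" for i in range(n)],
                          [f"LV{j}" for j in range(n)])
    Mi = LabelledMatrix(rng.standard_normal((n, 3)),
                        [f"g{i}" for i in range(n)], ["a", "b", "c"])
    id_err = float(np.abs(project(Mi, I_model, lambda2=0.0).values
                          - Mi.values).max())
    # orthonormal columns (disjoint supports keep loadings nonnegative):
    # with a vanishing ridge the projection approaches Z^T M
    Q = np.zeros((20, 4))
    for j in range(4):
        block = np.abs(rng.standard_normal(5)) + 0.1
        Q[5 * j:5 * (j + 1), j] = block / np.linalg.norm(block)
    ortho_model = LatentModel(Q, 1.0, [f"g{i}" for i in range(20)],
                              [f"LV{j}" for j in range(4)])
    Mo = LabelledMatrix(rng.standard_normal((20, 3)),
                        [f"g{i}" for i in range(20)], ["a", "b", "c"])
    ortho_err = float(np.abs(project(Mo, ortho_model, lambda2=0.0).values
                             - Q.T @ Mo.values).max())
    return {"normal_eq_residual": residual, "identity_error": id_err,
            "orthonormal_error": ortho_err}


def drug_recovery_study(seed: int, n_replicates: int = 100) -> dict:
    """Planted-reversal recovery rate in gene and LV space."""
    rng = np.random.default_rng(seed)
    wins_gene = wins_lv = 0
    for _ in range(n_replicates):
        sc = scenario_drug_reversal(int(rng.integers(0, 2 ** 31 - 1)))
        trait = sc.truth.reversal_compounds[0][1]
        planted = sc.truth.reversal_compounds[0][0]
        g = score_pairs(sc.twas.tissue_z, sc.profiles, k_grid=GENE_K_GRID,
                        space="gene")
        if g.final.row_ids[int(np.argmax(g.final.col(trait)))] == planted:
            wins_gene += 1
        mt_lv = {t: project(m, sc.latent_model).as_labelled()
                 for t, m in sc.twas.tissue_z.items()}
        l_lv = project(sc.profiles, sc.latent_model).as_labelled()
        lv = score_pairs(mt_lv, l_lv, k_grid=LV_K_GRID, space="lv")
        if lv.final.row_ids[int(np.argmax(lv.final.col(trait)))] == planted:
            wins_lv += 1
    return {"recovery_gene": wins_gene / n_replicates,
            "recovery_lv": wins_lv / n_replicates,
            "n_replicates": n_replicates}


def brute_force_rank_scores(mt_by_tissue, profiles, k_grid) -> np.ndarray:
    """Independent small-case oracle for the rank-averaged, tissue-maximized
    scores: explicit loops, sorting-based midranks."""
    tissues = list(mt_by_tissue)
    compounds = list(profiles.col_ids)
    traits = list(mt_by_tissue[tissues[0]].col_ids)
    genes = list(profiles.row_ids)
    final = np.full((len(compounds), len(traits)), -np.inf)
    for tissue in tissues:
        mt = mt_by_tissue[tissue]
        acc = np.zeros((len(compounds), len(traits)))
        for k in k_grid:
            for jt, trait in enumerate(traits):
                col = [mt.values[i, jt] for i in range(len(genes))]
                if k == "all":
                    keep = set(range(len(genes)))
                else:
                    order = sorted(range(len(genes)),
                                   key=lambda i: (-abs(col[i]), genes[i]))
                    keep = set(order[:int(k)])
                raw = []
                for jc in range(len(compounds)):
                    v = -sum(profiles.values[i, jc] * col[i] for i in keep)
                    raw.append(v)
                # midranks: rank 1 = smallest value
                for jc in range(len(compounds)):
                    less = sum(1 for v in raw if v < raw[jc])
                    equal = sum(1 for v in raw if v == raw[jc])
                    acc[jc, jt] += less + (equal + 1) / 2
        final = np.maximum(final, acc / len(k_grid))
    return final


# ---------------------------------------------------------------------------
# consensus clustering + interpretation recovery

def consensus_study(seed: int, n_replicates: int = 50,
                    ari_threshold: float = 0.9,
                    interpretation_window: int = 5) -> dict:
    """Consensus recovery on planted clusters, paired null-structure control,
    and decision-stump recovery of the planted discriminative LVs.

    Each replicate runs the full ensemble/consensus pipeline on a structured
    draw and on a matched structureless draw (same dimensions, no planted
    separation), comparing the maximum ensemble agreement between the two.
    """
    from .clustering import ari as _ari

    rng = np.random.default_rng(seed)
    recovered = null_lower = interp_ok = 0
    for _ in range(n_replicates):
        s = int(rng.integers(0, 2 ** 31 - 1))
        mhat, truth, _ = scenario_trait_clusters(s, structured=True)
        reps = make_representations(mhat.values, seed=s)
        ens = generate_ensemble(reps, RunConfig(seed=s), seed=s)
        cons = consensus(eac_distance(ens), ens, range(2, 8), seed=s)
        labels_true = np.array([truth.cluster_labels[t] for t in mhat.row_ids])
        k_true = len(set(labels_true.tolist()))
        if _ari(cons.labels_for(k_true), labels_true) >= ari_threshold:
            recovered += 1
        agree = cons.solutions["agreement"].max()
        mhat0, _, _ = scenario_trait_clusters(s, structured=False)
        reps0 = make_representations(mhat0.values, seed=s)
        ens0 = generate_ensemble(reps0, RunConfig(seed=s), seed=s)
        cons0 = consensus(eac_distance(ens0), ens0, range(2, 8), seed=s)
        if cons0.solutions["agreement"].max() < agree:
            null_lower += 1
        ok = True
        for c, lvs in truth.cluster_lvs.items():
            report = discriminative_lvs(mhat, labels_true, c, iterations=20,
                                        seed=s)
            if not set(lvs) <= set(report.root_lvs[:interpretation_window]):
                ok = False
        interp_ok += ok
    return {"consensus_recovery": recovered / n_replicates,
            "null_agreement_lower": null_lower / n_replicates,
            "interpretation_recovery": interp_ok / n_replicates,
            "n_replicates": n_replicates}
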