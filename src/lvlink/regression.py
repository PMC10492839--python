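"""Competitive gene-set regression of LV membership on TWAS gene p-values.

For one trait and one LV, the model regresses the per-gene association
strength ``m = -log10(p)`` on a binary top-gene indicator ``s`` plus two
technical covariates (gene size: retained PCs; gene density: retained PCs
over available tissues), with correlated errors.  The error covariance is
block structured: the analytic correlation submatrix R_l over the LV's
member genes, identity elsewhere, zero cross-block — correlations are
accounted for among top genes only, which is conservative.  Estimation is
generalized least squares via Cholesky whitening of the member block; the
one-sided test of the membership coefficient (beta_s > 0) asks whether the
LV's top genes are more strongly trait-associated than the remaining genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .containers import LatentModel, TwasResultSet, RunConfig, top_lv_genes
from .correlation import LvSubCorrelation

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionInput",
    "LvTraitResult",
    "build_design",
    "gls_fit",
    "gls_fit_batch",
    "regress_all",
    "bh_adjust",
]

P_CLAMP = 1e-300


@dataclass
class RegressionInput:
    """Design pieces for one (trait, LV) competitive test."""

    m: np.ndarray                 # per-gene -log10 p
    s: np.ndarray                 # binary membership indicator
    covariates: pd.DataFrame      # gene_size, gene_density (per gene)
    gene_ids: list[str]
    trait_id: str
    lv_id: str


@dataclass
class LvTraitResult:
    lv_id: str
    trait_id: str
    beta_s: float
    se: float
    statistic: float
    p_one_sided: float
    n_genes: int
    n_members: int
    repair_delta: float
    fdr: float | None = None


def build_design(trait_pvals: pd.Series, model: LatentModel, lv_id: str,
                 gene_meta: pd.DataFrame, fraction: float = 0.01,
                 trait_id: str = "") -> RegressionInput:
    """Assemble the regression input for one trait and LV.

    ``trait_pvals`` maps gene id to the cross-tissue p-value; ``gene_meta``
    must be indexed by gene id with columns ``k`` (retained PCs) and ``p``
    (tissue count).  P-values are clamped at 1e-300 before the -log10
    transform so the design stays finite.
    """
    genes = [g for g in model.gene_ids if g in trait_pvals.index]
    if not genes:
        raise ValueError("no genes shared between p-values and the model")
    p = trait_pvals.loc[genes].to_numpy(dtype=float)
    if np.any((p <= 0) | (p > 1)):
        if np.any(p > 1) or np.any(p < 0):
            raise ValueError("p-values must lie in [0, 1]")
    m = -np.log10(np.clip(p, P_CLAMP, None))
    if np.allclose(m, m[0]):
        warnings.warn("all gene p-values identical: degenerate design",
                      stacklevel=2)
    members = set(top_lv_genes(model, lv_id, fraction))
    s = np.array([1.0 if g in members else 0.0 for g in genes])
    meta = gene_meta.loc[genes]
    cov = pd.DataFrame({
        "gene_size": meta["k"].to_numpy(dtype=float),
        "gene_density": (meta["k"] / meta["p"]).to_numpy(dtype=float),
    }, index=genes)
    if not np.all(np.isfinite(cov.to_numpy())):
        raise ValueError("non-finite covariates")
    return RegressionInput(m=m, s=s, covariates=cov, gene_ids=genes,
                           trait_id=trait_id, lv_id=lv_id)


def _design_matrix(inp: RegressionInput) -> tuple[np.ndarray, list[str]]:
    """[intercept, s, standardized covariates]; constant covariates dropped."""
    cols = [np.ones_like(inp.m), inp.s]
    names = ["intercept", "s"]
    for name in inp.covariates.columns:
        x = inp.covariates[name].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd <= 0:
            logger.info("covariate %s is constant; dropped from design", name)
            continue
        cand = (x - x.mean()) / sd
        # a covariate adding no rank (e.g. density proportional to size when
        # tissue counts are uniform) is dropped rather than breaking the fit
        trial = np.column_stack(cols + [cand])
        if np.linalg.matrix_rank(trial) <= len(cols):
            logger.info("covariate %s is collinear with the design; dropped", name)
            continue
        cols.append(cand)
        names.append(name)
    X = np.column_stack(cols)
    return X, names


def _member_indices(inp: RegressionInput, corr: LvSubCorrelation) -> np.ndarray:
    pos = {g: i for i, g in enumerate(inp.gene_ids)}
    try:
        return np.array([pos[g] for g in corr.gene_ids])
    except KeyError as exc:
        raise ValueError(f"member gene {exc.args[0]!r} missing from design") from None


def _whiten(arr: np.ndarray, idx: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Apply the block whitening transform: solve the member-block Cholesky,
    leave off-member rows untouched."""
    out = np.array(arr, dtype=float, copy=True)
    out[idx] = linalg.solve_triangular(L, arr[idx], lower=True)
    return out


def gls_fit_batch(X: np.ndarray, M: np.ndarray, member_idx: np.ndarray,
                  R_l: np.ndarray, names: list[str] | None = None
                  ) -> dict[str, np.ndarray]:
    """Whitened-OLS fit of many response columns against one design.

    ``M`` is genes x q responses.  Returns per-column beta_s, se, t and
    one-sided upper-tail p (Student-t with dof = genes - parameters).
    """
    n, npar = X.shape
    L = linalg.cholesky(R_l, lower=True)
    Xw = _whiten(X, member_idx, L)
    Mw = _whiten(M, member_idx, L)
    Q, Rq = np.linalg.qr(Xw)
    diag = np.abs(np.diag(Rq))
    if diag.min() < 1e-10 * max(diag.max(), 1.0):
        bad = int(np.argmin(diag))
        label = names[bad] if names else f"column {bad}"
        raise np.linalg.LinAlgError(f"design is rank deficient: collinear {label}")
    beta = linalg.solve_triangular(Rq, Q.T @ Mw, lower=False)
    resid = Mw - Xw @ beta
    dof = n - npar
    sigma2 = (resid ** 2).sum(axis=0) / dof
    XtXi = linalg.solve_triangular(
        Rq, linalg.solve_triangular(Rq, np.eye(npar), lower=False).T, lower=False)
    se = np.sqrt(sigma2 * XtXi[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    p = stats.t.sf(t, dof)
    return {"beta_s": beta[1], "se": se, "stat": t, "p_one_sided": p,
            "dof": dof, "beta": beta}


def gls_fit(inp: RegressionInput, corr: LvSubCorrelation) -> LvTraitResult:
    """Fit the competitive GLS model for one trait and LV."""
    X, names = _design_matrix(inp)
    idx = _member_indices(inp, corr)
    res = gls_fit_batch(X, inp.m[:, None], idx, corr.R, names)
    return LvTraitResult(
        lv_id=inp.lv_id, trait_id=inp.trait_id,
        beta_s=float(res["beta_s"][0]), se=float(res["se"][0]),
        statistic=float(res["stat"][0]), p_one_sided=float(res["p_one_sided"][0]),
        n_genes=len(inp.gene_ids), n_members=len(corr.gene_ids),
        repair_delta=corr.repair_delta,
    )


def bh_adjust(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, alpha=alpha, method="fdr_bh")[1]


def regress_all(twas: TwasResultSet, model: LatentModel,
                corrs: dict[str, LvSubCorrelation],
                config: RunConfig | None = None) -> pd.DataFrame:
    """Run the competitive test for every (LV, trait) pair.

    ``corrs`` maps LV id to its member-gene correlation submatrix; the
    design is built once per LV and fitted against all traits jointly.
    Adjusted p-values are computed over the configured family (all tests,
    or separately per trait).
    """
    config = config or RunConfig()
    pmat = twas.pvalues
    meta = twas.gene_meta
    if meta is None:
        raise ValueError("TWAS result set lacks gene metadata (k, p)")
    rows = []
    trait_ids = pmat.col_ids
    for lv_id, corr in corrs.items():
        inp0 = build_design(
            pd.Series(pmat.values[:, 0], index=pmat.row_ids), model, lv_id,
            meta, fraction=config.top_gene_fraction, trait_id=trait_ids[0])
        X, names = _design_matrix(inp0)
        idx = _member_indices(inp0, corr)
        gene_rows = [pmat.row_ids.index(g) for g in inp0.gene_ids]
        M = -np.log10(np.clip(pmat.values[gene_rows, :], P_CLAMP, None))
        res = gls_fit_batch(X, M, idx, corr.R, names)
        for j, trait in enumerate(trait_ids):
            rows.append({
                "lv": lv_id, "trait": trait,
                "beta": res["beta_s"][j], "se": res["se"][j],
                "stat": res["stat"][j], "pval": res["p_one_sided"][j],
                "n_members": len(corr.gene_ids),
                "repair_delta": corr.repair_delta,
            })
    table = pd.DataFrame(rows)
    if config.bh_family == "per-trait":
        table["fdr"] = table.groupby("trait")["pval"].transform(
            lambda p: bh_adjust(p.to_numpy(), config.fdr_alpha))
    else:
        table["fdr"] = bh_adjust(table["pval"].to_numpy(), config.fdr_alpha)
    return table
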