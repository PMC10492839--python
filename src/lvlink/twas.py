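"""Individual-level and summary-level TWAS primitives.

Predicted expression of a gene in a tissue is the weighted sum of SNP
dosages given by an eQTL prediction model.  The summary-level per-tissue
z-score approximates the individual-level association z using only GWAS
summary statistics and reference-panel variances.  The cross-tissue test
projects the per-gene predicted-expression matrix onto the principal
components retained under a condition-number threshold and sums squared
per-PC association statistics, which under the null follows a chi-square
with as many degrees of freedom as retained PCs.

These routines both generate realistic synthetic inputs and serve as the
individual-level oracle against which the analytic gene-correlation model
is validated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypePanel",
    "PredictionModelSet",
    "PredictedExpression",
    "predict_expression",
    "reduce_pcs",
    "spredixcan_z",
    "smultixcan_p",
    "smultixcan_batch",
    "retain_by_condition_number",
]


@dataclass
class GenotypePanel:
    """Reference-panel dosages (individuals x SNPs, on the 0-2 scale).

    ``snp_blocks`` optionally records the LD-block partition of the SNPs
    (used by the synthetic generators to control cross-gene correlation).
    """

    dosages: np.ndarray
    snp_ids: list[str]
    snp_blocks: list[list[str]] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if len(self.snp_ids) != self.dosages.shape[1]:
            raise ValueError("snp_ids length does not match dosage columns")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @cached_property
    def covariance(self) -> np.ndarray:
        """SNP covariance (X - mean)^T (X - mean) / (n - 1)."""
        return np.cov(self.dosages, rowvar=False, ddof=1)

    def snp_index(self, snp_ids: list[str]) -> np.ndarray:
        try:
            return np.array([self._index[s] for s in snp_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"SNP {exc.args[0]!r} not in panel") from None


@dataclass
class PredictionModelSet:
    """Per-(gene, tissue) eQTL weight tables.

    Stored as a long-format table with columns (gene, tissue, snp_id, weight);
    accessors return the sparse weight vector of a single tissue model.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "tissue", "snp_id", "weight"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"model table needs columns {sorted(required)}")
        self.table = self.table.reset_index(drop=True)
        self._by_model = {
            key: grp for key, grp in self.table.groupby(["gene", "tissue"], sort=False)
        }
        self._tissues: dict[str, list[str]] = {}
        for gene, tissue in self._by_model:
            self._tissues.setdefault(gene, []).append(tissue)

    @property
    def genes(self) -> list[str]:
        return list(self._tissues)

    def tissues(self, gene: str) -> list[str]:
        return list(self._tissues.get(gene, []))

    def weights(self, gene: str, tissue: str,
                snp_filter: set[str] | None = None) -> tuple[list[str], np.ndarray]:
        """(snp_ids, weights) of one tissue model, optionally SNP-filtered."""
        grp = self._by_model.get((gene, tissue))
        if grp is None:
            raise KeyError(f"no model for gene {gene!r}, tissue {tissue!r}")
        if snp_filter is not None:
            grp = grp[grp["snp_id"].isin(snp_filter)]
        return list(grp["snp_id"]), grp["weight"].to_numpy(dtype=float)

    @classmethod
    def read_tsv(cls, path) -> "PredictionModelSet":
        return cls(pd.read_csv(path, sep="\t", dtype={"gene": str, "tissue": str,
                                                      "snp_id": str}))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class PredictedExpression:
    """Per-gene predicted expression across tissues, before/after PC reduction.

    ``T`` holds standardized columns (mean 0, sd 1 with ddof=1); after
    :func:`reduce_pcs`, ``V`` (tissues x k), ``lam`` (k eigenvalues of the
    tissue correlation matrix, descending) and ``P`` (standardized PC scores)
    are populated and ``k`` is set.
    """

    gene_id: str
    tissue_ids: list[str]
    T: np.ndarray
    raw_sd: np.ndarray
    dropped_tissues: list[str] = field(default_factory=list)
    V: np.ndarray | None = None
    lam: np.ndarray | None = None
    P: np.ndarray | None = None
    k: int | None = None

    @property
    def p(self) -> int:
        return self.T.shape[1]

    @property
    def n(self) -> int:
        return self.T.shape[0]


def predict_expression(panel: GenotypePanel, models: PredictionModelSet,
                       gene: str,
                       snp_filter: set[str] | None = None) -> PredictedExpression:
    """Build the individuals-by-tissues predicted-expression matrix of a gene.

    Each tissue column is the dosage-weighted sum over the model's SNPs,
    then standardized.  Zero-variance columns are dropped with a log entry.
    """
    cols, ids, sds, dropped = [], [], [], []
    for tissue in models.tissues(gene):
        snps, w = models.weights(gene, tissue, snp_filter)
        if len(snps) == 0:
            dropped.append(tissue)
            continue
        t_raw = panel.dosages[:, panel.snp_index(snps)] @ w
        sd = np.std(t_raw, ddof=1)
        if sd <= 0 or not np.isfinite(sd):
            logger.info("gene %s tissue %s: zero-variance prediction dropped",
                        gene, tissue)
            dropped.append(tissue)
            continue
        cols.append((t_raw - t_raw.mean()) / sd)
        ids.append(tissue)
        sds.append(sd)
    if not cols:
        raise ValueError(f"gene {gene!r}: no usable tissue model")
    return PredictedExpression(gene_id=gene, tissue_ids=ids,
                               T=np.column_stack(cols),
                               raw_sd=np.asarray(sds), dropped_tissues=dropped)


def retain_by_condition_number(lam: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of eigenvalues kept under ``max(lam)/lam < threshold`` (strict).

    Eigenvalues at or below numerical zero are never kept.
    """
    lam = np.asarray(lam, dtype=float)
    tol = 1e-12 * max(lam.max(), 1.0)
    keep = (lam > tol) & (lam.max() / np.maximum(lam, tol) < threshold)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("all eigenvalues below numeric tolerance")
    return idx


def reduce_pcs(pe: PredictedExpression, threshold: float = 30.0) -> PredictedExpression:
    """Project predicted expression onto the retained principal components.

    Eigendecomposes the tissue correlation matrix of ``T``; keeps components
    whose eigenvalue ratio to the largest is strictly below ``threshold``;
    PC score columns are standardized.  Pure function of ``pe.T``, hence
    idempotent.
    """
    n = pe.n
    cor = pe.T.T @ pe.T / (n - 1)
    lam, vec = np.linalg.eigh(cor)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    idx = retain_by_condition_number(lam, threshold)
    lam_k, V_k = lam[idx], vec[:, idx]
    P = pe.T @ V_k / np.sqrt(lam_k)
    P = (P - P.mean(axis=0)) / np.std(P, axis=0, ddof=1)
    return PredictedExpression(gene_id=pe.gene_id, tissue_ids=pe.tissue_ids,
                               T=pe.T, raw_sd=pe.raw_sd,
                               dropped_tissues=pe.dropped_tissues,
                               V=V_k, lam=lam_k, P=P, k=int(idx.size))


def spredixcan_z(gwas: pd.DataFrame, models: PredictionModelSet,
                 panel: GenotypePanel, gene: str, tissue: str) -> float | None:
    """Summary-statistics per-tissue association z-score.

    ``gwas`` must have columns (snp_id, beta, se); only SNPs present in both
    the model and the GWAS are used.  Returns ``None`` (with a log entry)
    when the filtered model has zero predicted-expression variance.
    """
    gwas = gwas.set_index("snp_id") if "snp_id" in gwas.columns else gwas
    snps, w = models.weights(gene, tissue, set(gwas.index))
    if len(snps) == 0:
        logger.info("gene %s tissue %s: no model SNPs in GWAS, skipped", gene, tissue)
        return None
    idx = panel.snp_index(snps)
    gamma = panel.covariance[np.ix_(idx, idx)]
    var_l = float(w @ gamma @ w)
    if var_l <= 0:
        logger.info("gene %s tissue %s: zero predicted-expression variance, skipped",
                    gene, tissue)
        return None
    sigma_a = np.sqrt(np.diag(gamma))
    beta = gwas.loc[snps, "beta"].to_numpy(dtype=float)
    se = gwas.loc[snps, "se"].to_numpy(dtype=float)
    return float(np.sum(w * sigma_a / np.sqrt(var_l) * beta / se))


def _marginal_z(y: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Association z (= t statistic) of centered y on each standardized column.

    No-intercept regression on centered data; residual df = n - 1.
    """
    n = y.shape[0]
    y = y - y.mean()
    r = cols.T @ y / np.sqrt((cols ** 2).sum(axis=0) * (y @ y))
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    return r * np.sqrt((n - 1) / (1 - r ** 2))


def smultixcan_p(y: np.ndarray, pe: PredictedExpression) -> tuple[float, int, float]:
    """Cross-tissue association statistic, degrees of freedom, and p-value.

    The statistic is the squared-norm of per-PC marginal association
    statistics, equal to the z-vector quadratic form with the pseudo-inverse
    tissue correlation restricted to the retained PCs.  Under no association
    it follows a chi-square with ``k`` degrees of freedom.
    """
    if pe.P is None or pe.k is None:
        raise ValueError("predicted expression must be PC-reduced first")
    y = np.asarray(y, dtype=float)
    if y.shape[0] != pe.n:
        raise ValueError("phenotype length does not match panel")
    if y.shape[0] <= pe.k:
        raise ValueError("sample size must exceed the number of retained PCs")
    z = _marginal_z(y, pe.P)
    stat = float(z @ z)
    return stat, pe.k, float(stats.chi2.sf(stat, pe.k))


def smultixcan_batch(Y: np.ndarray, pes: list[PredictedExpression]) -> np.ndarray:
    """Cross-tissue p-values for many phenotypes at once.

    ``Y`` is individuals x traits.  Returns a genes x traits p-value matrix,
    numerically identical to calling :func:`smultixcan_p` per (gene, trait)
    but with the per-PC statistics computed in one matrix product.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    P_all = np.column_stack([pe.P for pe in pes])
    ks = np.array([pe.k for pe in pes])
    if np.any(n <= ks):
        raise ValueError("sample size must exceed the number of retained PCs")
    Yc = Y - Y.mean(axis=0)
    norms = np.sqrt((P_all ** 2).sum(axis=0))[:, None] * \
        np.sqrt((Yc ** 2).sum(axis=0))[None, :]
    r = np.clip(P_all.T @ Yc / norms, -1 + 1e-15, 1 - 1e-15)
    z2 = r ** 2 * (n - 1) / (1 - r ** 2)
    bounds = np.concatenate([[0], np.cumsum(ks)])
    pvals = np.empty((len(pes), Y.shape[1]))
    for i, pe in enumerate(pes):
        stat = z2[bounds[i]:bounds[i + 1], :].sum(axis=0)
        pvals[i, :] = stats.chi2.sf(stat, pe.k)
    return pvals
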