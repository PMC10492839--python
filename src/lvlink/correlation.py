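"""Analytic gene-gene correlation of TWAS association statistics.

Under no association, each gene's cross-tissue association statistic is a
quadratic form in its retained predicted-expression PCs; the correlation
between the model sums of squares (SSM) of two genes is

    R_ij = 2 Tr(C_ij C_ij^T) / (sqrt(2 k_i) sqrt(2 k_j)),

where ``C_ij`` is the PC cross-correlation matrix.  All quantities derive
from eQTL prediction weights and the reference-panel SNP covariance, so R
can be assembled without individual-level phenotypes.  The per-LV submatrix
R_l over an LV's member genes is what the regression stage consumes, with a
small identity shrinkage applied when numerically indefinite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import h5py
import numpy as np

from .containers import LatentModel, top_lv_genes
from .twas import GenotypePanel, PredictionModelSet, retain_by_condition_number

logger = logging.getLogger(__name__)

__all__ = [
    "GeneCorrelation",
    "LvSubCorrelation",
    "cross_gene_tissue_correlation",
    "pc_cross_correlation",
    "ssm_correlation",
    "build_correlation_matrix",
    "lv_submatrix",
]

_REPAIR_DELTAS = (1e-4, 1e-3, 1e-2, 1e-1)
_SPD_TOL = 1e-8


@dataclass
class GeneCorrelation:
    """Symmetric unit-diagonal gene-gene SSM correlation matrix."""

    R: np.ndarray
    gene_ids: list[str]
    k: dict[str, int]
    p: dict[str, int]

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        n = len(self.gene_ids)
        if self.R.shape != (n, n):
            raise ValueError("R shape does not match gene id count")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValueError("R is not symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-8):
            raise ValueError("R diagonal deviates from 1")
        if np.any(np.abs(self.R) > 1 + 1e-8):
            raise ValueError("R has entries beyond [-1, 1]")

    def save_h5(self, path) -> None:
        genes = np.array(self.gene_ids, dtype="S")
        with h5py.File(path, "w") as fh:
            fh.create_dataset("R", data=self.R)
            fh.create_dataset("gene_ids", data=genes)
            fh.create_dataset("k", data=np.array([self.k[g] for g in self.gene_ids]))
            fh.create_dataset("p", data=np.array([self.p[g] for g in self.gene_ids]))

    @classmethod
    def load_h5(cls, path) -> "GeneCorrelation":
        with h5py.File(path, "r") as fh:
            genes = [g.decode() for g in fh["gene_ids"][...]]
            k = dict(zip(genes, (int(v) for v in fh["k"][...])))
            p = dict(zip(genes, (int(v) for v in fh["p"][...])))
            return cls(fh["R"][...], genes, k, p)


@dataclass
class LvSubCorrelation:
    """Correlation submatrix over an LV's member genes, SPD-repaired if needed."""

    lv_id: str
    gene_ids: list[str]
    R: np.ndarray
    repair_delta: float = 0.0


@dataclass
class _AnalyticGene:
    """Eigen-structure of one gene's analytic tissue correlation matrix."""

    gene_id: str
    tissue_ids: list[str]
    sd: np.ndarray          # per-tissue predicted-expression sd, unfiltered scale
    V: np.ndarray           # tissues x k eigenvectors
    lam: np.ndarray         # k eigenvalues, descending
    k: int = field(init=False)
    p: int = field(init=False)

    def __post_init__(self) -> None:
        self.k = int(self.lam.size)
        self.p = len(self.tissue_ids)


def _filtered_weights(models: PredictionModelSet, panel: GenotypePanel,
                      gene: str, tissue: str, snp_filter: set[str] | None):
    snps, w = models.weights(gene, tissue, snp_filter)
    if len(snps) == 0:
        return None, None
    return panel.snp_index(snps), w


def cross_gene_tissue_correlation(models: PredictionModelSet, panel: GenotypePanel,
                                  gene_i: str, tissue_k: str,
                                  gene_j: str, tissue_l: str,
                                  snp_filter: set[str] | None = None) -> float:
    """Correlation between two predicted-expression columns, from weights and
    the reference-panel SNP covariance."""
    gamma = panel.covariance
    idx_k, w_k = _filtered_weights(models, panel, gene_i, tissue_k, snp_filter)
    idx_l, w_l = _filtered_weights(models, panel, gene_j, tissue_l, snp_filter)
    if idx_k is None or idx_l is None:
        raise ValueError("tissue model empty after SNP filtering")
    var_k = float(w_k @ gamma[np.ix_(idx_k, idx_k)] @ w_k)
    var_l = float(w_l @ gamma[np.ix_(idx_l, idx_l)] @ w_l)
    if var_k <= 0 or var_l <= 0:
        raise ValueError("zero predicted-expression variance: correlation undefined")
    cov = float(w_k @ gamma[np.ix_(idx_k, idx_l)] @ w_l)
    return cov / math.sqrt(var_k * var_l)


def pc_cross_correlation(pe_i, pe_j, cross: np.ndarray) -> np.ndarray:
    """PC cross-correlation ``diag(lam_i)^{-1/2} V_i^T cross V_j diag(lam_j)^{-1/2}``.

    ``pe_i``/``pe_j`` are PC-reduced genes (individual-level or analytic)
    exposing ``V`` (tissues x k) and ``lam``; ``cross`` is the tissue-by-tissue
    correlation block between the two genes.
    """
    if pe_i.V is None or pe_j.V is None:
        raise ValueError("genes must be PC-reduced")
    cross = np.asarray(cross, dtype=float)
    if cross.shape != (pe_i.V.shape[0], pe_j.V.shape[0]):
        raise ValueError(
            f"cross block shape {cross.shape} does not match tissue counts "
            f"({pe_i.V.shape[0]}, {pe_j.V.shape[0]})"
        )
    return (pe_i.V / np.sqrt(pe_i.lam)).T @ cross @ (pe_j.V / np.sqrt(pe_j.lam))


def ssm_correlation(C_ij: np.ndarray) -> float:
    """SSM correlation from a PC cross-correlation block."""
    C_ij = np.asarray(C_ij, dtype=float)
    k_i, k_j = C_ij.shape
    if k_i == 0 or k_j == 0:
        raise ValueError("empty PC cross-correlation block")
    if not np.all(np.isfinite(C_ij)):
        raise ValueError("non-finite PC cross-correlation")
    return float(2.0 * np.sum(C_ij * C_ij) /
                 (math.sqrt(2 * k_i) * math.sqrt(2 * k_j)))


def _analytic_gene(models: PredictionModelSet, panel: GenotypePanel, gene: str,
                   snp_filter: set[str] | None,
                   threshold: float) -> _AnalyticGene | None:
    gamma = panel.covariance
    tissues, idxs, ws, sds = [], [], [], []
    for tissue in models.tissues(gene):
        idx, w = _filtered_weights(models, panel, gene, tissue, snp_filter)
        if idx is None:
            continue
        var = float(w @ gamma[np.ix_(idx, idx)] @ w)
        if var <= 0:
            logger.info("gene %s tissue %s: zero variance, tissue dropped", gene, tissue)
            continue
        tissues.append(tissue)
        idxs.append(idx)
        ws.append(w)
        sds.append(math.sqrt(var))
    if not tissues:
        return None
    p = len(tissues)
    cor = np.eye(p)
    for a in range(p):
        for b in range(a + 1, p):
            cov = float(ws[a] @ gamma[np.ix_(idxs[a], idxs[b])] @ ws[b])
            cor[a, b] = cor[b, a] = cov / (sds[a] * sds[b])
    lam, vec = np.linalg.eigh(cor)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    keep = retain_by_condition_number(lam, threshold)
    gene_obj = _AnalyticGene(gene_id=gene, tissue_ids=tissues,
                             sd=np.asarray(sds), V=vec[:, keep], lam=lam[keep])
    gene_obj._idxs = idxs  # type: ignore[attr-defined]
    gene_obj._ws = ws      # type: ignore[attr-defined]
    return gene_obj


def build_correlation_matrix(models: PredictionModelSet, panel: GenotypePanel,
                             gwas_snps: set[str] | None, genes: list[str],
                             pc_condition_threshold: float = 30.0) -> GeneCorrelation:
    """Assemble the full gene-gene SSM correlation matrix.

    Only SNPs present in ``gwas_snps`` (when given) are used, mirroring the
    restriction to SNPs shared between the prediction models and the GWAS.
    Genes without any usable tissue model are dropped with a log entry.
    The diagonal is forced to exactly 1 and the matrix is symmetric by
    construction.
    """
    gamma = panel.covariance
    reduced: list[_AnalyticGene] = []
    for gene in genes:
        obj = _analytic_gene(models, panel, gene, gwas_snps, pc_condition_threshold)
        if obj is None:
            logger.info("gene %s: no usable model, dropped from correlation matrix", gene)
            continue
        reduced.append(obj)
    if not reduced:
        raise ValueError("no genes with usable models")
    m = len(reduced)
    R = np.eye(m)
    for a in range(m):
        ga = reduced[a]
        for b in range(a + 1, m):
            gb = reduced[b]
            cross = np.empty((ga.p, gb.p))
            for s in range(ga.p):
                for t in range(gb.p):
                    cov = float(ga._ws[s] @ gamma[np.ix_(ga._idxs[s], gb._idxs[t])]
                                @ gb._ws[t])
                    cross[s, t] = cov / (ga.sd[s] * gb.sd[t])
            C = pc_cross_correlation(ga, gb, cross)
            R[a, b] = R[b, a] = ssm_correlation(C)
    ids = [g.gene_id for g in reduced]
    return GeneCorrelation(R=R, gene_ids=ids,
                           k={g.gene_id: g.k for g in reduced},
                           p={g.gene_id: g.p for g in reduced})


def lv_submatrix(corr: GeneCorrelation, model: LatentModel, lv_id: str,
                 top_gene_fraction: float = 0.01) -> LvSubCorrelation:
    """Extract the correlation submatrix over an LV's member genes.

    Members are the top ``ceil(fraction * n_genes)`` loadings (deterministic
    tie-break).  If the submatrix's smallest eigenvalue is below 1e-8 it is
    shrunk toward the identity, ``(1-d) R_l + d I``, with the smallest repair
    ``d`` from {1e-4, 1e-3, 1e-2, 1e-1} that restores positive definiteness.
    """
    members = [g for g in top_lv_genes(model, lv_id, top_gene_fraction)
               if g in set(corr.gene_ids)]
    if len(members) < 2:
        raise ValueError(f"LV {lv_id!r}: fewer than 2 member genes with correlations")
    pos = {g: i for i, g in enumerate(corr.gene_ids)}
    idx = np.array([pos[g] for g in members])
    R_l = corr.R[np.ix_(idx, idx)].copy()
    delta = 0.0
    if np.linalg.eigvalsh(R_l).min() < _SPD_TOL:
        for d in _REPAIR_DELTAS:
            cand = (1 - d) * R_l + d * np.eye(len(members))
            if np.linalg.eigvalsh(cand).min() >= _SPD_TOL:
                R_l, delta = cand, d
                break
        else:
            raise np.linalg.LinAlgError(
                f"LV {lv_id!r}: submatrix not repairable to positive definite")
        logger.info("LV %s: correlation submatrix repaired with delta=%g", lv_id, delta)
    return LvSubCorrelation(lv_id=lv_id, gene_ids=members, R=R_l, repair_delta=delta)
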