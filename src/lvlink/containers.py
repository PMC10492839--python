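"""Core in-memory containers shared across the package.

All matrices that enter a projection are oriented genes-as-rows with
entities (traits, compounds, tissues) as columns; the ``orientation``
attribute of :class:`LabelledMatrix` records how a file was laid out on
disk.  A :class:`LatentModel` holds the nonnegative gene-by-module loading
matrix ``Z`` that defines the shared latent coordinate system, together
with the ridge penalty used when the model was trained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabelledMatrix",
    "LatentModel",
    "RunConfig",
    "TwasResultSet",
    "top_lv_genes",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicate {what}: {', '.join(dups)}")
    return ids


@dataclass
class LabelledMatrix:
    """A dense 2-D array with ordered, unique row and column identifiers."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    orientation: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        self.row_ids = _check_unique(self.row_ids, "row ids")
        self.col_ids = _check_unique(self.col_ids, "column ids")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match id counts "
                f"({len(self.row_ids)}, {len(self.col_ids)})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, orientation: str | None = None) -> "LabelledMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)),
                   list(df.columns.astype(str)), orientation=orientation)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def transpose(self) -> "LabelledMatrix":
        return LabelledMatrix(self.values.T.copy(), list(self.col_ids),
                              list(self.row_ids), orientation=self.orientation)

    def col(self, col_id: str) -> np.ndarray:
        return self.values[:, self.col_ids.index(col_id)]

    def row(self, row_id: str) -> np.ndarray:
        return self.values[self.row_ids.index(row_id), :]


@dataclass
class LatentModel:
    """A trained gene-module model: nonnegative loadings plus the training ridge penalty.

    ``Z`` is genes-by-LVs; every entry must be nonnegative (the factorization
    that produces these models constrains loadings to be positive) and no LV
    column may be entirely zero.  ``lambda2`` is the ridge penalty applied to
    the latent sample matrix during training; projections of new data reuse it.
    ``B`` optionally carries the LV-by-sample latent activities from training.
    """

    Z: np.ndarray
    lambda2: float
    gene_ids: list[str]
    lv_ids: list[str]
    B: np.ndarray | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2:
            raise ValueError("Z must be 2-D (genes x LVs)")
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.lv_ids = _check_unique(self.lv_ids, "LV ids")
        if self.Z.shape != (len(self.gene_ids), len(self.lv_ids)):
            raise ValueError("Z shape does not match gene/LV id counts")
        if not np.isfinite(self.lambda2) or self.lambda2 <= 0:
            raise ValueError("lambda2 must be a positive scalar")
        if np.any(self.Z < 0):
            bad = np.argwhere(self.Z < 0)[0]
            raise ValueError(
                "negative loading at gene "
                f"{self.gene_ids[bad[0]]!r}, LV {self.lv_ids[bad[1]]!r}: "
                "loadings must be nonnegative"
            )
        zero = np.flatnonzero(~self.Z.any(axis=0))
        if zero.size:
            raise ValueError(
                "all-zero LV columns: " + ", ".join(self.lv_ids[i] for i in zero)
            )
        if self.B is not None:
            self.B = np.asarray(self.B, dtype=float)
            if self.B.shape[0] != len(self.lv_ids):
                raise ValueError("B must have one row per LV")
            if self.sample_ids is None:
                self.sample_ids = [f"s{i}" for i in range(self.B.shape[1])]
            self.sample_ids = _check_unique(self.sample_ids, "sample ids")
            if len(self.sample_ids) != self.B.shape[1]:
                raise ValueError("sample id count does not match B columns")

    @property
    def n_genes(self) -> int:
        return self.Z.shape[0]

    @property
    def n_lvs(self) -> int:
        return self.Z.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "LatentModel":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return LatentModel(self.Z[rows, :].copy(), self.lambda2,
                           list(gene_ids), list(self.lv_ids),
                           B=self.B, sample_ids=self.sample_ids)


def top_lv_genes(model: LatentModel, lv_id: str, fraction: float) -> list[str]:
    """Member genes of an LV: the top ``ceil(fraction * n_genes)`` by loading.

    Ties are broken by larger loading first, then lexicographic gene id, so
    membership is deterministic.  This single rule defines the gene set used
    both for the correlation submatrix and for the regression indicator.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    j = model.lv_ids.index(lv_id)
    loadings = model.Z[:, j]
    n = math.ceil(fraction * model.n_genes)
    order = sorted(range(model.n_genes),
                   key=lambda i: (-loadings[i], model.gene_ids[i]))
    return [model.gene_ids[i] for i in order[:n]]


@dataclass
class RunConfig:
    """Tunable knobs shared across pipeline stages, with validated defaults."""

    seed: int = 0
    top_gene_fraction: float = 0.01
    pc_condition_threshold: float = 30.0
    fdr_alpha: float = 0.05
    # drug scoring: per-trait gene/LV counts over which score ranks are averaged
    gene_k_grid: tuple = ("all", 50, 100, 250, 500)
    lv_k_grid: tuple = ("all", 5, 10, 25, 50)
    # ensemble generation
    n_algo_seeds: int = 5
    linkages: tuple = ("ward", "complete", "average", "single")
    minpts_grid: tuple = (2, 3, 5, 8, 13, 21, 34, 55, 89, 125)
    eps_quantiles: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)
    # consensus: RBF gamma grid as multiples of 1/median(offdiag D^2)
    gamma_factors: tuple = (0.5, 1.0, 2.0, 5.0)
    bh_family: str = "all"  # or "per-trait"

    def __post_init__(self) -> None:
        if not (0 < self.top_gene_fraction <= 1):
            raise ValueError("top_gene_fraction must be in (0, 1]")
        if self.pc_condition_threshold <= 1:
            raise ValueError("pc_condition_threshold must exceed 1")
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must be in (0, 1)")
        for name in ("gene_k_grid", "lv_k_grid", "linkages", "minpts_grid",
                     "eps_quantiles", "gamma_factors"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if self.bh_family not in ("all", "per-trait"):
            raise ValueError("bh_family must be 'all' or 'per-trait'")


@dataclass
class TwasResultSet:
    """Gene-trait association results: cross-tissue p-values plus per-tissue z-scores.

    ``pvalues`` is genes-by-traits; ``tissue_z`` maps tissue name to a
    genes-by-traits matrix of signed z-scores; ``gene_meta`` carries, per gene,
    the number of principal components retained (``k``) and the number of
    tissues with a usable prediction model (``p``).
    """

    pvalues: LabelledMatrix
    tissue_z: Mapping[str, LabelledMatrix] = field(default_factory=dict)
    gene_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for t, m in self.tissue_z.items():
            if m.col_ids != self.pvalues.col_ids:
                raise ValueError(f"tissue {t!r} traits differ from p-value matrix")

    @property
    def gene_ids(self) -> list[str]:
        return self.pvalues.row_ids

    @property
    def trait_ids(self) -> list[str]:
        return self.pvalues.col_ids
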