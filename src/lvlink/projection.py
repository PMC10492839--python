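"""Ridge projection of gene-rows matrices into the latent gene-module space.

Given loadings Z (genes x LVs) and the training ridge penalty, a new
genes-by-entities matrix M is represented in module coordinates as
``(Z^T Z + lambda2 I)^{-1} Z^T M``, solved as a symmetric positive-definite
linear system rather than by explicit inversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .containers import LabelledMatrix, LatentModel
from .io import align_genes

__all__ = ["ProjectedMatrix", "project"]


@dataclass
class ProjectedMatrix:
    """LV-by-entity coordinates of a projected matrix, with provenance."""

    values: np.ndarray
    lv_ids: list[str]
    entity_ids: list[str]
    provenance: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.lv_ids), len(self.entity_ids)):
            raise ValueError("shape does not match LV/entity id counts")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("projected matrix contains non-finite entries")

    def as_labelled(self) -> LabelledMatrix:
        return LabelledMatrix(self.values, list(self.lv_ids), list(self.entity_ids))


def project(m: LabelledMatrix, model: LatentModel, policy: str = "zero_fill",
            lambda2: float | None = None) -> ProjectedMatrix:
    """Project a genes-as-rows matrix into LV space.

    ``lambda2`` defaults to the model's training penalty; it may be
    overridden for sensitivity analysis.  With ``policy='intersect'`` the
    loading matrix is subset to the shared genes before solving.
    """
    lam = model.lambda2 if lambda2 is None else float(lambda2)
    aligned = align_genes(m, model, policy=policy)
    if policy == "intersect" and aligned.row_ids != model.gene_ids:
        model = model.subset_genes(aligned.row_ids)
    Z = model.Z
    A = Z.T @ Z + lam * np.eye(model.n_lvs)
    try:
        c, low = linalg.cho_factor(A)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "Z^T Z + lambda2 I is numerically singular; use lambda2 > 0"
        ) from exc
    values = linalg.cho_solve((c, low), Z.T @ aligned.values)
    return ProjectedMatrix(
        values=values,
        lv_ids=list(model.lv_ids),
        entity_ids=list(aligned.col_ids),
        provenance={"policy": policy, "lambda2": lam,
                    "source_shape": list(m.shape)},
    )
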