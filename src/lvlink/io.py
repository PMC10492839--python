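"""Readers and writers for labelled matrices and latent-model bundles.

On-disk formats are plain tab-separated text (optionally gzip-compressed)
with one header row and one id column.  A latent-model bundle is a directory
with ``loadings.tsv[.gz]`` (genes x LVs), ``meta.yaml`` (at least ``lambda2``)
and an optional ``B.tsv[.gz]`` (LVs x samples).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import LabelledMatrix, LatentModel

logger = logging.getLogger(__name__)

__all__ = [
    "read_labelled_matrix",
    "write_labelled_matrix",
    "read_latent_model",
    "write_latent_model",
    "align_genes",
]

# full round-trip precision for float64 text output
_FLOAT_FMT = "%.17g"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    ids = df.index.astype(str)
    if ids.duplicated().any():
        dups = sorted(set(ids[ids.duplicated()]))
        raise ValueError(f"{path}: duplicate row ids: {', '.join(dups)}")
    cols = pd.Index(df.columns.astype(str))
    if cols.duplicated().any():
        dups = sorted(set(cols[cols.duplicated()]))
        raise ValueError(f"{path}: duplicate column ids: {', '.join(dups)}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        df[col] = coerced
    return df.astype(float)


def read_labelled_matrix(path: str | Path, orientation: str = "rows=genes") -> LabelledMatrix:
    """Read a tab-separated matrix with a header row and a leading id column.

    ``orientation`` records what the file's rows mean (``rows=genes`` or
    ``rows=traits``); ids are preserved in file order and no transposition
    is performed here.
    """
    if orientation not in ("rows=genes", "rows=traits", "rows=compounds"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path)
    return LabelledMatrix.from_dataframe(df, orientation=orientation)


def write_labelled_matrix(m: LabelledMatrix, path: str | Path) -> None:
    m.to_dataframe().to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def _find(bundle: Path, stem: str) -> Path | None:
    for suffix in (".tsv", ".tsv.gz"):
        p = bundle / f"{stem}{suffix}"
        if p.exists():
            return p
    return None


def read_latent_model(bundle_path: str | Path) -> LatentModel:
    """Load a latent-model bundle directory and validate its invariants."""
    bundle = Path(bundle_path)
    loadings_path = _find(bundle, "loadings")
    if loadings_path is None:
        raise FileNotFoundError(f"{bundle}: no loadings.tsv[.gz] found")
    meta_path = bundle / "meta.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(f"{bundle}: no meta.yaml found")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh) or {}
    if "lambda2" not in meta:
        raise ValueError(f"{meta_path}: missing required key 'lambda2'")
    loadings = _read_table(loadings_path)
    b_path = _find(bundle, "B")
    B = sample_ids = None
    if b_path is not None:
        b_df = _read_table(b_path)
        B = b_df.to_numpy()
        sample_ids = list(b_df.columns.astype(str))
    return LatentModel(
        Z=loadings.to_numpy(),
        lambda2=float(meta["lambda2"]),
        gene_ids=list(loadings.index.astype(str)),
        lv_ids=list(loadings.columns.astype(str)),
        B=B,
        sample_ids=sample_ids,
    )


def write_latent_model(model: LatentModel, bundle_path: str | Path) -> None:
    bundle = Path(bundle_path)
    bundle.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(model.Z, index=model.gene_ids, columns=model.lv_ids).to_csv(
        bundle / "loadings.tsv", sep="\t", float_format=_FLOAT_FMT)
    with open(bundle / "meta.yaml", "w") as fh:
        yaml.safe_dump({"lambda2": float(model.lambda2)}, fh)
    if model.B is not None:
        pd.DataFrame(model.B, index=model.lv_ids, columns=model.sample_ids).to_csv(
            bundle / "B.tsv", sep="\t", float_format=_FLOAT_FMT)


def align_genes(m: LabelledMatrix, model: LatentModel,
                policy: str = "zero_fill") -> LabelledMatrix:
    """Reorder a genes-as-rows matrix to the latent model's gene order.

    ``zero_fill`` inserts all-zero rows for model genes absent from ``m``
    (a zero z-score is neutral in the projection dot products), so the output
    always has one row per model gene.  ``intersect`` drops absent genes,
    keeping model order.  Genes in ``m`` that the model does not know are
    always dropped.  Counts of filled/dropped genes are logged.
    """
    if policy not in ("zero_fill", "intersect"):
        raise ValueError(f"unknown policy {policy!r}")
    pos = {g: i for i, g in enumerate(m.row_ids)}
    present = [g for g in model.gene_ids if g in pos]
    if not present:
        raise ValueError("no genes shared between matrix and latent model")
    extra = len(m.row_ids) - len(present)
    if extra:
        logger.info("align_genes: dropped %d genes absent from the model", extra)
    if policy == "intersect":
        rows = [pos[g] for g in present]
        values = m.values[rows, :]
        out_ids = present
        missing = len(model.gene_ids) - len(present)
        if missing:
            logger.info("align_genes: intersect dropped %d model genes", missing)
    else:
        values = np.zeros((model.n_genes, len(m.col_ids)))
        for i, g in enumerate(model.gene_ids):
            if g in pos:
                values[i, :] = m.values[pos[g], :]
        out_ids = list(model.gene_ids)
        missing = model.n_genes - len(present)
        if missing:
            logger.info("align_genes: zero-filled %d model genes", missing)
    return LabelledMatrix(values, out_ids, list(m.col_ids), orientation="rows=genes")
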