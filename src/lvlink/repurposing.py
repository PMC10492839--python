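"""Signature-reversal drug-disease scoring and its evaluation.

A drug-disease raw score is the negative dot product between the trait's
signed association profile and the compound's perturbation profile over a
shared gene (or LV) axis: a drug that down-regulates what the disease
up-regulates gets a positive score.  Per tissue, raw scores are computed
for several per-trait profile sizes k (restricting each trait to its k
strongest associations), converted to within-trait compound ranks, and the
ranks averaged across k.  The final score matrix takes, for each pair, the
maximum of the rank-averaged score across tissues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, roc_auc_score

from .containers import LabelledMatrix

__all__ = [
    "DrugScores",
    "topk_restrict",
    "score_pairs",
    "lv_contributions",
    "evaluate",
]

GENE_K_GRID = ("all", 50, 100, 250, 500)
LV_K_GRID = ("all", 5, 10, 25, 50)


@dataclass
class DrugScores:
    """Per-tissue/per-k raw scores, rank-averaged per-tissue scores, and the
    tissue-maximized final compound-by-trait matrix."""

    per_tissue_k: dict[str, dict[object, LabelledMatrix]]
    per_tissue: dict[str, LabelledMatrix]
    final: LabelledMatrix
    k_grid: tuple
    space: str


def _tie_order(values: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    """Indices sorted by descending value, ties by lexicographic id."""
    return np.array(sorted(range(len(ids)), key=lambda i: (-values[i], ids[i])))


def topk_restrict(mt: LabelledMatrix, k) -> LabelledMatrix:
    """Zero out, per trait column, all but the k largest-|z| gene entries.

    ``k='all'`` returns the input unchanged.  Ties at the boundary are broken
    by larger |z| first, then lexicographic gene id.
    """
    if k == "all":
        return mt
    k = int(k)
    if k <= 0:
        raise ValueError("k must be positive or 'all'")
    k = min(k, len(mt.row_ids))
    out = np.zeros_like(mt.values)
    for j in range(len(mt.col_ids)):
        col = np.abs(mt.values[:, j])
        keep = _tie_order(col, mt.row_ids)[:k]
        out[keep, j] = mt.values[keep, j]
    return LabelledMatrix(out, list(mt.row_ids), list(mt.col_ids),
                          orientation=mt.orientation)


def _check_axis(mt: LabelledMatrix, profiles: LabelledMatrix) -> None:
    if mt.row_ids != profiles.row_ids:
        raise ValueError("trait and compound matrices must share the same "
                         "gene/LV axis (identical row ids)")
    if len(mt.row_ids) == 0:
        raise ValueError("empty shared axis")


def raw_scores(mt: LabelledMatrix, profiles: LabelledMatrix) -> LabelledMatrix:
    """Raw compound-by-trait scores: -profiles^T mt over the shared axis."""
    _check_axis(mt, profiles)
    return LabelledMatrix(-(profiles.values.T @ mt.values),
                          list(profiles.col_ids), list(mt.col_ids))


def score_pairs(mt_by_tissue: Mapping[str, LabelledMatrix],
                profiles: LabelledMatrix,
                k_grid: Sequence = GENE_K_GRID, space: str = "gene") -> DrugScores:
    """Full scoring pipeline over tissues and profile sizes.

    ``mt_by_tissue`` maps tissue name to a genes(or LVs)-as-rows,
    traits-as-columns signed matrix; ``profiles`` is the compound matrix on
    the same axis (rows) with compounds as columns.  Ranks are assigned
    within each trait column across compounds (midranks on ties; larger
    score, higher rank number), averaged over ``k_grid``, then maximized
    over tissues.
    """
    if not mt_by_tissue:
        raise ValueError("no tissue matrices given")
    per_tissue_k: dict[str, dict[object, LabelledMatrix]] = {}
    per_tissue: dict[str, LabelledMatrix] = {}
    compounds = list(profiles.col_ids)
    traits = list(next(iter(mt_by_tissue.values())).col_ids)
    final = None
    for tissue in mt_by_tissue:
        mt = mt_by_tissue[tissue]
        _check_axis(mt, profiles)
        if list(mt.col_ids) != traits:
            raise ValueError("all tissue matrices must share the same traits")
        by_k: dict[object, LabelledMatrix] = {}
        rank_sum = np.zeros((len(compounds), len(traits)))
        for k in k_grid:
            D_tk = raw_scores(topk_restrict(mt, k), profiles)
            by_k[k] = D_tk
            rank_sum += rankdata(D_tk.values, method="average", axis=0)
        avg = rank_sum / len(k_grid)
        per_tissue_k[tissue] = by_k
        per_tissue[tissue] = LabelledMatrix(avg, compounds, traits)
        final = avg if final is None else np.maximum(final, avg)
    return DrugScores(per_tissue_k=per_tissue_k, per_tissue=per_tissue,
                      final=LabelledMatrix(final, compounds, traits),
                      k_grid=tuple(k_grid), space=space)


def lv_contributions(mhat_t: LabelledMatrix, lhat: LabelledMatrix,
                     compound: str, trait: str) -> pd.DataFrame:
    """Per-LV contribution to one pair's raw LV-space score, sorted descending.

    The contribution of LV j is ``-(lhat[j, compound] * mhat_t[j, trait])``;
    contributions sum to the k='all' raw score.  LVs whose contribution is
    positive act in opposite directions in trait and compound — the reversal
    signal.
    """
    _check_axis(mhat_t, lhat)
    if compound not in lhat.col_ids:
        raise KeyError(f"unknown compound {compound!r}")
    if trait not in mhat_t.col_ids:
        raise KeyError(f"unknown trait {trait!r}")
    contrib = -(lhat.col(compound) * mhat_t.col(trait))
    df = pd.DataFrame({"lv": mhat_t.row_ids, "contribution": contrib})
    return df.sort_values("contribution", ascending=False,
                          kind="mergesort").reset_index(drop=True)


def evaluate(scores: LabelledMatrix, gold: pd.DataFrame,
             n_permutations: int = 100, seed: int = 0) -> dict:
    """AUROC / average precision of final scores against a gold standard.

    ``gold`` needs columns (compound, trait, indicated) where ``indicated``
    is boolean; every gold pair must be scored.  The permutation baseline
    shuffles the score vector against fixed labels.
    """
    comp_pos = {c: i for i, c in enumerate(scores.row_ids)}
    trait_pos = {t: i for i, t in enumerate(scores.col_ids)}
    if gold.duplicated(["compound", "trait"]).any():
        raise ValueError("duplicate gold-standard pairs")
    try:
        s = np.array([scores.values[comp_pos[c], trait_pos[t]]
                      for c, t in zip(gold["compound"], gold["trait"])])
    except KeyError as exc:
        raise ValueError(f"gold pair references unscored id {exc.args[0]!r}") from None
    y = gold["indicated"].to_numpy(dtype=bool)
    if y.all() or not y.any():
        raise ValueError("gold standard must contain both classes")
    auroc = float(roc_auc_score(y, s))
    ap = float(average_precision_score(y, s))
    rng = np.random.default_rng(seed)
    perm = np.empty(n_permutations)
    for i in range(n_permutations):
        perm[i] = roc_auc_score(y, rng.permutation(s))
    lo, hi = np.percentile(perm, [2.5, 97.5])
    return {"auroc": auroc, "average_precision": ap,
            "baseline_mean": float(perm.mean()),
            "baseline_ci": (float(lo), float(hi)),
            "n_pairs": int(len(y)), "n_positive": int(y.sum())}
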