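"""Iterative decision-stump extraction of cluster-discriminative LVs.

For one trait cluster, a depth-1 classification tree is fit on the
traits-by-LV matrix with binary labels (cluster vs rest, classes weighted
inversely to frequency).  The root LV and its split threshold are recorded;
the LV counts as *selected* only when the threshold is positive and exceeds
one standard deviation of that LV's values across all traits.  The root LV
is then removed regardless and the procedure repeats, yielding an ordered,
duplicate-free list of the most discriminative modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .containers import LabelledMatrix

logger = logging.getLogger(__name__)

__all__ = ["ClusterLvReport", "discriminative_lvs"]


@dataclass
class ClusterLvReport:
    cluster_id: int
    entries: list[dict]  # lv, threshold, selected per iteration
    iterations_run: int

    @property
    def root_lvs(self) -> list[str]:
        return [e["lv"] for e in self.entries]

    @property
    def selected_lvs(self) -> list[str]:
        return [e["lv"] for e in self.entries if e["selected"]]


def discriminative_lvs(mhat: LabelledMatrix, labels: np.ndarray, cluster_id: int,
                       iterations: int = 20, seed: int = 0) -> ClusterLvReport:
    """Extract the LVs that best separate one cluster from the rest.

    ``mhat`` is traits-as-rows, LVs-as-columns; ``labels`` assigns each trait
    a cluster id.  The selection rule compares the root split threshold with
    the standard deviation (ddof=1) of the root LV across all traits.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != len(mhat.row_ids):
        raise ValueError("label vector length does not match trait count")
    y = (labels == cluster_id).astype(int)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("cluster needs at least 2 members and 2 non-members")
    X = mhat.values.copy()
    lv_ids = list(mhat.col_ids)
    col_sd = {lv: sd for lv, sd in zip(lv_ids, np.std(mhat.values, axis=0, ddof=1))}
    entries: list[dict] = []
    for _ in range(iterations):
        if X.shape[1] == 0:
            logger.info("cluster %s: ran out of LVs after %d iterations",
                        cluster_id, len(entries))
            break
        tree = DecisionTreeClassifier(max_depth=1, class_weight="balanced",
                                      random_state=seed)
        tree.fit(X, y)
        root_feature = tree.tree_.feature[0]
        if root_feature < 0:  # no split possible
            logger.info("cluster %s: tree produced no split; stopping", cluster_id)
            break
        lv = lv_ids[root_feature]
        threshold = float(tree.tree_.threshold[0])
        selected = threshold > 0 and threshold > col_sd[lv]
        entries.append({"lv": lv, "threshold": threshold, "selected": selected})
        X = np.delete(X, root_feature, axis=1)
        del lv_ids[root_feature]
    return ClusterLvReport(cluster_id=cluster_id, entries=entries,
                           iterations_run=len(entries))
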