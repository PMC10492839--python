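"""Evidence-accumulation consensus clustering of traits in LV space.

The pipeline preprocesses a genes-by-traits association matrix (probit
transform of p-values, optional combining of duplicate traits, per-trait
polygenicity normalization), projects it into LV space, and clusters the
traits.  Diversity comes from three data representations (raw, PCA, UMAP)
each partitioned by five algorithm families over parameter grids.  The
ensemble is condensed into a disagreement matrix D (fraction of partitions
splitting each trait pair), an RBF kernel turns D into a similarity, and
spectral clustering yields one candidate per (k, gamma); the winner per k
maximizes the median adjusted Rand index against the whole ensemble.
Solutions whose agreement does not exceed the 75th percentile across k are
filtered out, and cluster-membership flows between consecutive retained
resolutions form the clustering-tree edge table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN, KMeans, AgglomerativeClustering, SpectralClustering
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from .containers import LabelledMatrix, RunConfig

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "Ensemble",
    "EacDistance",
    "ConsensusSolution",
    "stouffer_combine",
    "probit_transform",
    "polygenicity_normalize",
    "make_representations",
    "generate_ensemble",
    "eac_distance",
    "ari",
    "consensus",
    "filter_solutions",
    "clustering_tree_edges",
]

P_CLAMP = 1e-300


@dataclass
class Partition:
    labels: np.ndarray
    algorithm: str
    params: dict = field(default_factory=dict)
    representation: str = "raw"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)


@dataclass
class Ensemble:
    partitions: list[Partition]

    @property
    def r(self) -> int:
        return len(self.partitions)

    def __post_init__(self) -> None:
        sizes = {p.labels.shape[0] for p in self.partitions}
        if len(sizes) > 1:
            raise ValueError("partitions cover different trait sets")


@dataclass
class EacDistance:
    """Pairwise disagreement fractions: exact counts over r partitions."""

    D: np.ndarray
    r: int


@dataclass
class ConsensusSolution:
    """One consensus partition per k with its winning gamma and agreement."""

    solutions: pd.DataFrame  # columns: k, gamma, agreement, labels (object)

    def labels_for(self, k: int) -> np.ndarray:
        row = self.solutions[self.solutions["k"] == k]
        if row.empty:
            raise KeyError(f"no consensus solution at k={k}")
        return row.iloc[0]["labels"]


# ---------------------------------------------------------------------------
# preprocessing

def probit_transform(p: LabelledMatrix | np.ndarray):
    """Convert two-sided p-values to nonnegative z-scores, ``z = probit(1 - p/2)``.

    Smaller p maps to larger z.  P-values are clamped below at 1e-300.
    """
    values = p.values if isinstance(p, LabelledMatrix) else np.asarray(p, dtype=float)
    if np.any(values > 1) or np.any(values < 0):
        raise ValueError("p-values must lie in [0, 1]")
    z = stats.norm.isf(np.clip(values, P_CLAMP, None) / 2.0)
    if isinstance(p, LabelledMatrix):
        return LabelledMatrix(z, list(p.row_ids), list(p.col_ids),
                              orientation=p.orientation)
    return z


def stouffer_combine(z: LabelledMatrix, groups: Mapping[str, str],
                     weights: Mapping[str, float]) -> LabelledMatrix:
    """Combine trait columns mapping to the same group:
    ``sum(w_i z_i) / sqrt(sum(w_i^2))``.

    Singleton groups pass through unchanged.  Output columns are named by
    group, in first-appearance order.
    """
    missing = [t for t in z.col_ids if t not in weights]
    if missing:
        raise ValueError(f"missing weights for traits: {', '.join(missing[:5])}")
    order: list[str] = []
    members: dict[str, list[int]] = {}
    for j, t in enumerate(z.col_ids):
        g = groups.get(t, t)
        if g not in members:
            members[g] = []
            order.append(g)
        members[g].append(j)
    out = np.empty((len(z.row_ids), len(order)))
    for j, g in enumerate(order):
        idx = members[g]
        w = np.array([weights[z.col_ids[i]] for i in idx], dtype=float)
        if np.any(w <= 0):
            raise ValueError(f"weights must be positive (group {g!r})")
        out[:, j] = z.values[:, idx] @ w / np.sqrt((w ** 2).sum())
    return LabelledMatrix(out, list(z.row_ids), order, orientation=z.orientation)


def polygenicity_normalize(z: LabelledMatrix) -> LabelledMatrix:
    """Divide each trait column by its sum so highly polygenic traits do not
    dominate distances.  Requires nonnegative entries and positive sums."""
    if np.any(z.values < 0):
        raise ValueError("normalization expects nonnegative association scores")
    sums = z.values.sum(axis=0)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise ValueError("zero column sum for traits: "
                         + ", ".join(z.col_ids[i] for i in zero))
    return LabelledMatrix(z.values / sums, list(z.row_ids), list(z.col_ids),
                          orientation=z.orientation)


# ---------------------------------------------------------------------------
# ensemble generation

def make_representations(mhat: np.ndarray, seed: int = 0,
                         n_components: int = 50) -> dict[str, np.ndarray]:
    """Raw, PCA and UMAP views of a traits-by-LV matrix.

    Component counts are capped at ``min(n_components, n_traits - 1,
    n_features)`` with a log entry when the cap binds.  PCA is deterministic;
    UMAP is seeded (which also forces single-threaded, reproducible layout).
    """
    mhat = np.asarray(mhat, dtype=float)
    n, d = mhat.shape
    nc = min(n_components, n - 1, d)
    if nc < n_components:
        logger.info("representations: component count capped at %d", nc)
    pca = PCA(n_components=nc, svd_solver="full").fit_transform(mhat)
    import umap  # deferred: numba compilation is slow at import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = umap.UMAP(n_components=nc, random_state=seed,
                        n_neighbors=min(15, n - 1)).fit_transform(mhat)
    return {"raw": mhat, "pca": pca, "umap": np.asarray(emb, dtype=float)}


def _expand_noise(labels: np.ndarray) -> np.ndarray:
    """Give each density-based noise point its own singleton cluster."""
    labels = labels.copy()
    nxt = labels.max() + 1 if labels.size else 0
    for i in np.flatnonzero(labels == -1):
        labels[i] = nxt
        nxt += 1
    return labels


def _valid(labels: np.ndarray) -> bool:
    return np.unique(labels).size >= 2


def generate_ensemble(representations: Mapping[str, np.ndarray],
                      config: RunConfig | None = None,
                      seed: int = 0) -> Ensemble:
    """Build the multi-algorithm partition ensemble.

    Per representation: k-means, spectral clustering and Gaussian mixtures
    run for every k in [2, floor(sqrt(n))] with five seeded repetitions;
    hierarchical clustering contributes four linkages per k; the
    density-based family scans a minPts grid with an epsilon grid taken at
    the {10,30,50,70,90}th percentiles of the mean minPts-nearest-neighbor
    distance.  Partitions with a single cluster or all points noise are
    dropped; density-based partitions are resampled with replacement to the
    mean count of the other four families.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    parts: list[Partition] = []
    for rep_name, data in representations.items():
        n = data.shape[0]
        kmax = int(np.floor(np.sqrt(n)))
        ks = range(2, kmax + 1)
        rep_parts: dict[str, list[Partition]] = {a: [] for a in
                                                 ("kmeans", "spectral", "gmm",
                                                  "hierarchical", "dbscan")}
        for k in ks:
            for rep_i in range(config.n_algo_seeds):
                s = int(rng.integers(0, 2 ** 31 - 1))
                lab = KMeans(n_clusters=k, n_init=1, random_state=s).fit_predict(data)
                if _valid(lab):
                    rep_parts["kmeans"].append(Partition(
                        lab, "kmeans", {"k": k, "seed": s}, rep_name))
                s = int(rng.integers(0, 2 ** 31 - 1))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    lab = SpectralClustering(
                        n_clusters=k, random_state=s,
                        affinity="nearest_neighbors",
                        n_neighbors=min(10, n - 1)).fit_predict(data)
                if _valid(lab):
                    rep_parts["spectral"].append(Partition(
                        lab, "spectral", {"k": k, "seed": s}, rep_name))
                s = int(rng.integers(0, 2 ** 31 - 1))
                lab = GaussianMixture(n_components=k, random_state=s,
                                      reg_covar=1e-4).fit_predict(data)
                if _valid(lab):
                    rep_parts["gmm"].append(Partition(
                        lab, "gmm", {"k": k, "seed": s}, rep_name))
            for linkage in config.linkages:
                lab = AgglomerativeClustering(
                    n_clusters=k, linkage=linkage).fit_predict(data)
                if _valid(lab):
                    rep_parts["hierarchical"].append(Partition(
                        lab, "hierarchical", {"k": k, "linkage": linkage}, rep_name))
        for minpts in config.minpts_grid:
            if minpts >= n:
                continue
            nn = NearestNeighbors(n_neighbors=minpts).fit(data)
            dists, _ = nn.kneighbors(data)
            mean_d = dists[:, 1:].mean(axis=1) if minpts > 1 else dists[:, 0]
            eps_grid = np.quantile(mean_d, config.eps_quantiles)
            for eps in eps_grid:
                if eps <= 0:
                    continue
                lab = DBSCAN(eps=eps, min_samples=minpts).fit_predict(data)
                if np.all(lab == -1):
                    continue
                lab = _expand_noise(lab)
                if _valid(lab):
                    rep_parts["dbscan"].append(Partition(
                        lab, "dbscan", {"minpts": int(minpts), "eps": float(eps)},
                        rep_name))
        others = [len(rep_parts[a]) for a in ("kmeans", "spectral", "gmm",
                                              "hierarchical")]
        target = int(round(np.mean(others)))
        db = rep_parts["dbscan"]
        if not db:
            logger.info("representation %s: no valid density-based partition",
                        rep_name)
        elif len(db) != target and target > 0:
            pick = rng.choice(len(db), size=target, replace=True)
            rep_parts["dbscan"] = [db[i] for i in pick]
        for algo in ("kmeans", "spectral", "gmm", "hierarchical", "dbscan"):
            parts.extend(rep_parts[algo])
    return Ensemble(parts)


# ---------------------------------------------------------------------------
# consensus

def eac_distance(ens: Ensemble) -> EacDistance:
    """Fraction of ensemble partitions placing each trait pair in different
    clusters (exact rational counts over r)."""
    if ens.r < 1:
        raise ValueError("ensemble is empty")
    n = ens.partitions[0].labels.shape[0]
    counts = np.zeros((n, n), dtype=np.int64)
    for p in ens.partitions:
        lab = p.labels
        counts += lab[:, None] != lab[None, :]
    D = counts / ens.r
    np.fill_diagonal(D, 0.0)
    return EacDistance(D=D, r=ens.r)


def ari(p1: Partition | np.ndarray, p2: Partition | np.ndarray) -> float:
    """Adjusted Rand index between two partitions (permutation model)."""
    a = p1.labels if isinstance(p1, Partition) else np.asarray(p1)
    b = p2.labels if isinstance(p2, Partition) else np.asarray(p2)
    if a.shape != b.shape:
        raise ValueError("partitions cover different trait sets")
    return float(adjusted_rand_score(a, b))


def _fast_ari(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted Rand index via a bincount contingency table.

    Numerically identical to the permutation-model ARI; used in the
    consensus agreement loop where per-call overhead matters.
    """
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    na, nb = ai.max() + 1, bi.max() + 1
    ct = np.bincount(ai * nb + bi, minlength=na * nb).reshape(na, nb)
    n = a.shape[0]
    sum_comb = (ct * (ct - 1) // 2).sum()
    rows = ct.sum(axis=1)
    cols = ct.sum(axis=0)
    comb_rows = (rows * (rows - 1) // 2).sum()
    comb_cols = (cols * (cols - 1) // 2).sum()
    total = n * (n - 1) // 2
    expected = comb_rows * comb_cols / total
    max_index = (comb_rows + comb_cols) / 2
    if max_index == expected:
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def default_gamma_grid(D: np.ndarray,
                       factors: Sequence[float] = (0.5, 1.0, 2.0, 5.0)) -> list[float]:
    """RBF bandwidths as multiples of 1/median(offdiagonal D^2)."""
    off = D[np.triu_indices_from(D, k=1)] ** 2
    med = np.median(off)
    if med <= 0:
        raise ValueError("degenerate distance matrix: median off-diagonal is zero")
    return [f / med for f in factors]


def consensus(dist: EacDistance, ens: Ensemble, k_range: Sequence[int],
              gamma_grid: Sequence[float] | None = None,
              seed: int = 0) -> ConsensusSolution:
    """Spectral consensus over the disagreement matrix.

    For each k and each RBF bandwidth gamma, the similarity ``exp(-gamma D^2)``
    is spectrally partitioned into k clusters; the winner per k maximizes the
    median adjusted Rand index against the full ensemble.
    """
    D = dist.D
    n = D.shape[0]
    kmax = int(np.floor(np.sqrt(n)))
    for k in k_range:
        if not (2 <= k <= kmax):
            raise ValueError(f"k={k} outside [2, floor(sqrt(n))={kmax}]")
    if gamma_grid is None:
        gamma_grid = default_gamma_grid(D)
    ens_labels = [p.labels for p in ens.partitions]
    rows = []
    for k in k_range:
        best = None
        for gamma in gamma_grid:
            S = np.exp(-gamma * D ** 2)
            if S.max() - S.min() < 1e-12:
                raise ValueError(
                    "similarity matrix is nearly constant; try a different gamma")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lab = SpectralClustering(
                    n_clusters=k, affinity="precomputed",
                    random_state=seed).fit_predict(S)
            agreement = float(np.median([_fast_ari(lab, e) for e in ens_labels]))
            if best is None or agreement > best[0]:
                best = (agreement, gamma, lab)
        rows.append({"k": k, "gamma": best[1], "agreement": best[0],
                     "labels": best[2]})
    return ConsensusSolution(pd.DataFrame(rows))


def filter_solutions(cons: ConsensusSolution) -> ConsensusSolution:
    """Keep consensus solutions whose agreement strictly exceeds the 75th
    percentile of agreements across k."""
    if len(cons.solutions) < 4:
        raise ValueError("need at least 4 solutions to filter")
    agreements = cons.solutions["agreement"].to_numpy()
    cutoff = np.percentile(agreements, 75)
    keep = cons.solutions[cons.solutions["agreement"] > cutoff]
    if keep.empty:
        warnings.warn("no solution exceeds the 75th-percentile agreement",
                      stacklevel=2)
    return ConsensusSolution(keep.reset_index(drop=True))


def clustering_tree_edges(cons: ConsensusSolution) -> pd.DataFrame:
    """Trait flows between consecutive resolutions of the retained solutions.

    One row per (parent cluster at k_a, child cluster at k_b) pair with a
    positive shared-trait count, for each consecutive pair of resolutions
    sorted by k.
    """
    sols = cons.solutions.sort_values("k").reset_index(drop=True)
    if len(sols) < 2:
        raise ValueError("need at least 2 resolutions for a clustering tree")
    rows = []
    for i in range(len(sols) - 1):
        ka, kb = int(sols.loc[i, "k"]), int(sols.loc[i + 1, "k"])
        la, lb = sols.loc[i, "labels"], sols.loc[i + 1, "labels"]
        ct = pd.crosstab(pd.Series(la, name="a"), pd.Series(lb, name="b"))
        for a in ct.index:
            for b in ct.columns:
                cnt = int(ct.loc[a, b])
                if cnt > 0:
                    rows.append({"k_parent": ka, "cluster_parent": int(a),
                                 "k_child": kb, "cluster_child": int(b),
                                 "n_shared": cnt})
    return pd.DataFrame(rows)
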