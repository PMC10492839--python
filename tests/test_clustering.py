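import numpy as np
import pandas as pd
import pytest


from lvlink.containers import LabelledMatrix, RunConfig
from lvlink.clustering import (ConsensusSolution, Ensemble, Partition, ari,
                               clustering_tree_edges, consensus, eac_distance,
                               filter_solutions, generate_ensemble,
                               make_representations, polygenicity_normalize,
                               probit_transform, stouffer_combine)


def _lm(values, rows=None, cols=None):
    values = np.asarray(values, dtype=float)
    rows = rows or [f"g{i}" for i in range(values.shape[0])]
    cols = cols or [f"t{j}" for j in range(values.shape[1])]
    return LabelledMatrix(values, rows, cols)


class TestStouffer:
    def test_identical_columns_scale_by_sqrt2(self):
        z = _lm(np.tile([[1.0], [2.0]], (1, 2)), cols=["a", "b"])
        out = stouffer_combine(z, {"a": "grp", "b": "grp"}, {"a": 1, "b": 1})
        np.testing.assert_allclose(out.values[:, 0], np.sqrt(2) * z.values[:, 0])

    def test_singleton_passes_through(self):
        z = _lm([[1.0, 5.0]], cols=["a", "b"])
        out = stouffer_combine(z, {}, {"a": 1, "b": 2})
        np.testing.assert_array_equal(out.values, z.values)
        assert out.col_ids == ["a", "b"]

    def test_weighted_formula_oracle(self):
        rng = np.random.default_rng(0)
        z = _lm(rng.standard_normal((4, 3)), cols=["a", "b", "c"])
        w = {"a": 1.0, "b": 2.0, "c": 3.0}
        out = stouffer_combine(z, {t: "g" for t in "abc"}, w)
        expected = (z.values @ np.array([1, 2, 3])) / np.sqrt(1 + 4 + 9)
        np.testing.assert_allclose(out.values[:, 0], expected)

    def test_missing_weight_errors(self):
        z = _lm([[1.0]], cols=["a"])
        with pytest.raises(ValueError, match="a"):
            stouffer_combine(z, {}, {})


class TestProbit:
    def test_p_one_maps_to_zero(self):
        assert probit_transform(np.array([[1.0]]))[0, 0] == 0.0

    def test_p_005(self):
        assert abs(probit_transform(np.array([[0.05]]))[0, 0] - 1.959964) < 1e-5

    def test_monotone(self):
        p = np.sort(np.random.default_rng(0).uniform(1e-6, 1, 50))
        z = probit_transform(p[None, :])[0]
        assert np.all(np.diff(z) <= 0)

    def test_p_above_one_errors(self):
        with pytest.raises(ValueError):
            probit_transform(np.array([[1.5]]))


class TestPolygenicityNormalize:
    def test_column_values(self):
        z = _lm(np.array([[1.0], [1.0], [2.0]]), cols=["tr"])
        np.testing.assert_allclose(polygenicity_normalize(z).values[:, 0],
                                   [0.25, 0.25, 0.5])

    def test_scale_invariance_and_unit_sums(self):
        rng = np.random.default_rng(1)
        z = _lm(rng.uniform(0.1, 2.0, (6, 3)))
        out1 = polygenicity_normalize(z)
        out2 = polygenicity_normalize(_lm(z.values * 10, cols=z.col_ids))
        np.testing.assert_allclose(out1.values, out2.values, atol=1e-12)
        np.testing.assert_allclose(out1.values.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_sum_names_trait(self):
        z = _lm(np.array([[0.0, 1.0], [0.0, 1.0]]), cols=["bad", "ok"])
        with pytest.raises(ValueError, match="bad"):
            polygenicity_normalize(z)


class TestEacDistance:
    def test_single_partition_binary(self):
        ens = Ensemble([Partition(np.array([0, 0, 1]), "x")])
        D = eac_distance(ens).D
        assert D[0, 1] == 0.0 and D[0, 2] == 1.0 and D[1, 2] == 1.0

    def test_half_split(self):
        ens = Ensemble([Partition(np.array([0, 0]), "x"),
                        Partition(np.array([0, 1]), "x")])
        assert eac_distance(ens).D[0, 1] == 0.5

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(2)
        parts = [Partition(rng.integers(0, 4, 20), "x") for _ in range(15)]
        ens = Ensemble(parts)
        D = eac_distance(ens).D
        for i in range(20):
            for j in range(20):
                d = sum(p.labels[i] != p.labels[j] for p in parts) / 15
                assert D[i, j] == pytest.approx(d if i != j else 0.0)

    def test_symmetric_bounded(self):
        rng = np.random.default_rng(3)
        ens = Ensemble([Partition(rng.integers(0, 3, 10), "x")
                        for _ in range(7)])
        D = eac_distance(ens).D
        np.testing.assert_array_equal(D, D.T)
        assert D.min() >= 0 and D.max() <= 1
        np.testing.assert_array_equal(np.diag(D), 0.0)


class TestAri:
    def test_identical_and_relabeled(self):
        a = np.array([0, 0, 1, 1, 2])
        assert ari(a, a) == 1.0
        assert ari(a, (a + 1) % 3) == 1.0

    def test_contingency_closed_form(self):
        a = np.array([1, 1, 2, 2])
        b = np.array([1, 2, 2, 2])
        # closed form from the 2x2 contingency table
        from scipy.special import comb
        ct = np.array([[1, 1], [0, 2]])
        sum_comb = sum(comb(x, 2) for x in ct.ravel())
        rows = sum(comb(x, 2) for x in ct.sum(axis=1))
        cols = sum(comb(x, 2) for x in ct.sum(axis=0))
        total = comb(4, 2)
        expected = (sum_comb - rows * cols / total) / \
            ((rows + cols) / 2 - rows * cols / total)
        assert abs(ari(a, b) - expected) < 1e-12


class TestRepresentations:
    def test_raw_is_input_and_pca_orthogonal(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 10))
        reps = make_representations(X, seed=0)
        np.testing.assert_array_equal(reps["raw"], X)
        pc = reps["pca"]
        gram = pc.T @ pc
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)
        assert reps["umap"].shape[0] == 30

    def test_pca_reconstruction_error_decreases(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((25, 12))
        from sklearn.decomposition import PCA
        errs = []
        for nc in (2, 5, 11):
            p = PCA(n_components=nc, svd_solver="full").fit(X)
            rec = p.inverse_transform(p.transform(X))
            errs.append(np.linalg.norm(X - rec))
        assert errs[0] >= errs[1] >= errs[2]


@pytest.fixture()
def reps():
    rng = np.random.default_rng(6)
    X = rng.standard_normal((40, 6)) + 3.0 * (rng.integers(0, 2, (40, 1)))
    return {"raw": X}


class TestEnsemble:

    def test_kmeans_partition_count_follows_grid(self, reps):
        cfg = RunConfig(seed=0)
        ens = generate_ensemble(reps, cfg, seed=0)
        kmeans = [p for p in ens.partitions if p.algorithm == "kmeans"]
        # k in [2, floor(sqrt(40))=6] and five seeded runs each
        assert len(kmeans) == 5 * 5
        assert all(p.labels.shape == (40,) for p in ens.partitions)

    def test_deterministic_under_seed(self, reps):
        cfg = RunConfig(seed=0)
        e1 = generate_ensemble(reps, cfg, seed=3)
        e2 = generate_ensemble(reps, cfg, seed=3)
        assert e1.r == e2.r
        for p1, p2 in zip(e1.partitions, e2.partitions):
            np.testing.assert_array_equal(p1.labels, p2.labels)
            assert p1.algorithm == p2.algorithm and p1.params == p2.params


class TestConsensus:
    def _block_distance(self, sizes):
        labels = np.repeat(np.arange(len(sizes)), sizes)
        D = (labels[:, None] != labels[None, :]).astype(float)
        return D, labels

    def test_perfect_coassociation_recovered(self):
        D, labels = self._block_distance([7, 6, 7])
        parts = [Partition(labels, "x") for _ in range(4)]
        ens = Ensemble(parts)
        from lvlink.clustering import EacDistance
        cons = consensus(EacDistance(D, 4), ens, [3], seed=0)
        assert ari(cons.labels_for(3), labels) == 1.0
        assert cons.solutions.iloc[0]["agreement"] == 1.0

    def test_winner_maximizes_agreement(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 3, 30)
        parts = [Partition(np.where(rng.uniform(size=30) < 0.2,
                                    rng.integers(0, 3, 30), labels), "x")
                 for _ in range(20)]
        ens = Ensemble(parts)
        dist = eac_distance(ens)
        gammas = [0.1, 1.0, 10.0]
        cons = consensus(dist, ens, [3], gamma_grid=gammas, seed=0)
        row = cons.solutions.iloc[0]
        from lvlink.clustering import _fast_ari
        from sklearn.cluster import SpectralClustering
        for g in gammas:
            S = np.exp(-g * dist.D ** 2)
            lab = SpectralClustering(n_clusters=3, affinity="precomputed",
                                     random_state=0).fit_predict(S)
            agr = np.median([_fast_ari(lab, p.labels) for p in parts])
            assert row["agreement"] >= agr - 1e-12

    def test_k_outside_range_errors(self):
        D, labels = self._block_distance([5, 5])
        ens = Ensemble([Partition(labels, "x")])
        from lvlink.clustering import EacDistance
        with pytest.raises(ValueError):
            consensus(EacDistance(D, 1), ens, [9], seed=0)


class TestFilterSolutions:
    def _cons(self, agreements):
        rows = [{"k": i + 2, "gamma": 1.0, "agreement": a,
                 "labels": np.zeros(4, dtype=int)}
                for i, a in enumerate(agreements)]
        return ConsensusSolution(pd.DataFrame(rows))

    def test_sixteen_solutions_keep_at_most_four(self):
        cons = self._cons(np.linspace(0.1, 0.9, 16))
        kept = filter_solutions(cons)
        assert len(kept.solutions) <= 4
        assert kept.solutions["agreement"].min() > \
            np.percentile(np.linspace(0.1, 0.9, 16), 75)

    def test_all_equal_keeps_none_with_warning(self):
        cons = self._cons([0.5] * 6)
        with pytest.warns(UserWarning):
            kept = filter_solutions(cons)
        assert kept.solutions.empty

    def test_retained_have_maximal_agreement(self):
        agreements = [0.2, 0.9, 0.4, 0.8, 0.3, 0.7]
        kept = filter_solutions(self._cons(agreements))
        dropped_max = max(a for a in agreements
                          if a not in set(kept.solutions["agreement"]))
        assert kept.solutions["agreement"].min() > dropped_max


class TestClusteringTree:
    def test_nested_partitions_single_parent_edges(self):
        coarse = np.array([0, 0, 0, 1, 1, 1])
        fine = np.array([0, 0, 1, 2, 2, 3])
        cons = ConsensusSolution(pd.DataFrame([
            {"k": 2, "gamma": 1.0, "agreement": 0.9, "labels": coarse},
            {"k": 4, "gamma": 1.0, "agreement": 0.8, "labels": fine}]))
        edges = clustering_tree_edges(cons)
        per_child = edges.groupby("cluster_child").size()
        assert (per_child == 1).all()

    def test_edge_counts_conserve_cluster_sizes(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 3, 40)
        b = rng.integers(0, 5, 40)
        cons = ConsensusSolution(pd.DataFrame([
            {"k": 3, "gamma": 1.0, "agreement": 0.9, "labels": a},
            {"k": 5, "gamma": 1.0, "agreement": 0.8, "labels": b}]))
        edges = clustering_tree_edges(cons)
        for c in np.unique(a):
            out = edges[edges["cluster_parent"] == c]["n_shared"].sum()
            assert out == (a == c).sum()
        ct = pd.crosstab(a, b)
        for row in edges.itertuples():
            assert ct.loc[row.cluster_parent, row.cluster_child] == row.n_shared
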