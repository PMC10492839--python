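import numpy as np
import pandas as pd
import pytest

from lvlink.containers import LabelledMatrix
from lvlink.repurposing import (evaluate, lv_contributions, raw_scores,
                                score_pairs, topk_restrict)
from lvlink.studies import brute_force_rank_scores


def _lm(values, rows=None, cols=None):
    values = np.asarray(values, dtype=float)
    rows = rows or [f"g{i}" for i in range(values.shape[0])]
    cols = cols or [f"c{j}" for j in range(values.shape[1])]
    return LabelledMatrix(values, rows, cols)


class TestTopkRestrict:
    def test_all_keeps_input(self):
        m = _lm([[3.0], [-2.0], [1.0]])
        assert topk_restrict(m, "all") is m

    def test_magnitude_order(self):
        m = _lm([[3.0], [-2.0], [1.0]])
        out = topk_restrict(m, 2)
        np.testing.assert_array_equal(out.values[:, 0], [3.0, -2.0, 0.0])

    def test_tie_keeps_lexicographically_first(self):
        m = _lm([[2.0], [2.0], [1.0]], rows=["gb", "ga", "gc"])
        out = topk_restrict(m, 1)
        np.testing.assert_array_equal(out.values[:, 0], [0.0, 2.0, 0.0])

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            topk_restrict(_lm([[1.0]]), 0)


class TestRawScores:
    def test_reversal_sign_convention(self):
        # trait z = +2, drug z = -1 on one gene: reversal scores positive
        mt = _lm([[2.0]], cols=["tr"])
        drug = _lm([[-1.0]], cols=["d"])
        assert raw_scores(mt, drug).values[0, 0] == 2.0

    def test_orthogonal_profile_scores_zero(self):
        mt = _lm([[1.0], [0.0]], cols=["tr"])
        drug = _lm([[0.0], [1.0]], cols=["d"])
        assert raw_scores(mt, drug).values[0, 0] == 0.0

    def test_antisymmetry_under_profile_negation(self):
        rng = np.random.default_rng(0)
        mt = _lm(rng.standard_normal((6, 2)))
        drug = _lm(rng.standard_normal((6, 3)))
        neg = _lm(-drug.values, cols=drug.col_ids)
        np.testing.assert_allclose(raw_scores(mt, neg).values,
                                   -raw_scores(mt, drug).values)


class TestScorePairs:
    def _case(self, seed=0):
        rng = np.random.default_rng(seed)
        mt = {"tisA": _lm(rng.standard_normal((5, 2)), cols=["tr0", "tr1"]),
              "tisB": _lm(rng.standard_normal((5, 2)), cols=["tr0", "tr1"])}
        drugs = _lm(rng.standard_normal((5, 3)), cols=["d0", "d1", "d2"])
        return mt, drugs

    def test_matches_brute_force_oracle(self):
        mt, drugs = self._case()
        scores = score_pairs(mt, drugs, k_grid=("all", 1, 2))
        oracle = brute_force_rank_scores(mt, drugs, ("all", 1, 2))
        np.testing.assert_allclose(scores.final.values, oracle, atol=1e-12)

    def test_final_is_max_over_tissues(self):
        mt, drugs = self._case(1)
        scores = score_pairs(mt, drugs, k_grid=("all", 2))
        stacked = np.stack([scores.per_tissue[t].values for t in mt])
        np.testing.assert_array_equal(scores.final.values, stacked.max(axis=0))

    def test_rank_average_invariant_to_monotone_transform(self):
        mt, drugs = self._case(2)
        base = score_pairs(mt, drugs, k_grid=("all",))
        # applying a strictly increasing transform to the raw scores does not
        # change within-trait compound ranks; emulate by scaling all inputs
        mt_scaled = {t: _lm(m.values * 3.0, cols=m.col_ids)
                     for t, m in mt.items()}
        scaled = score_pairs(mt_scaled, drugs, k_grid=("all",))
        np.testing.assert_array_equal(base.final.values, scaled.final.values)

    def test_empty_axis_errors(self):
        with pytest.raises(ValueError):
            score_pairs({}, _lm([[1.0]]))


class TestLvContributions:
    def test_additivity(self):
        rng = np.random.default_rng(3)
        mhat = _lm(rng.standard_normal((20, 2)),
                   rows=[f"LV{i}" for i in range(20)], cols=["tr0", "tr1"])
        lhat = _lm(rng.standard_normal((20, 3)),
                   rows=[f"LV{i}" for i in range(20)], cols=["d0", "d1", "d2"])
        contrib = lv_contributions(mhat, lhat, "d1", "tr0")
        total = raw_scores(mhat, lhat).values[1, 0]
        assert abs(contrib["contribution"].sum() - total) < 1e-10
        assert list(contrib["contribution"]) == sorted(
            contrib["contribution"], reverse=True)

    def test_single_lv_toy(self):
        mhat = _lm([[2.0]], rows=["LV0"], cols=["tr"])
        lhat = _lm([[-1.5]], rows=["LV0"], cols=["d"])
        contrib = lv_contributions(mhat, lhat, "d", "tr")
        assert contrib.loc[0, "lv"] == "LV0"
        assert contrib.loc[0, "contribution"] == 3.0

    def test_sign_flip_reverses_contributions(self):
        rng = np.random.default_rng(4)
        mhat = _lm(rng.standard_normal((5, 1)), rows=[f"LV{i}" for i in range(5)],
                   cols=["tr"])
        lhat = _lm(rng.standard_normal((5, 1)), rows=[f"LV{i}" for i in range(5)],
                   cols=["d"])
        neg = _lm(-lhat.values, rows=lhat.row_ids, cols=["d"])
        c1 = lv_contributions(mhat, lhat, "d", "tr").set_index("lv")
        c2 = lv_contributions(mhat, neg, "d", "tr").set_index("lv")
        np.testing.assert_allclose(c2.loc[c1.index, "contribution"],
                                   -c1["contribution"])

    def test_unknown_ids_error(self):
        mhat = _lm([[1.0]], rows=["LV0"], cols=["tr"])
        lhat = _lm([[1.0]], rows=["LV0"], cols=["d"])
        with pytest.raises(KeyError):
            lv_contributions(mhat, lhat, "nope", "tr")


class TestEvaluate:
    def _gold(self, scores, positives):
        rows = []
        for c in scores.row_ids:
            for t in scores.col_ids:
                rows.append({"compound": c, "trait": t,
                             "indicated": (c, t) in positives})
        return pd.DataFrame(rows)

    def test_perfect_separation(self):
        scores = _lm([[10.0], [1.0]], rows=["good", "bad"], cols=["tr"])
        gold = self._gold(scores, {("good", "tr")})
        res = evaluate(scores, gold, n_permutations=10, seed=0)
        assert res["auroc"] == 1.0 and res["average_precision"] == 1.0

    def test_constant_scores_give_half(self):
        scores = _lm([[1.0], [1.0], [1.0]], rows=["a", "b", "c"], cols=["tr"])
        gold = self._gold(scores, {("a", "tr")})
        assert evaluate(scores, gold, n_permutations=5, seed=0)["auroc"] == 0.5

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(5)
        scores = _lm(rng.standard_normal((10, 1)),
                     rows=[f"d{i}" for i in range(10)], cols=["tr"])
        positives = {(f"d{i}", "tr") for i in (0, 3, 7)}
        gold = self._gold(scores, positives)
        res = evaluate(scores, gold, n_permutations=5, seed=0)
        s = scores.values[:, 0]
        y = np.array([(f"d{i}", "tr") in positives for i in range(10)])
        num = den = 0.0
        for i in np.flatnonzero(y):
            for j in np.flatnonzero(~y):
                den += 1
                num += (s[i] > s[j]) + 0.5 * (s[i] == s[j])
        assert abs(res["auroc"] - num / den) < 1e-12

    def test_single_class_errors(self):
        scores = _lm([[1.0], [2.0]], rows=["a", "b"], cols=["tr"])
        gold = self._gold(scores, {("a", "tr"), ("b", "tr")})
        with pytest.raises(ValueError):
            evaluate(scores, gold)
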