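import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from lvlink.containers import LatentModel, RunConfig, TwasResultSet
from lvlink.containers import LabelledMatrix
from lvlink.correlation import LvSubCorrelation
from lvlink.regression import (RegressionInput, bh_adjust, build_design,
                               gls_fit, regress_all)


def _model(n_genes=20, n_lvs=2, seed=0):
    rng = np.random.default_rng(seed)
    Z = rng.uniform(0.01, 0.05, size=(n_genes, n_lvs))
    Z[:4, 0] += 1.0
    Z[4:8, 1] += 1.0
    return LatentModel(Z, 0.5, [f"g{i:02d}" for i in range(n_genes)],
                       [f"LV{j}" for j in range(n_lvs)])


def _meta(model, seed=1):
    rng = np.random.default_rng(seed)
    k = rng.integers(1, 4, model.n_genes)
    p = k + rng.integers(0, 3, model.n_genes)
    return pd.DataFrame({"k": k, "p": np.maximum(p, k)}, index=model.gene_ids)


class TestBuildDesign:
    def test_p_one_gives_zero_m(self):
        model = _model()
        pv = pd.Series(1.0, index=model.gene_ids)
        with pytest.warns(UserWarning, match="identical"):
            inp = build_design(pv, model, "LV0", _meta(model), fraction=0.2)
        np.testing.assert_array_equal(inp.m, 0.0)

    def test_clamp_at_floor(self):
        model = _model()
        pv = pd.Series(1e-310, index=model.gene_ids)
        with pytest.warns(UserWarning):
            inp = build_design(pv, model, "LV0", _meta(model), fraction=0.2)
        np.testing.assert_allclose(inp.m, 300.0)

    def test_membership_count_matches_fraction(self):
        model = _model(n_genes=200)
        pv = pd.Series(np.linspace(0.01, 0.99, 200), index=model.gene_ids)
        inp = build_design(pv, model, "LV0", _meta(model), fraction=0.01)
        assert inp.s.sum() == 2


class TestGlsFit:
    def _inputs(self, seed=0, n=60, m=6, beta=0.0):
        rng = np.random.default_rng(seed)
        gene_ids = [f"g{i:02d}" for i in range(n)]
        s = np.zeros(n)
        member_ids = gene_ids[:m]
        s[:m] = 1.0
        cov = pd.DataFrame({"gene_size": rng.integers(1, 5, n).astype(float),
                            "gene_density": rng.uniform(0.3, 1.0, n)},
                           index=gene_ids)
        y = rng.standard_normal(n) + beta * s
        inp = RegressionInput(m=y, s=s, covariates=cov, gene_ids=gene_ids,
                              trait_id="t", lv_id="LV0")
        A = rng.standard_normal((m, m + 3))
        S = A @ A.T / (m + 3)
        d = np.sqrt(np.diag(S))
        R = S / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        return inp, LvSubCorrelation("LV0", member_ids, R)

    def test_identity_correlation_equals_ols(self):
        inp, sub = self._inputs()
        sub_id = LvSubCorrelation("LV0", sub.gene_ids, np.eye(len(sub.gene_ids)))
        res = gls_fit(inp, sub_id)
        from lvlink.regression import _design_matrix
        X, _ = _design_matrix(inp)
        ols = sm.OLS(inp.m, X).fit()
        assert abs(res.beta_s - ols.params[1]) < 1e-10
        assert abs(res.se - ols.bse[1]) < 1e-10

    def test_matches_statsmodels_gls(self):
        """Independent cross-check: full dense covariance via statsmodels."""
        inp, sub = self._inputs(seed=3)
        res = gls_fit(inp, sub)
        from lvlink.regression import _design_matrix, _member_indices
        X, _ = _design_matrix(inp)
        sigma = np.eye(len(inp.m))
        idx = _member_indices(inp, sub)
        sigma[np.ix_(idx, idx)] = sub.R
        ref = sm.GLS(inp.m, X, sigma=sigma).fit()
        assert abs(res.beta_s - ref.params[1]) < 1e-8
        assert abs(res.se - ref.bse[1]) < 1e-8
        # one-sided upper-tail p from the same t statistic
        from scipy import stats
        p_ref = stats.t.sf(ref.tvalues[1], ref.df_resid)
        assert abs(res.p_one_sided - p_ref) < 1e-10

    def test_intercept_absorbs_constant_shift(self):
        inp, sub = self._inputs(seed=5)
        res1 = gls_fit(inp, sub)
        shifted = RegressionInput(m=inp.m + 7.0, s=inp.s,
                                  covariates=inp.covariates,
                                  gene_ids=inp.gene_ids, trait_id="t",
                                  lv_id="LV0")
        res2 = gls_fit(shifted, sub)
        assert abs(res1.beta_s - res2.beta_s) < 1e-10

    def test_planted_effect_detected(self):
        inp, sub = self._inputs(seed=6, beta=2.0)
        res = gls_fit(inp, sub)
        assert res.beta_s > 1.0
        assert res.p_one_sided < 0.01


class TestBhAdjust:
    def test_step_up_example(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.03])),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.2])), [0.2])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_adjust(np.ones(5)), 1.0)

    def test_empty_input(self):
        assert bh_adjust(np.array([])).size == 0

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1.0, 20)
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        np.testing.assert_allclose(bh_adjust(p), adj, atol=1e-12)


class TestRegressAll:
    def _twas(self, model, n_traits=5, seed=0):
        rng = np.random.default_rng(seed)
        pv = LabelledMatrix(rng.uniform(0.001, 1.0, (model.n_genes, n_traits)),
                            model.gene_ids, [f"tr{j}" for j in range(n_traits)],
                            orientation="rows=genes")
        return TwasResultSet(pvalues=pv, gene_meta=_meta(model))

    def _corrs(self, model, fraction):
        from lvlink.containers import top_lv_genes
        out = {}
        for lv in model.lv_ids:
            members = top_lv_genes(model, lv, fraction)
            out[lv] = LvSubCorrelation(lv, members, np.eye(len(members)))
        return out

    def test_row_count_is_cartesian(self):
        model = _model()
        twas = self._twas(model)
        table = regress_all(twas, model, self._corrs(model, 0.2),
                            RunConfig(top_gene_fraction=0.2))
        assert len(table) == model.n_lvs * 5
        assert set(table.columns) >= {"lv", "trait", "beta", "se", "stat",
                                      "pval", "fdr", "n_members"}

    def test_trait_permutation_only_permutes_rows(self):
        model = _model()
        twas = self._twas(model)
        perm = [3, 1, 4, 0, 2]
        pv = twas.pvalues
        twas_p = TwasResultSet(
            pvalues=LabelledMatrix(pv.values[:, perm], pv.row_ids,
                                   [pv.col_ids[j] for j in perm]),
            gene_meta=twas.gene_meta)
        cfg = RunConfig(top_gene_fraction=0.2)
        t1 = regress_all(twas, model, self._corrs(model, 0.2), cfg)
        t2 = regress_all(twas_p, model, self._corrs(model, 0.2), cfg)
        merged = t1.merge(t2, on=["lv", "trait"], suffixes=("_a", "_b"))
        assert len(merged) == len(t1)
        np.testing.assert_allclose(merged["beta_a"], merged["beta_b"],
                                   atol=1e-12)

    def test_fdr_family_per_trait(self):
        model = _model()
        twas = self._twas(model)
        cfg = RunConfig(top_gene_fraction=0.2, bh_family="per-trait")
        table = regress_all(twas, model, self._corrs(model, 0.2), cfg)
        for _, grp in table.groupby("trait"):
            np.testing.assert_allclose(
                grp["fdr"], bh_adjust(grp["pval"].to_numpy()), atol=1e-12)
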