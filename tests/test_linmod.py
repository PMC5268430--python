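import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import cosig
from cosig.linmod import GenewiseFit, _trigamma_inverse
from scipy import special


def _two_group_expr(rng, genes=50, per_group=3, weights=None):
    y = rng.normal(size=(genes, 2 * per_group))
    idx = [f"g{i}" for i in range(genes)]
    cols = [f"s{j}" for j in range(2 * per_group)]
    w = None
    if weights is not None:
        w = pd.DataFrame(weights, index=idx, columns=cols)
    expr = cosig.LogExpression(pd.DataFrame(y, index=idx, columns=cols), weights=w)
    groups = pd.Series(["A"] * per_group + ["B"] * per_group, index=cols)
    return expr, cosig.group_means_design(groups)


class TestDesign:
    def test_rank_deficient_design_rejected_naming_alias(self):
        m = pd.DataFrame({"a": [1.0, 1, 1, 1], "b": [1.0, 1, 0, 0], "c": [0.0, 0, 1, 1]})
        with pytest.raises(ValueError, match="aliased"):
            cosig.Design(m)

    def test_contrast_length_checked(self):
        m = pd.DataFrame({"a": [1.0, 0], "b": [0.0, 1]})
        with pytest.raises(ValueError, match="length"):
            cosig.Design(m, contrasts={"bad": np.array([1.0])})


class TestGenewiseFit:
    def test_group_contrast_equals_difference_of_means(self, rng):
        expr, design = _two_group_expr(rng)
        fit = cosig.fit_genewise_lm(expr, design)
        beta, _ = fit.contrast_fit("A-B")
        y = expr.values
        expect = y.iloc[:, :3].mean(axis=1) - y.iloc[:, 3:].mean(axis=1)
        assert np.allclose(beta, expect, atol=1e-12)

    def test_constant_weights_match_unweighted_fit(self, rng):
        expr_u, design = _two_group_expr(rng)
        expr_w = cosig.LogExpression(expr_u.values,
                                     weights=expr_u.values * 0 + 7.5)
        fu = cosig.fit_genewise_lm(expr_u, design)
        fw = cosig.fit_genewise_lm(expr_w, design)
        assert np.allclose(fu.coef, fw.coef, atol=1e-10)
        # weighted residual variance scales by the constant weight
        assert np.allclose(fw.sigma2, fu.sigma2 * 7.5, atol=1e-10)

    def test_weighted_fit_matches_bruteforce_normal_equations(self, rng):
        w = rng.uniform(0.2, 5.0, size=(5, 6))
        expr, design = _two_group_expr(rng, genes=5, weights=w)
        fit = cosig.fit_genewise_lm(expr, design)
        X = design.matrix.to_numpy()
        Y = expr.values.to_numpy()
        for g in range(5):
            Wg = np.diag(w[g])
            beta = np.linalg.solve(X.T @ Wg @ X, X.T @ Wg @ Y[g])
            assert np.allclose(fit.coef.iloc[g], beta, atol=1e-10)
            r = Y[g] - X @ beta
            s2 = (r * w[g]) @ r / fit.df_residual
            assert fit.sigma2.iloc[g] == pytest.approx(s2, abs=1e-10)


class TestVoom:
    def test_homoscedastic_data_gets_nearly_flat_weights(self):
        rng = np.random.Generator(np.random.PCG64(1))
        # constant-CV counts: log-scale variance independent of abundance
        mu = np.exp(rng.uniform(np.log(200), np.log(5000), size=400))
        counts = rng.poisson(mu[:, None] * np.exp(rng.normal(0, 0.3, size=(400, 6))))
        cm = cosig.CountMatrix(
            pd.DataFrame(counts, index=[f"g{i}" for i in range(400)],
                         columns=[f"s{j}" for j in range(6)]))
        design = cosig.group_means_design(
            pd.Series(list("AAABBB"), index=cm.samples))
        v = cosig.voom_weights(cm, design)
        w = v.weights.to_numpy()
        assert w.max() / w.min() < 2.0

    def test_weights_equal_trend_value_to_minus_fourth_power(self, study):
        # definitional: w = trend(fitted log-count)^-4, recomputed from the
        # stored trend and an independent OLS of the same log-CPM values
        v = study["vexpr"]
        cm, design, norm = study["filtered"], study["design"], study["norm"]
        lib = cm.lib_sizes.to_numpy() * norm.factors.to_numpy()
        y = np.log2((cm.counts.to_numpy() + 0.5) / (lib + 1.0) * 1e6)
        X = design.matrix.to_numpy()
        beta = np.linalg.lstsq(X, y.T, rcond=None)[0].T
        fitted_logcount = beta @ X.T + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
        tx, ty = v.provenance["trend_x"], v.provenance["trend_y"]
        expect = np.interp(fitted_logcount, tx, ty) ** -4.0
        assert np.allclose(v.weights.to_numpy(), expect, rtol=1e-8)

    def test_nb_counts_weights_track_abundance(self):
        rng = np.random.Generator(np.random.PCG64(2))
        mu = np.exp(rng.uniform(np.log(2), np.log(2000), size=500))
        lam = rng.gamma(10.0, mu[:, None] / 10.0, size=(500, 6))
        counts = rng.poisson(lam)
        cm = cosig.CountMatrix(
            pd.DataFrame(counts, index=[f"g{i}" for i in range(500)],
                         columns=[f"s{j}" for j in range(6)]))
        design = cosig.group_means_design(pd.Series(list("AAABBB"), index=cm.samples))
        v = cosig.voom_weights(cm, design)
        rho = stats.spearmanr(v.weights.to_numpy().ravel(),
                              np.log(counts + 0.5).ravel()).statistic
        assert rho > 0.8

    def test_matches_reference_voom_weights(self):
        # frozen oracle: limma 3.58.1 voom on this generated fixture
        cfg = cosig.SimConfig(seed=3, n_genes=300, populations=("A", "B"),
                              genes_per_signature=10)
        cm, _ = cosig.gen_population_counts(cfg)
        norm = cosig.tmm_factors(cm)
        design = cosig.group_means_design(cm.groups)
        v = cosig.voom_weights(cm, design, norm=norm)
        expected = [4.856014, 5.026331, 5.838067]  # first 3 genes, sample 1
        assert np.allclose(v.weights.iloc[:3, 0], expected, rtol=5e-3)


class TestModeration:
    def _fit_from_s2(self, s2, df):
        g = len(s2)
        design = cosig.group_means_design(
            pd.Series(["A", "A", "B", "B"], index=list("wxyz")))
        return GenewiseFit(
            coef=pd.DataFrame(np.zeros((g, 2)), columns=["A", "B"]),
            cov_unscaled=np.eye(2)[None],
            sigma2=pd.Series(s2),
            df_residual=float(df),
            amean=pd.Series(np.zeros(g)),
            design=design,
        )

    def test_equal_variances_give_infinite_prior_df(self):
        prior = cosig.moderate_variances(self._fit_from_s2(np.full(100, 2.5), 4))
        assert np.isinf(prior.df_prior)
        assert prior.var_prior == pytest.approx(2.5)
        assert np.allclose(prior.var_post, 2.5)

    def test_huge_spread_leaves_variances_nearly_unshrunk(self, rng):
        s2 = np.exp(rng.normal(0, 6, size=2000))
        prior = cosig.moderate_variances(self._fit_from_s2(s2, 50))
        # d0 -> 0 limit: posterior approaches the genewise variances
        ratio = prior.var_post.to_numpy() / s2
        assert np.median(np.abs(np.log(ratio))) < 0.05

    def test_matches_reference_squeezevar(self):
        # frozen oracle: limma 3.58.1 squeezeVar(s2, df=6) on this fixture
        gen = np.random.Generator(np.random.PCG64(42))
        gen.integers(0, 400, size=(30, 4))  # stream position as when frozen
        s2 = gen.chisquare(4, size=50) * 2.0 / 4.0
        prior = cosig.moderate_variances(self._fit_from_s2(s2, 6))
        assert prior.df_prior == pytest.approx(9.74415281, abs=1e-6)
        assert prior.var_prior == pytest.approx(1.42009438, abs=1e-6)
        assert np.allclose(prior.var_post[:3],
                           [1.1762154978, 0.9937584939, 1.5975464650], atol=1e-8)

    def test_scaled_inverse_chisq_parameter_recovery(self):
        rng = np.random.Generator(np.random.PCG64(7))
        d0, s02, d = 4.0, 2.0, 6
        s2 = s02 * d0 / rng.chisquare(d0, size=10000) * rng.chisquare(d, size=10000) / d
        prior = cosig.moderate_variances(self._fit_from_s2(s2, d))
        assert abs(prior.df_prior - d0) < 0.5
        assert abs(prior.var_prior - s02) / s02 < 0.05

    def test_shrinkage_stays_between_genewise_and_prior(self, rng):
        s2 = np.exp(rng.normal(0, 1, size=500))
        prior = cosig.moderate_variances(self._fit_from_s2(s2, 5))
        lo = np.minimum(s2, prior.var_prior)
        hi = np.maximum(s2, prior.var_prior)
        post = prior.var_post.to_numpy()
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)

    def test_trigamma_inverse_roundtrip(self):
        for y in [0.1, 0.7, 3.0, 42.0]:
            x = float(special.polygamma(1, y))
            assert _trigamma_inverse(x) == pytest.approx(y, rel=1e-8)


class TestTreat:
    def _simple_fit_prior(self, rng):
        expr, design = _two_group_expr(rng, genes=200)
        fit = cosig.fit_genewise_lm(expr, design)
        return fit, cosig.moderate_variances(fit)

    def test_tau_one_reduces_to_two_sided_moderated_t(self, rng):
        fit, prior = self._simple_fit_prior(rng)
        tr = cosig.treat_test(fit, prior, "A-B", tau_fc=1.0)
        beta, u = fit.contrast_fit("A-B")
        se = np.sqrt(prior.var_post.to_numpy()) * u.to_numpy()
        expect = 2 * stats.t.sf(np.abs(beta.to_numpy()) / se, prior.df_total)
        assert np.allclose(tr.table["p"], expect, atol=0, rtol=1e-12)

    def test_hand_evaluated_two_tail_formula(self):
        # beta=1.0, se=0.2, df=10, tau=1.2
        delta = np.log2(1.2)
        expect = stats.t.sf((1.0 - delta) / 0.2, 10) + stats.t.sf((1.0 + delta) / 0.2, 10)
        design = cosig.Design(pd.DataFrame({"mu": [1.0] * 11}), contrasts={"c": np.array([1.0])})
        fit = GenewiseFit(
            coef=pd.DataFrame({"mu": [1.0, 1.0]}),
            cov_unscaled=np.array([[[0.2**2]]]),
            sigma2=pd.Series([1.0, 1.0]),
            df_residual=10.0,
            amean=pd.Series([0.0, 0.0]),
            design=design,
        )
        prior = cosig.ModerationPrior(df_prior=np.inf, var_prior=1.0,
                                      var_post=pd.Series([1.0, 1.0]), df_total=10.0)
        tr = cosig.treat_test(fit, prior, "c", tau_fc=1.2)
        assert tr.table["p"].iloc[0] == pytest.approx(expect, abs=1e-12)

    def test_p_monotone_in_threshold_and_null_effect_never_passes(self, rng):
        fit, prior = self._simple_fit_prior(rng)
        taus = [1.0, 1.05, 1.1, 1.2]
        ps = [cosig.treat_test(fit, prior, "A-B", tau_fc=t).table["p"].to_numpy()
              for t in taus]
        for a, b in zip(ps, ps[1:]):
            assert np.all(b >= a - 1e-12)

    def test_invalid_threshold_rejected(self, rng):
        fit, prior = self._simple_fit_prior(rng)
        with pytest.raises(ValueError, match="tau_fc"):
            cosig.treat_test(fit, prior, "A-B", tau_fc=0.9)


class TestBH:
    def test_stepup_by_hand(self):
        adj = cosig.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_identical_and_single(self):
        assert np.allclose(cosig.bh_fdr([0.3, 0.3, 0.3]), 0.3)
        assert cosig.bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_nan_propagates_and_is_excluded_from_m(self):
        adj = cosig.bh_fdr([0.01, np.nan, 0.02])
        assert np.isnan(adj[1])
        assert adj[0] == pytest.approx(0.02)  # m=2, not 3

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_order_preserving(self, pvals):
        p = np.array(pvals)
        adj = cosig.bh_fdr(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_global_null_false_discovery_fraction(self):
        rng = np.random.Generator(np.random.PCG64(13))
        y = rng.normal(size=(5000, 8))
        expr = cosig.LogExpression(
            pd.DataFrame(y, index=[f"g{i}" for i in range(5000)],
                         columns=[f"s{j}" for j in range(8)]))
        design = cosig.group_means_design(pd.Series(list("AAAABBBB"), index=expr.samples))
        fit = cosig.fit_genewise_lm(expr, design)
        prior = cosig.moderate_variances(fit)
        res = cosig.moderated_t_test(fit, prior, "A-B")
        frac = float((res.table["adj_p"] < 0.05).mean())
        sd = np.sqrt(0.05 * 0.95 / 5000)
        assert frac <= 0.05 + 3 * sd

    def test_voom_fit_pipeline_is_reproducible(self):
        def run():
            cfg = cosig.SimConfig(seed=21, n_genes=600)
            cm, _ = cosig.gen_population_counts(cfg)
            design = cosig.group_means_design(cm.groups)
            v = cosig.voom_weights(cm, design)
            fit = cosig.fit_genewise_lm(v, design)
            return fit.coef.to_numpy().copy(), fit.sigma2.to_numpy().copy()

        c1, s1 = run()
        c2, s2 = run()
        assert np.array_equal(c1, c2) and np.array_equal(s1, s2)
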