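"""Count GLMs, stepwise selection, LRT, GVIF, mixed models, permutation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from moundscape.inference import (
    SingularDesignError,
    backward_stepwise,
    fit_count_glm,
    fit_lm,
    fit_nb_mixed,
    gvif,
    likelihood_ratio_test,
    permutation_pvalue,
    predict_effect,
)


def nb_draw(rng, mu, theta):
    return rng.negative_binomial(theta, theta / (theta + mu))


class TestCountGlm:
    def test_intercept_only_poisson_closed_form(self):
        res = fit_count_glm([1, 2, 3], pd.DataFrame(index=range(3)), family="poisson")
        assert res.coef("const") == pytest.approx(np.log(2.0), abs=1e-8)

    def test_all_zero_response_boundary_warning(self):
        with pytest.warns(UserWarning, match="boundary"):
            fit_count_glm([0, 0, 0, 0], pd.DataFrame(index=range(4)), family="poisson")

    def test_nb_simulation_recovery(self):
        rng = np.random.default_rng(7)
        n = 2000
        x = rng.standard_normal(n)
        mu = np.exp(0.5 + 0.3 * x)
        y = nb_draw(rng, mu, theta=2.0)
        res = fit_count_glm(y, pd.DataFrame({"x": x}), family="negbin")
        assert res.converged
        for term, truth in (("const", 0.5), ("x", 0.3)):
            se = res.params.loc[term, "se"]
            assert res.coef(term) == pytest.approx(truth, abs=3 * se)
        assert res.theta == pytest.approx(2.0, rel=0.3)

    def test_nb_on_poisson_data_approaches_poisson_fit(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1500)
        y = rng.poisson(np.exp(0.2 + 0.4 * x))
        pois = fit_count_glm(y, pd.DataFrame({"x": x}), family="poisson")
        nb = fit_count_glm(y, pd.DataFrame({"x": x}), family="negbin")
        assert nb.theta > 100  # dispersion runs toward the Poisson limit
        for term in ("const", "x"):
            assert nb.coef(term) == pytest.approx(pois.coef(term), abs=1e-4)

    def test_rank_deficient_design(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(SingularDesignError):
            fit_count_glm([1, 2, 1, 2], X, family="poisson")

    def test_dispersion_ratio_near_one_for_poisson_data(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(2.0, 1000)
        res = fit_count_glm(y, pd.DataFrame(index=range(1000)), family="poisson")
        assert res.dispersion_ratio == pytest.approx(1.0, abs=0.15)

    def test_non_integer_response_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            fit_count_glm([1.5, 2.0], pd.DataFrame(index=range(2)), family="poisson")


class TestStepwise:
    def test_noise_column_removed_signal_retained(self):
        rng = np.random.default_rng(5)
        n = 500
        X = pd.DataFrame(
            {"signal": rng.standard_normal(n), "noise": rng.standard_normal(n)}
        )
        y = nb_draw(rng, np.exp(0.3 + 0.6 * X["signal"]), theta=3.0)
        trace = backward_stepwise(y, X, family="negbin")
        assert trace.final.terms == ["signal"]
        assert [s[0] for s in trace.steps] == ["noise"]

    def test_no_removal_when_all_significant(self):
        rng = np.random.default_rng(6)
        n = 800
        X = pd.DataFrame(
            {"a": rng.standard_normal(n), "b": rng.standard_normal(n)}
        )
        y = nb_draw(rng, np.exp(0.2 + 0.5 * X["a"] - 0.5 * X["b"]), theta=3.0)
        trace = backward_stepwise(y, X, family="negbin")
        assert trace.steps == []
        assert set(trace.final.terms) == {"a", "b"}

    def test_alpha_one_keeps_full_model(self, rng):
        X = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        y = rng.poisson(1.0, 200)
        trace = backward_stepwise(y, X, family="poisson", alpha=1.0000001)
        assert set(trace.final.terms) == {"a", "b", "c"}

    def test_alpha_zero_removes_everything(self, rng):
        X = pd.DataFrame(rng.standard_normal((200, 2)), columns=list("ab"))
        y = rng.poisson(np.exp(0.5 + 0.8 * X["a"]))
        with pytest.warns(UserWarning, match="intercept-only"):
            trace = backward_stepwise(y, X, family="poisson", alpha=1e-300)
        assert trace.final.terms == []
        assert trace.all_removed

    def test_near_collinear_pair_resolved_deterministically(self):
        rng = np.random.default_rng(8)
        n = 600
        z = rng.standard_normal(n)
        X = pd.DataFrame({"c1": z, "c2": z + 1e-8 * rng.standard_normal(n)})
        y = rng.poisson(np.exp(0.2 + 0.5 * z))
        t1 = backward_stepwise(y, X, family="poisson")
        t2 = backward_stepwise(y, X, family="poisson")
        assert len(t1.final.terms) == 1
        assert t1.final.terms == t2.final.terms


class TestLRT:
    def test_identical_models(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(2, 100)
        m = fit_count_glm(y, pd.DataFrame(index=range(100)), family="poisson")
        stat, df, p = likelihood_ratio_test(m, m)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert (df, p) == (0, 1.0)

    def test_poisson_data_does_not_prefer_nb(self):
        prefer_nb = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            y = rng.poisson(1.5, 400)
            X = pd.DataFrame(index=range(400))
            pois = fit_count_glm(y, X, family="poisson")
            nb = fit_count_glm(y, X, family="negbin")
            stat, df, p = likelihood_ratio_test(pois, nb)
            assert df == 1
            if p < 0.05:
                prefer_nb += 1
        assert prefer_nb <= 2

    def test_overdispersed_data_prefers_nb(self):
        rng = np.random.default_rng(2)
        y = nb_draw(rng, np.full(400, 2.0), theta=0.5)
        X = pd.DataFrame(index=range(400))
        pois = fit_count_glm(y, X, family="poisson")
        nb = fit_count_glm(y, X, family="negbin")
        stat, df, p = likelihood_ratio_test(pois, nb)
        assert p < 1e-6

    def test_different_n_rejected(self):
        rng = np.random.default_rng(4)
        m1 = fit_count_glm(rng.poisson(2, 50), pd.DataFrame(index=range(50)),
                           family="poisson")
        m2 = fit_count_glm(rng.poisson(2, 60), pd.DataFrame(index=range(60)),
                           family="poisson")
        with pytest.raises(ValueError, match="different"):
            likelihood_ratio_test(m1, m2)


class TestGvif:
    def test_orthonormal_design_exactly_one(self):
        X = pd.DataFrame(
            {"a": [1.0, 1, -1, -1], "b": [1.0, -1, 1, -1], "c": [1.0, -1, -1, 1]}
        )
        out = gvif(X)
        for v in out.values():
            assert v == pytest.approx(1.0, abs=1e-12)

    def test_half_correlation_closed_form(self):
        c1 = np.array([1.0, 0.0, -1.0, 0.0])
        c2 = np.array([0.5, np.sqrt(0.75), -0.5, -np.sqrt(0.75)])
        out = gvif(pd.DataFrame({"u": c1, "v": c2}))
        assert out["u"] == pytest.approx(4.0 / 3.0, abs=1e-9)
        assert out["v"] == pytest.approx(4.0 / 3.0, abs=1e-9)

    def test_duplicated_predictor_errors(self):
        x = np.arange(5.0)
        with pytest.raises(SingularDesignError):
            gvif(pd.DataFrame({"a": x, "b": x}))

    def test_term_groups_reduce_to_vif_for_singletons(self, rng):
        X = pd.DataFrame(rng.standard_normal((300, 3)), columns=list("abc"))
        X["b"] = 0.6 * X["a"] + 0.8 * X["b"]
        grouped = gvif(X, {"a": ["a"], "b": ["b"], "c": ["c"]})
        flat = gvif(X)
        for k in flat:
            assert grouped[k] == pytest.approx(flat[k], abs=1e-12)


class TestNbMixed:
    def test_all_singletons_matches_fixed_only(self):
        rng = np.random.default_rng(10)
        n = 400
        x = rng.standard_normal(n)
        y = nb_draw(rng, np.exp(0.3 + 0.2 * x), theta=2.0)
        mixed = fit_nb_mixed(y, pd.DataFrame({"x": x}), np.arange(n))
        fixed = fit_count_glm(y, pd.DataFrame({"x": x}), family="negbin")
        assert mixed.singular  # variance collapses to ~0
        assert mixed.re_sd < 0.05
        for term in ("const", "x"):
            assert mixed.coef(term) == pytest.approx(fixed.coef(term), abs=1e-3)

    def test_group_variance_recovered(self):
        rng = np.random.default_rng(42)
        G, m = 50, 10
        u = 0.5 * rng.standard_normal(G)
        x = rng.standard_normal(G * m)
        gid = np.repeat(np.arange(G), m)
        y = nb_draw(rng, np.exp(0.2 + 0.4 * x + u[gid]), theta=2.0)
        res = fit_nb_mixed(y, pd.DataFrame({"x": x}), gid)
        assert res.converged and not res.singular
        # sigma_hat ~ 0.5 within ~3 sd of a variance estimate at G=50
        assert res.re_sd == pytest.approx(0.5, abs=0.17)
        assert res.coef("x") == pytest.approx(0.4, abs=3 * res.params.loc["x", "se"])

    def test_matches_external_reference_values(self):
        # frozen from glmmTMB (nbinom2, 1|group) on the identical dataset:
        # beta = (0.2922, 0.4024), sigma = 0.3492, theta = 1.898
        rng = np.random.default_rng(42)
        G, m = 50, 10
        u = 0.5 * rng.standard_normal(G)
        x = rng.standard_normal(G * m)
        gid = np.repeat(np.arange(G), m)
        y = nb_draw(rng, np.exp(0.2 + 0.4 * x + u[gid]), theta=2.0)
        res = fit_nb_mixed(y, pd.DataFrame({"x": x}), gid)
        assert res.coef("const") == pytest.approx(0.2922, abs=0.002)
        assert res.coef("x") == pytest.approx(0.4024, abs=0.002)
        assert res.re_sd == pytest.approx(0.3492, abs=0.005)
        assert res.theta == pytest.approx(1.898, abs=0.02)

    def test_singleton_heavy_underdispersed_setting_flagged(self):
        # most groups observed once and no true heterogeneity: the
        # variance/dispersion pair is unidentifiable and the fit must say so
        rng = np.random.default_rng(17)
        n = 282
        gid = np.concatenate([np.arange(186), np.repeat(186 + np.arange(48), 2)])
        x = rng.standard_normal(n)
        lam = np.exp(0.1 + 0.1 * x)
        y = 1 + rng.binomial(2, np.clip(lam / 3, 0, 1))  # underdispersed counts
        res = fit_nb_mixed(y, pd.DataFrame({"x": x}), gid)
        assert (not res.converged) or res.singular


class TestLm:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = fit_lm(2 * x + 1, x)
        assert res.coef("const") == pytest.approx(1.0, abs=1e-10)
        assert res.coef(0) == pytest.approx(2.0, abs=1e-10)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_orthogonalized_predictor_zero_slope(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        xc = x - x.mean()
        y = y - (y @ xc) / (xc @ xc) * xc  # orthogonal to x given intercept
        res = fit_lm(y, x)
        assert res.coef(0) == pytest.approx(0.0, abs=1e-10)

    def test_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 10, 13)
        y = 1.5 * x + rng.normal(0, 2, 13)
        res = fit_lm(y, x)
        A = np.column_stack([np.ones(13), x])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert res.coef("const") == pytest.approx(beta[0], abs=1e-10)
        assert res.coef(0) == pytest.approx(beta[1], abs=1e-10)

    def test_constant_x_singular(self):
        with pytest.raises(SingularDesignError):
            fit_lm([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestPermutation:
    def test_perfect_fit_attains_minimum_p(self):
        x = np.linspace(0, 1, 30)
        res = permutation_pvalue(x.copy(), x, n_perm=999, seed=0)
        assert res.permuted_p == pytest.approx(1.0 / 1000)

    def test_constant_y_gives_p_one(self):
        res = permutation_pvalue(np.ones(20), np.arange(20.0), n_perm=99, seed=1)
        assert res.observed_coefficient == pytest.approx(0.0)
        assert res.permuted_p == 1.0

    def test_null_uniformity(self):
        rng = np.random.default_rng(123)
        x = rng.standard_normal(50)
        ps = [
            permutation_pvalue(rng.standard_normal(50), x, n_perm=1000, seed=i).permuted_p
            for i in range(500)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        p0 = permutation_pvalue(y, x, n_perm=500, seed=11).permuted_p
        p1 = permutation_pvalue(3 * y - 7, 0.5 * x + 2, n_perm=500, seed=11).permuted_p
        assert p0 == p1

    def test_t_statistic_option(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(40)
        y = 0.8 * x + rng.standard_normal(40)
        res = permutation_pvalue(y, x, n_perm=500, seed=3, statistic="t")
        assert 0 < res.permuted_p <= 1
        assert res.statistic == "t"


class TestPredictEffect:
    def test_intercept_only_flat(self):
        rng = np.random.default_rng(14)
        y = rng.poisson(3.0, 200)
        m = fit_count_glm(y, pd.DataFrame(index=range(200)), family="poisson")
        out = predict_effect(m, "const", [1.0, 1.0])
        assert out["predicted"].nunique() == 1
        assert out["predicted"].iloc[0] == pytest.approx(y.mean(), rel=1e-6)

    def test_log_link_hand_computed(self):
        rng = np.random.default_rng(15)
        x1 = rng.standard_normal(500)
        x2 = rng.standard_normal(500)
        y = nb_draw(rng, np.exp(0.4 + 0.3 * x1 - 0.2 * x2), theta=2.0)
        m = fit_count_glm(y, pd.DataFrame({"x1": x1, "x2": x2}), family="negbin")
        grid = np.array([-1.0, 0.0, 2.0])
        out = predict_effect(m, "x1", grid)
        b = m.params["estimate"]
        expected = np.exp(b["const"] + b["x1"] * grid + b["x2"] * x2.mean())
        np.testing.assert_allclose(out["predicted"], expected, rtol=1e-10)
        assert (out["ci_lo"] <= out["predicted"]).all()
        assert (out["predicted"] <= out["ci_hi"]).all()

    def test_missing_focal_term(self):
        m = fit_lm(np.arange(5.0), np.arange(5.0) ** 2)
        with pytest.raises(ValueError, match="focal"):
            predict_effect(m, "zzz", [0.0])
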