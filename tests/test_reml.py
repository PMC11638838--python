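"""REML engine tests against closed-form ANOVA, direct-likelihood, and
profile-search oracles, plus structural invariants of the standard models."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from linetester import reml
from linetester.reml import ModelSpec, RemlError, fit_reml, lrt_variance_component


def direct_restricted_loglik(y, X, Zs, s2, s2e):
    """Dense V-based restricted likelihood, independent of the MME path."""
    n = len(y)
    V = s2e * np.eye(n)
    for Z, v in zip(Zs, s2):
        Zd = Z.toarray()
        V += v * (Zd @ Zd.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    p = X.shape[1]
    return -0.5 * (ldV + ldX + y @ P @ y + (n - p) * np.log(2 * np.pi))


def _design(df, fixed, random):
    X, _ = reml._fixed_design(df, tuple(fixed))
    Zs = []
    for t in random:
        codes, levels = reml._combined_factor(df, t)
        Zs.append(reml._indicator(codes, len(levels)))
    return X, Zs


def one_way_data(g=15, r=4, s_g=1.0, s_e=0.7, seed=42):
    rng = np.random.default_rng(seed)
    gi = np.repeat(np.arange(g), r)
    y = 5 + rng.normal(0, s_g, g)[gi] + rng.normal(0, s_e, g * r)
    return pd.DataFrame({"geno": gi.astype(str), "y": y})


def two_way_data(g=20, e=3, r=2, seed=7):
    rng = np.random.default_rng(seed)
    gi = np.repeat(np.arange(g), e * r)
    env = np.tile(np.repeat(np.arange(e), r), g)
    y = (3 + np.linspace(-1, 1, e)[env] + rng.normal(0, np.sqrt(0.6), g)[gi]
         + rng.normal(0, np.sqrt(0.3), (g, e))[gi, env]
         + rng.normal(0, np.sqrt(0.5), g * e * r))
    return pd.DataFrame({"geno": gi.astype(str), "env": env.astype(str), "y": y})


class TestBalancedAnovaEquivalence:
    def test_one_way(self):
        df = one_way_data()
        g = df["geno"].nunique()
        r = len(df) // g
        fit = fit_reml(df, ModelSpec("y", (), ("geno",)))
        gm = df.groupby("geno")["y"].mean()
        mse = (df["y"] - gm[df["geno"]].to_numpy()).pow(2).sum() / (g * (r - 1))
        msg = r * (gm - gm.mean()).pow(2).sum() / (g - 1)
        assert fit.components["geno"] == pytest.approx(max(0, (msg - mse) / r), abs=1e-8)
        assert fit.components.residual == pytest.approx(mse, abs=1e-8)

    def test_two_way_with_fixed_environment(self):
        df = two_way_data()
        g, e = df["geno"].nunique(), df["env"].nunique()
        r = len(df) // (g * e)
        fit = fit_reml(df, ModelSpec("y", ("env",), ("geno", "geno:env")))
        cell = df.groupby(["geno", "env"])["y"].mean().unstack()
        mse = (df.set_index(["geno", "env"])["y"] - cell.stack()).pow(2).sum() \
            / (g * e * (r - 1))
        gm = df["y"].mean()
        gmeans, emeans = cell.mean(axis=1), cell.mean(axis=0)
        ms_ge = r * ((cell.sub(gmeans, axis=0).sub(emeans, axis=1) + gm) ** 2
                     ).to_numpy().sum() / ((g - 1) * (e - 1))
        ms_g = e * r * (gmeans - gm).pow(2).sum() / (g - 1)
        assert fit.components["geno"] == pytest.approx((ms_g - ms_ge) / (e * r), abs=1e-8)
        assert fit.components["geno:env"] == pytest.approx((ms_ge - mse) / r, abs=1e-8)
        assert fit.components.residual == pytest.approx(mse, abs=1e-8)


class TestLikelihoodAgainstDirectOracle:
    @pytest.mark.parametrize("maker,fixed,random", [
        (one_way_data, (), ("geno",)),
        (two_way_data, ("env",), ("geno", "geno:env")),
    ])
    def test_fitted_loglik_matches_dense_formula(self, maker, fixed, random):
        df = maker()
        fit = fit_reml(df, ModelSpec("y", fixed, random))
        X, Zs = _design(df, fixed, random)
        s2 = [max(fit.components[t], 1e-10) for t in random]
        ll = direct_restricted_loglik(df["y"].to_numpy(), X, Zs, s2,
                                      fit.components.residual)
        assert fit.loglik == pytest.approx(ll, abs=1e-6)

    def test_profile_search_oracle(self):
        """Engine optimum matches a brute-force grid + simplex search of the
        dense restricted likelihood to 3 significant figures."""
        df = two_way_data(g=20, e=3, r=2, seed=31)
        fit = fit_reml(df, ModelSpec("y", ("env",), ("geno", "geno:env")))
        X, Zs = _design(df, ("env",), ("geno", "geno:env"))
        y = df["y"].to_numpy()

        def nll(logpars):
            s2 = np.exp(logpars)
            return -direct_restricted_loglik(y, X, Zs, s2[:2], s2[2])

        # coarse grid start, then simplex polish
        grid = [np.log([a, b, c])
                for a in (0.2, 0.6, 1.2) for b in (0.1, 0.3, 0.9) for c in (0.25, 0.5, 1.0)]
        best = min(grid, key=nll)
        res = minimize(nll, best, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        oracle = np.exp(res.x)
        got = np.array([fit.components["geno"], fit.components["geno:env"],
                        fit.components.residual])
        assert np.allclose(got, oracle, rtol=1e-3)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)


class TestDegenerateAndInvariance:
    def test_all_equal_observations(self):
        df = pd.DataFrame({"geno": list("aabbcc"), "y": 4.2})
        fit = fit_reml(df, ModelSpec("y", (), ("geno",)))
        assert fit.components["geno"] == 0.0
        assert 0 < fit.components.residual < 1e-6

    def test_row_permutation_invariance(self):
        df = two_way_data(seed=19)
        fit = fit_reml(df, ModelSpec("y", ("env",), ("geno", "geno:env")))
        shuffled = df.sample(frac=1, random_state=5).reset_index(drop=True)
        fit2 = fit_reml(shuffled, ModelSpec("y", ("env",), ("geno", "geno:env")))
        for t in ("geno", "geno:env"):
            assert fit2.components[t] == pytest.approx(fit.components[t], abs=1e-7)
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-6)

    def test_too_few_levels_raises(self):
        df = pd.DataFrame({"geno": ["a"] * 4, "y": [1.0, 2.0, 1.5, 2.5]})
        with pytest.raises(RemlError, match="fewer than 2 levels"):
            fit_reml(df, ModelSpec("y", (), ("geno",)))


def _lxt_frame(l_eff, t_eff, reps=2, mu=5.0, sca=None, noise=None, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i, lv in enumerate(l_eff):
        for j, tv in enumerate(t_eff):
            for r in range(reps):
                y = mu + lv + tv
                if sca is not None:
                    y += sca[i, j]
                if noise is not None:
                    y += rng.normal(0, noise)
                rows.append({"env": "E1", "rep": r + 1, "block": f"B{(i + j) % 2}",
                             "line": f"L{i:02d}", "tester": f"T{j}",
                             "entry": f"L{i:02d}:T{j}", "entry_kind": "testcross",
                             "y": y})
    return pd.DataFrame(rows)


class TestLineByTesterModels:
    def test_noise_free_effect_recovery(self):
        rng = np.random.default_rng(2)
        l_eff = rng.normal(0, 1.0, 4)
        t_eff = rng.normal(0, 0.4, 3)
        fit = reml.fit_lxt_single_env(_lxt_frame(l_eff, t_eff), "y")
        assert fit.components["line"] == pytest.approx(np.var(l_eff, ddof=1), rel=1e-4)
        assert fit.components["tester"] == pytest.approx(np.var(t_eff, ddof=1), rel=1e-4)
        assert fit.components["line:tester"] == 0.0
        assert fit.components.residual < 1e-6

    def test_additive_only_sca_collapses_to_boundary(self):
        """With no SCA in truth, the fitted SCA component collapses onto the
        zero boundary: negligible (<5% of the line variance) in at least 95%
        of seeded simulations, and exactly zero in a large share of them
        (the boundary projection puts roughly half the null mass at 0)."""
        n_sim = 100
        zeros = 0
        negligible = 0
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            df = _lxt_frame(rng.normal(0, 1.0, 60), rng.normal(0, 0.5, 3),
                            reps=4, noise=0.7, seed=seed + 1000)
            fit = reml.fit_lxt_single_env(df, "y")
            zeros += fit.components["line:tester"] == 0.0
            negligible += fit.components["line:tester"] < 0.05 * fit.components["line"]
        assert negligible >= 0.95 * n_sim
        assert zeros >= 0.3 * n_sim

    def test_across_env_collapses_to_single_env(self):
        rng = np.random.default_rng(9)
        df = _lxt_frame(rng.normal(0, 1.0, 8), rng.normal(0, 0.4, 3), noise=0.5)
        single = reml.fit_lxt_single_env(df, "y")
        with pytest.warns(UserWarning, match="single environment"):
            across = reml.fit_lxt_across_env(df, "y")
        for t in ("line", "tester", "line:tester"):
            assert across.components[t] == pytest.approx(single.components[t], abs=1e-8)

    def test_blups_sum_to_zero(self):
        rng = np.random.default_rng(3)
        df = _lxt_frame(rng.normal(0, 1.0, 10), rng.normal(0, 0.4, 3), noise=0.6)
        fit = reml.fit_lxt_single_env(df, "y")
        for term, blup in fit.blups.items():
            assert blup.sum() == pytest.approx(0.0, abs=1e-6)


class TestGenotypeModel:
    def test_single_environment_drops_gxe(self):
        df = two_way_data(seed=3).query("env == '0'").rename(columns={"geno": "entry"})
        df["rep"] = np.tile([1, 2], len(df) // 2)
        df["block"] = "B1"
        df.loc[df.rep == 2, "block"] = "B2"
        with pytest.warns(UserWarning, match="genotype-by-environment"):
            fit = reml.fit_genotype_model(df, "y")
        assert "entry:env" not in fit.components.components
        assert "entry" in fit.components.components


class TestLrt:
    def _fits(self, df, with_term=("geno", "geno:env"), without=("geno",)):
        full = fit_reml(df, ModelSpec("y", ("env",), with_term))
        red = fit_reml(df, ModelSpec("y", ("env",), without))
        return full, red

    def test_null_term_gives_zero_statistic_and_p_one(self):
        # genotype-by-env truly absent: full and reduced likelihoods coincide
        rng = np.random.default_rng(0)
        g, e, r = 15, 3, 2
        gi = np.repeat(np.arange(g), e * r)
        env = np.tile(np.repeat(np.arange(e), r), g)
        y = rng.normal(0, 1.0, g)[gi] + rng.normal(0, 0.5, g * e * r)
        df = pd.DataFrame({"geno": gi.astype(str), "env": env.astype(str), "y": y})
        full, red = self._fits(df)
        t = lrt_variance_component(full, red)
        assert t["statistic"] == pytest.approx(0.0, abs=1e-4)
        assert t["p_value"] > 0.9

    def test_scale_invariance(self):
        df = two_way_data(seed=23)
        full, red = self._fits(df)
        stat = lrt_variance_component(full, red)["statistic"]
        df2 = df.assign(y=df["y"] * 3.7)
        full2, red2 = self._fits(df2)
        stat2 = lrt_variance_component(full2, red2)["statistic"]
        assert stat2 == pytest.approx(stat, abs=1e-5)

    def test_non_nested_rejected(self):
        df = two_way_data(seed=2)
        full = fit_reml(df, ModelSpec("y", ("env",), ("geno", "geno:env")))
        other = fit_reml(df, ModelSpec("y", (), ("geno",)))
        with pytest.raises(ValueError):
            lrt_variance_component(full, other)


class TestModelSpec:
    def test_parse_grammar(self):
        spec = ModelSpec.parse(
            "GY ~ fixed(env + rep%in%env) + random(block%in%rep%in%env + line + "
            "tester + line:tester)")
        assert spec.response == "GY"
        assert spec.fixed_terms == ("env", "rep:env")
        assert "block:rep:env" in spec.random_terms

    def test_term_in_both_parts_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("y", ("line",), ("line",))
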