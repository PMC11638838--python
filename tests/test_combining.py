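import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import null_space

from linetester import combining
from linetester.combining import (
    bakers_ratio,
    estimate_gca_sca,
    gca_summary_stats,
    heritability_broad,
    proportional_contribution,
)
from linetester.crossing import CrossingPlan, InbredLine
from linetester.crossing import Tester as _Tester

from .conftest import additive_entry_means


class TestHeritability:
    @pytest.mark.parametrize("g,ge,e_,env,rep,expected", [
        (0.06, 0.28, 0.50, 3, 2, 0.25),    # drought grain yield
        (4.71, 0.97, 2.90, 3, 2, 0.85),    # drought anthesis date
        (4.98, 1.68, 5.40, 3, 2, 0.77),    # drought silking date
        (140.23, 56.48, 260.30, 3, 2, 0.69),  # drought plant height
        (86.29, 28.48, 103.40, 3, 2, 0.76),   # drought ear height
    ])
    def test_published_drought_values(self, g, ge, e_, env, rep, expected):
        h2 = heritability_broad(sigma2_g=g, sigma2_ge=ge, sigma2_e=e_,
                                n_env=env, n_rep=rep)
        assert round(h2, 2) == expected

    def test_limits(self):
        assert heritability_broad(sigma2_g=1.0, sigma2_ge=0.0, sigma2_e=0.0,
                                  n_env=3, n_rep=2) == 1.0
        assert heritability_broad(sigma2_g=0.0, sigma2_ge=0.5, sigma2_e=0.5,
                                  n_env=3, n_rep=2) == 0.0

    def test_all_zero_undefined(self):
        with pytest.warns(UserWarning):
            assert np.isnan(heritability_broad(sigma2_g=0, sigma2_ge=0, sigma2_e=0,
                                               n_env=2, n_rep=2))

    @given(g=st.floats(0.01, 10), ge=st.floats(0, 10), e_=st.floats(0.01, 10),
           env=st.integers(1, 10), rep=st.integers(1, 5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_environments_and_reps(self, g, ge, e_, env, rep):
        h = heritability_broad(sigma2_g=g, sigma2_ge=ge, sigma2_e=e_,
                               n_env=env, n_rep=rep)
        assert h <= heritability_broad(sigma2_g=g, sigma2_ge=ge, sigma2_e=e_,
                                       n_env=env + 1, n_rep=rep) + 1e-12
        assert h <= heritability_broad(sigma2_g=g, sigma2_ge=ge, sigma2_e=e_,
                                       n_env=env, n_rep=rep + 1) + 1e-12
        assert h <= heritability_broad(sigma2_g=g * 1.5, sigma2_ge=ge, sigma2_e=e_,
                                       n_env=env, n_rep=rep) + 1e-12


class TestBakersRatio:
    @pytest.mark.parametrize("l,t,s,expected,nd", [
        (0.36, 0.00, 0.00, 1.0, 1),   # drought grain yield
        (6.18, 0.06, 0.09, 0.99, 2),  # drought silking date
        (0.47, 0.02, 0.00, 1.00, 2),  # drought anthesis-silking interval
        (0.5, 0.5, 2.0, 0.50, 2),
    ])
    def test_known_values(self, l, t, s, expected, nd):
        assert round(bakers_ratio(l, t, s), nd) == expected

    def test_no_sca_limit(self):
        assert bakers_ratio(0.7, 0.1, 0.0) == 1.0

    @given(l=st.floats(0.001, 10), t=st.floats(0, 10), s=st.floats(0, 10),
           k=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, l, t, s, k):
        assert bakers_ratio(l * k, t * k, s * k) == pytest.approx(
            bakers_ratio(l, t, s), rel=1e-9)

    def test_all_zero_undefined(self):
        with pytest.warns(UserWarning):
            assert np.isnan(bakers_ratio(0, 0, 0))


class TestProportionalContribution:
    @pytest.mark.parametrize("l,t,s,expected", [
        (0.36, 0.0, 0.0, (100.0, 0.0, 0.0)),
        (1.0, 1.0, 2.0, (25.0, 25.0, 50.0)),
        (0.228, 0.015, 0.01, (90.1, 5.9, 4.0)),  # optimum grain yield components
    ])
    def test_known_values(self, l, t, s, expected):
        got = proportional_contribution(l, t, s)
        assert tuple(round(v, 1) for v in got) == expected
        assert sum(got) == pytest.approx(100.0)


def _oracle_decomposition(entry_means, pairs):
    """Independent least-squares oracle: null-space parametrisation of the
    constrained system (instead of KKT normal equations)."""
    sysm = combining.DecompositionSystem(pairs)
    N = null_space(sysm.C)
    coef, *_ = np.linalg.lstsq(sysm.A @ N, entry_means.to_numpy(float), rcond=None)
    theta = N @ coef
    return sysm, theta


class TestGcaScaDecomposition:
    def _plan(self, n_lines=5, n_testers=2):
        lines = [InbredLine(f"L{i}", "A") for i in range(n_lines)]
        testers = [_Tester(f"T{j}", "B") for j in range(n_testers)]
        crosses = {(l.line_id, t.tester_id) for l in lines for t in testers}
        return CrossingPlan(lines, testers, crosses)

    def test_complete_additive_design(self):
        plan = self._plan(3, 2)
        gl = {"L0": -0.5, "L1": 0.2, "L2": 0.3}
        gt = {"T0": -0.1, "T1": 0.1}
        means = pd.Series({f"{l}:{t}": 4.0 + gl[l] + gt[t] for l, t in sorted(plan.crosses)})
        tab = estimate_gca_sca(means, plan, 0.1, 20)
        assert np.abs(tab.sca["effect"]).max() < 1e-10
        assert tab.grand_mean == pytest.approx(4.0)
        for l, v in gl.items():
            # marginal mean deviation equals the injected effect here
            assert tab.gca_line.loc[l, "effect"] == pytest.approx(v, abs=1e-10)

    def test_matches_nullspace_oracle_on_incomplete_plan(self, reference_plan):
        rng = np.random.default_rng(8)
        pairs = sorted(reference_plan.crosses)
        means = pd.Series(rng.normal(5, 1, len(pairs)),
                          index=[f"{l}:{t}" for l, t in pairs])
        tab = estimate_gca_sca(means, reference_plan, 0.1, 100)
        sysm, theta = _oracle_decomposition(means, pairs)
        mu, g_line, g_tester = sysm.split(theta)
        assert np.allclose(tab.gca_line["effect"].to_numpy(), g_line, atol=1e-8)
        assert np.allclose(tab.gca_tester["effect"].to_numpy(), g_tester, atol=1e-8)
        oracle_sca = means.to_numpy() - sysm.A @ theta
        assert np.allclose(tab.sca["effect"].to_numpy(), oracle_sca, atol=1e-8)

    def test_translation_invariance(self, reference_plan, additive_means):
        noisy = additive_means + np.random.default_rng(1).normal(0, 0.2, len(additive_means))
        t1 = estimate_gca_sca(noisy, reference_plan, 0.1, 50)
        t2 = estimate_gca_sca(noisy + 11.5, reference_plan, 0.1, 50)
        assert t2.grand_mean - t1.grand_mean == pytest.approx(11.5, abs=1e-9)
        assert np.allclose(t1.gca_line["effect"], t2.gca_line["effect"], atol=1e-9)
        assert np.allclose(t1.sca["effect"], t2.sca["effect"], atol=1e-9)

    def test_sum_to_zero_constraints(self, reference_plan, additive_means):
        noisy = additive_means + np.random.default_rng(2).normal(0, 0.3, len(additive_means))
        tab = estimate_gca_sca(noisy, reference_plan, 0.1, 50)
        assert tab.gca_line["effect"].sum() == pytest.approx(0.0, abs=1e-8)
        assert tab.gca_tester["effect"].sum() == pytest.approx(0.0, abs=1e-8)
        # SCA sums to zero over each line's and each tester's realized crosses
        per_line = tab.sca["effect"].groupby(level="line").sum()
        per_tester = tab.sca["effect"].groupby(level="tester").sum()
        assert np.abs(per_line).max() < 1e-8
        assert np.abs(per_tester).max() < 1e-8

    def test_sca_shrinks_with_replication(self):
        """Under a purely additive truth, mean |SCA| estimate decreases as
        entry means get more precise (more replication)."""
        plan = self._plan(20, 4)
        pairs = sorted(plan.crosses)
        gl = np.random.default_rng(3).normal(0, 1.0, 20)
        gt = np.random.default_rng(4).normal(0, 0.3, 4)
        rng = np.random.default_rng(5)
        mean_abs = []
        for n_rep in (1, 4, 16, 64):
            truth = np.array([gl[int(l[1:])] + gt[int(t[1:])] for l, t in pairs])
            noise = rng.normal(0, 1.0, (50, len(pairs))).mean(axis=0) \
                if False else rng.normal(0, 1.0 / np.sqrt(n_rep), len(pairs))
            means = pd.Series(5 + truth + noise, index=[f"{l}:{t}" for l, t in pairs])
            tab = estimate_gca_sca(means, plan, 1.0 / n_rep, 50)
            mean_abs.append(np.abs(tab.sca["effect"]).mean())
        assert all(a > b for a, b in zip(mean_abs, mean_abs[1:]))

    def test_disconnected_plan_rejected(self):
        lines = [InbredLine("L0", "A"), InbredLine("L1", "A")]
        testers = [_Tester("T0", "B"), _Tester("T1", "B")]
        plan = object.__new__(CrossingPlan)
        plan.lines, plan.testers = lines, testers
        plan.crosses = {("L0", "T0"), ("L1", "T1")}
        means = pd.Series([1.0, 2.0], index=["L0:T0", "L1:T1"])
        from linetester.crossing import DesignError
        with pytest.raises(DesignError):
            estimate_gca_sca(means, plan, 0.1, 10)


class TestSummaryStats:
    def _table_from_effects(self, line_eff, tester_eff, sca_eff):
        def frame(vals, name):
            idx = pd.Index([f"{name}{i}" for i in range(len(vals))])
            return pd.DataFrame({"effect": vals, "se": 1.0, "t": vals, "p": 0.5,
                                 "stars": ""}, index=idx)
        sca_idx = pd.MultiIndex.from_tuples(
            [(f"L{i}", "T0") for i in range(len(sca_eff))])
        sca = pd.DataFrame({"effect": sca_eff, "se": 1.0, "t": sca_eff, "p": 0.5,
                            "stars": ""}, index=sca_idx)
        return combining.CombiningAbilityTable(
            frame(line_eff, "L"), frame(tester_eff, "T"), sca, 0.0, 10)

    def test_all_positive(self):
        s = gca_summary_stats(self._table_from_effects([1.0, 2.0], [0.5], [0.1]))
        assert s["line"]["pct_positive"] == 100.0
        assert s["line"]["pct_negative"] == 0.0

    def test_balanced_signs(self):
        s = gca_summary_stats(self._table_from_effects([1.0, -1.0], [0.5], [0.1]))
        assert s["line"]["pct_positive"] == 50.0
        assert s["line"]["pct_negative"] == 50.0
        assert s["line"]["max_positive"] == 1.0
        assert s["line"]["min_negative"] == -1.0

    def test_percentages_sum_to_100_at_scale(self, reference_plan, additive_means):
        noisy = additive_means + np.random.default_rng(0).normal(0, 0.2, len(additive_means))
        tab = estimate_gca_sca(noisy, reference_plan, 0.1, 100)
        s = gca_summary_stats(tab)
        for cat in ("line", "tester", "sca"):
            assert s[cat]["pct_positive"] + s[cat]["pct_negative"] == pytest.approx(100.0)

    def test_empty_table_rejected(self):
        empty = pd.DataFrame(columns=["effect", "se", "t", "p", "stars"])
        tab = combining.CombiningAbilityTable(empty, empty, empty, 0.0, 10)
        with pytest.raises(ValueError):
            gca_summary_stats(tab)
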