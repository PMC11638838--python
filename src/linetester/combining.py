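"""Heritability, GCA/SCA effects, Baker's ratio, and contribution summaries.

Combining-ability statistics follow the classical line-by-tester treatment:
entry means (BLUEs) of the realized crosses are decomposed by least squares as

    mean(i, j) = mu + g_i + g_j + s_ij

under sum-to-zero constraints on line and tester GCA effects, with the SCA
effect ``s_ij`` as the cross-specific deviation.  Effects are tested by
t statistics (effect / SE) at the residual degrees of freedom supplied from
the stage-1 mixed-model fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .crossing import CrossingPlan, DesignError

__all__ = [
    "HeritabilityInput",
    "CombiningAbilityTable",
    "heritability_broad",
    "bakers_ratio",
    "proportional_contribution",
    "estimate_gca_sca",
    "gca_summary_stats",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    """Star convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class HeritabilityInput:
    """Variance components and design dimensions feeding H²."""

    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    n_env: int
    n_rep: int

    def __post_init__(self):
        if min(self.sigma2_g, self.sigma2_ge, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")
        if self.n_env < 1 or self.n_rep < 1:
            raise ValueError("environment and replicate counts must be >= 1")


def heritability_broad(inp: HeritabilityInput | None = None, *,
                       sigma2_g: float | None = None,
                       sigma2_ge: float | None = None,
                       sigma2_e: float | None = None,
                       n_env: int | None = None,
                       n_rep: int | None = None) -> float:
    """Broad-sense heritability on an entry-mean basis.

    H² = s²g / (s²g + s²ge/e + s²e/(r·e)) for e environments and r
    replicates.  Full precision is returned; round to 2 decimals only for
    reporting.  All-zero variances are undefined and return NaN with a
    warning.
    """
    if inp is None:
        inp = HeritabilityInput(sigma2_g, sigma2_ge, sigma2_e, n_env, n_rep)
    denom = inp.sigma2_g + inp.sigma2_ge / inp.n_env + inp.sigma2_e / (inp.n_rep * inp.n_env)
    if denom <= 0:
        warnings.warn("all variance components zero: heritability undefined")
        return float("nan")
    return inp.sigma2_g / denom


def bakers_ratio(sigma2_gca_line: float, sigma2_gca_tester: float,
                 sigma2_sca: float) -> float:
    """Baker's ratio 2σ²GCA / (2σ²GCA + σ²SCA).

    σ²GCA is the sum of the line and tester GCA variances.  A value near 1
    means hybrid performance is predictable from GCA (additive) effects
    alone.  All-zero input is undefined and returns NaN with a warning.
    """
    if min(sigma2_gca_line, sigma2_gca_tester, sigma2_sca) < 0:
        raise ValueError("variance components must be non-negative")
    gca2 = 2.0 * (sigma2_gca_line + sigma2_gca_tester)
    denom = gca2 + sigma2_sca
    if denom <= 0:
        warnings.warn("all variance components zero: Baker's ratio undefined")
        return float("nan")
    return gca2 / denom


def proportional_contribution(sigma2_gca_line: float, sigma2_gca_tester: float,
                              sigma2_sca: float) -> tuple[float, float, float]:
    """Percent of the total genetic variance due to lines, testers, and SCA."""
    if min(sigma2_gca_line, sigma2_gca_tester, sigma2_sca) < 0:
        raise ValueError("variance components must be non-negative")
    total = sigma2_gca_line + sigma2_gca_tester + sigma2_sca
    if total <= 0:
        warnings.warn("all variance components zero: contributions undefined")
        return (float("nan"),) * 3
    return (100.0 * sigma2_gca_line / total,
            100.0 * sigma2_gca_tester / total,
            100.0 * sigma2_sca / total)


class DecompositionSystem:
    """Least-squares system for the mean = mu + g_line + g_tester model.

    A line-by-tester trial with two heterotic directions consists of two
    internally connected sub-designs (group-A lines × group-B testers and
    vice versa) that share no parents, so the decomposition carries one
    intercept per connected component of the line–tester graph and
    sum-to-zero constraints on the line and tester effects within each
    component.  For a single connected design this is exactly the textbook
    one-mean, two-constraint system.

    Attributes
    ----------
    A : (n_cross, n_comp + n_lines + n_testers) design matrix
    C : constraint rows (line-sum and tester-sum per component)
    lines, testers : sorted parent ids
    comp_of_line, comp_of_tester : component index per parent
    """

    def __init__(self, pairs: list[tuple[str, str]]):
        self.pairs = list(pairs)
        self.lines = sorted({l for l, _ in pairs})
        self.testers = sorted({t for _, t in pairs})
        nl, nt = len(self.lines), len(self.testers)
        self.li = {l: i for i, l in enumerate(self.lines)}
        self.ti = {t: i for i, t in enumerate(self.testers)}

        g = nx.Graph()
        g.add_edges_from((("L", l), ("T", t)) for l, t in pairs)
        comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
        self.n_comp = len(comps)
        self.comp_of_line = {}
        self.comp_of_tester = {}
        for ci, comp in enumerate(comps):
            for kind, name in comp:
                if kind == "L":
                    self.comp_of_line[name] = ci
                else:
                    self.comp_of_tester[name] = ci

        n = len(pairs)
        self.p = self.n_comp + nl + nt
        A = np.zeros((n, self.p))
        for r, (l, t) in enumerate(pairs):
            A[r, self.comp_of_line[l]] = 1.0
            A[r, self.n_comp + self.li[l]] = 1.0
            A[r, self.n_comp + nl + self.ti[t]] = 1.0
        self.A = A

        rows = []
        for ci in range(self.n_comp):
            lrow = np.zeros(self.p)
            trow = np.zeros(self.p)
            for l, i in self.li.items():
                if self.comp_of_line[l] == ci:
                    lrow[self.n_comp + i] = 1.0
            for t, i in self.ti.items():
                if self.comp_of_tester[t] == ci:
                    trow[self.n_comp + nl + i] = 1.0
            rows.extend([lrow, trow])
        self.C = np.asarray(rows)

    def split(self, theta: np.ndarray):
        """Partition a solution vector into (mu per component, g_line, g_tester)."""
        nl = len(self.lines)
        mu = theta[:self.n_comp]
        g_line = theta[self.n_comp:self.n_comp + nl]
        g_tester = theta[self.n_comp + nl:self.p]
        return mu, g_line, g_tester

    def predict_row(self, theta: np.ndarray, line: str, tester: str) -> float:
        """GCA-only prediction mu_c + g_line + g_tester for one cross."""
        mu, g_line, g_tester = self.split(theta)
        return float(mu[self.comp_of_line[line]] + g_line[self.li[line]]
                     + g_tester[self.ti[tester]])


@dataclass
class CombiningAbilityTable:
    """GCA effects per parent and SCA per realized cross, with tests.

    ``gca_line`` / ``gca_tester`` are DataFrames indexed by parent id with
    columns ``effect, se, t, p, stars``; ``sca`` is indexed by
    (line, tester).  Effects satisfy sum-to-zero constraints; per line (and
    per tester), SCA effects over its realized crosses sum to ~0.
    """

    gca_line: pd.DataFrame
    gca_tester: pd.DataFrame
    sca: pd.DataFrame
    grand_mean: float
    residual_df: int
    # per-parent intercept (the mean of the parent's sub-design); equals the
    # grand mean everywhere when the design is a single connected component
    mu_line: pd.Series | None = None
    mu_tester: pd.Series | None = None


def _effect_frame(effects, se, df, index) -> pd.DataFrame:
    effects = np.asarray(effects, float)
    se = np.asarray(se, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effects / se, np.nan)
    p = 2.0 * t_dist.sf(np.abs(t), df)
    frame = pd.DataFrame({"effect": effects, "se": se, "t": t, "p": p}, index=index)
    frame["stars"] = [significance_stars(v) for v in frame["p"]]
    return frame


def estimate_gca_sca(entry_means: pd.Series, plan: CrossingPlan,
                     error_variance: float, residual_df: int) -> CombiningAbilityTable:
    """Decompose cross means into GCA and SCA effects.

    Parameters
    ----------
    entry_means : Series
        BLUEs of the realized crosses, indexed by ``(line, tester)`` tuples
        or by ``"line:tester"`` labels matching the plan.
    plan : CrossingPlan
        Realized crosses; must be connected.
    error_variance : float
        Sampling variance of one entry mean (from the stage-1 fit).
    residual_df : int
        Degrees of freedom for the t tests.

    The least-squares system ``mean = mu + g_line + g_tester`` is solved over
    realized crosses with explicit sum-to-zero constraint rows on line and
    tester effects; SCA effects are the fit residuals, hence they sum to zero
    over the realized crosses of every line and of every tester.
    """
    if not plan.is_connected():
        raise DesignError("disconnected plan: GCA effects not jointly estimable")

    idx = entry_means.index
    if idx.nlevels == 1:
        pairs = [tuple(str(k).split(":", 1)) for k in idx]
    else:
        pairs = [(str(a), str(b)) for a, b in idx]
    known = set(plan.crosses)
    missing = [p for p in pairs if p not in known]
    if missing:
        raise DesignError(f"entry means for crosses not in the plan: {missing[:5]}")

    # flag lines whose SCA is confounded (a single realized cross)
    line_counts: dict[str, int] = {}
    tester_counts: dict[str, int] = {}
    for l, t in pairs:
        line_counts[l] = line_counts.get(l, 0) + 1
        tester_counts[t] = tester_counts.get(t, 0) + 1

    sysm = DecompositionSystem(pairs)
    A, Cmat, lines, testers = sysm.A, sysm.C, sysm.lines, sysm.testers
    nl, nt = len(lines), len(testers)
    n = len(pairs)
    p = sysm.p
    m = entry_means.to_numpy(float)

    nc = Cmat.shape[0]
    K = np.zeros((p + nc, p + nc))
    K[:p, :p] = A.T @ A
    K[:p, p:] = Cmat.T
    K[p:, :p] = Cmat
    rhs = np.concatenate([A.T @ m, np.zeros(nc)])
    try:
        Kinv = np.linalg.inv(K)
    except np.linalg.LinAlgError as err:
        raise DesignError("singular combining-ability system (disconnected plan?)") from err
    theta = (Kinv @ rhs)[:p]
    mu_c, g_line, g_tester = sysm.split(theta)
    fitted = A @ theta
    sca_vals = m - fitted
    mu = float(np.mean(mu_c[[sysm.comp_of_line[l] for l, _ in pairs]]))

    # covariance of effects: theta_hat = B m with B the top-left rows of K^{-1} A'
    B = Kinv[:p, :p] @ A.T
    cov_theta = error_variance * (B @ B.T)
    se_theta = np.sqrt(np.maximum(np.diag(cov_theta), 0.0))
    # SCA covariance: s = (I - A B) m
    M = np.eye(n) - A @ B
    se_sca = np.sqrt(np.maximum(np.einsum("ij,ij->i", M, M) * error_variance, 0.0))

    o = sysm.n_comp
    gca_line = _effect_frame(g_line, se_theta[o:o + nl], residual_df,
                             pd.Index(lines, name="line"))
    gca_tester = _effect_frame(g_tester, se_theta[o + nl:p], residual_df,
                               pd.Index(testers, name="tester"))
    sca = _effect_frame(sca_vals, se_sca, residual_df,
                        pd.MultiIndex.from_tuples(pairs, names=["line", "tester"]))
    sca["estimable"] = [line_counts[l] > 1 and tester_counts[t] > 1 for l, t in pairs]
    mu_line = pd.Series({l: float(mu_c[sysm.comp_of_line[l]]) for l in lines})
    mu_tester = pd.Series({t: float(mu_c[sysm.comp_of_tester[t]]) for t in testers})
    return CombiningAbilityTable(gca_line, gca_tester, sca, mu, residual_df,
                                 mu_line, mu_tester)


def _effect_summary(values: np.ndarray) -> dict:
    values = np.asarray(values, float)
    values = values[~np.isnan(values)]
    n = len(values)
    pos = values[values > 0]
    neg = values[values < 0]
    return {
        "n": n,
        "pct_positive": 100.0 * len(pos) / n if n else float("nan"),
        "pct_negative": 100.0 * len(neg) / n if n else float("nan"),
        "min_positive": float(pos.min()) if len(pos) else float("nan"),
        "max_positive": float(pos.max()) if len(pos) else float("nan"),
        "min_negative": float(neg.min()) if len(neg) else float("nan"),
        "max_negative": float(neg.max()) if len(neg) else float("nan"),
    }


def gca_summary_stats(table: CombiningAbilityTable) -> dict:
    """Summary of effect signs and extremes for lines, testers, and SCA.

    Mirrors the usual combining-ability report: percent positive/negative
    effects, and the smallest/largest positive and negative values, per
    category.
    """
    if len(table.gca_line) == 0:
        raise ValueError("empty combining-ability table")
    return {
        "line": _effect_summary(table.gca_line["effect"].to_numpy()),
        "tester": _effect_summary(table.gca_tester["effect"].to_numpy()),
        "sca": _effect_summary(table.sca["effect"].to_numpy()),
    }
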