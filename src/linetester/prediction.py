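"""GCA-based hybrid prediction and leave-one-hybrid-out cross-validation.

A hybrid's performance is predicted from its parents' general combining
abilities alone: ``pred(i, j) = mu + g_i + g_j`` (no SCA term).  The
leave-one-hybrid-out correlation r(GCA, TCP) between such predictions and
the observed testcross performance measures how far additive effects carry:
with Baker's ratio near 1 it approaches the trait's repeatability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .combining import CombiningAbilityTable, DecompositionSystem, estimate_gca_sca
from .crossing import CrossingPlan

__all__ = ["PredictionResult", "predict_hybrid", "loo_gca_cv"]


@dataclass
class PredictionResult:
    """Observed vs GCA-predicted values per hybrid, with the pooled Pearson r."""

    per_hybrid: pd.DataFrame  # index (line, tester); columns observed, predicted
    r: float
    p_value: float
    n: int
    trait: str | None = None
    regime: str | None = None
    skipped: list[tuple[str, str]] | None = None


def predict_hybrid(table: CombiningAbilityTable, line_id: str, tester_id: str) -> float:
    """Predicted performance mu + g_line + g_tester for one cross."""
    if line_id not in table.gca_line.index:
        raise KeyError(f"unknown line {line_id!r}")
    if tester_id not in table.gca_tester.index:
        raise KeyError(f"unknown tester {tester_id!r}")
    mu = table.grand_mean if table.mu_line is None else float(table.mu_line[line_id])
    return float(mu
                 + table.gca_line.loc[line_id, "effect"]
                 + table.gca_tester.loc[tester_id, "effect"])


def _normalize_pairs(entry_means: pd.Series) -> list[tuple[str, str]]:
    idx = entry_means.index
    if idx.nlevels == 1:
        return [tuple(str(k).split(":", 1)) for k in idx]
    return [(str(a), str(b)) for a, b in idx]


def loo_gca_cv(entry_means: pd.Series, plan: CrossingPlan,
               trait: str | None = None, regime: str | None = None,
               error_variance: float = 1.0, residual_df: int = 10) -> PredictionResult:
    """Leave-one-hybrid-out r(GCA, TCP).

    For every hybrid the GCA decomposition is re-estimated from all other
    hybrids and the left-out hybrid is predicted as mu + g_line + g_tester;
    the pooled Pearson correlation of (observed, predicted) pairs is
    returned.  Hybrids whose removal disconnects the design (bridge edges of
    the line–tester graph) are skipped with a warning, never imputed.

    The per-fold re-estimation uses a rank-one downdate of the constrained
    normal equations, which is algebraically identical to refitting from
    scratch for each fold.
    """
    pairs = _normalize_pairs(entry_means)
    n = len(pairs)
    if n < 10:
        raise ValueError("need at least 10 hybrids for leave-one-hybrid-out CV")

    # bridge edges: their removal disconnects the plan, leaving a parent
    # without any estimable GCA contrast
    g = nx.Graph()
    g.add_edges_from((("L", l), ("T", t)) for l, t in pairs)
    bridges = {(e[0][1], e[1][1]) if e[0][0] == "L" else (e[1][1], e[0][1])
               for e in nx.bridges(g)}

    sysm = DecompositionSystem(pairs)
    A, Cmat = sysm.A, sysm.C
    p = sysm.p
    m = entry_means.to_numpy(float)

    nc = Cmat.shape[0]
    K = np.zeros((p + nc, p + nc))
    K[:p, :p] = A.T @ A
    K[:p, p:] = Cmat.T
    K[p:, :p] = Cmat
    Kinv = np.linalg.inv(K)
    rhs_full = np.concatenate([A.T @ m, np.zeros(nc)])

    obs, preds, kept, skipped = [], [], [], []
    for h, (l, t) in enumerate(pairs):
        if (l, t) in bridges:
            skipped.append((l, t))
            continue
        a = np.concatenate([A[h], np.zeros(nc)])
        # Sherman–Morrison downdate: K_h = K - a a', rhs_h = rhs - a*m_h
        Ka = Kinv @ a
        denom = 1.0 - float(a @ Ka)
        Kinv_h_rhs = Kinv @ (rhs_full - a * m[h]) \
            + Ka * (float(a @ (Kinv @ (rhs_full - a * m[h]))) / denom)
        theta = Kinv_h_rhs[:p]
        pred = sysm.predict_row(theta, l, t)
        obs.append(m[h])
        preds.append(pred)
        kept.append((l, t))

    if skipped:
        warnings.warn(f"skipped {len(skipped)} hybrids whose removal disconnects the plan")
    if len(kept) < 3:
        raise ValueError("fewer than 3 predictable hybrids: cannot correlate")

    obs = np.asarray(obs)
    preds = np.asarray(preds)
    r, pval = pearsonr(obs, preds)
    per_hybrid = pd.DataFrame(
        {"observed": obs, "predicted": preds},
        index=pd.MultiIndex.from_tuples(kept, names=["line", "tester"]))
    return PredictionResult(per_hybrid, float(r), float(pval), len(kept),
                            trait, regime, skipped or None)


def loo_gca_cv_bruteforce(entry_means: pd.Series, plan: CrossingPlan) -> pd.DataFrame:
    """Naive per-fold refit (independent oracle for :func:`loo_gca_cv`).

    Re-runs the full constrained decomposition once per left-out hybrid.
    Used in validation; O(n) full solves, so only sensible at small scale.
    """
    pairs = _normalize_pairs(entry_means)
    g = nx.Graph()
    g.add_edges_from((("L", l), ("T", t)) for l, t in pairs)
    bridges = {(e[0][1], e[1][1]) if e[0][0] == "L" else (e[1][1], e[0][1])
               for e in nx.bridges(g)}
    rows = []
    for h, (l, t) in enumerate(pairs):
        if (l, t) in bridges:
            continue
        rest = entry_means.drop(entry_means.index[h])
        table = estimate_gca_sca(rest, plan, 1.0, 10)
        rows.append(((l, t), entry_means.iloc[h], predict_hybrid(table, l, t)))
    return pd.DataFrame(
        {"observed": [r[1] for r in rows], "predicted": [r[2] for r in rows]},
        index=pd.MultiIndex.from_tuples([r[0] for r in rows], names=["line", "tester"]))
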