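"""End-to-end analysis report in the standard combining-ability layout.

:func:`run_full_analysis` chains the whole pipeline for each management
regime and trait: trait derivation -> combined genotype model (checks
included, as planted) -> heritability and CV -> line-by-tester models
(checks excluded) -> GCA/SCA effects and tests -> Baker's ratio and
proportional contributions -> trait correlations -> leave-one-hybrid-out
prediction.  Every reported number is traceable to a module output;
rounding happens only at serialisation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import combining, prediction, relations, reml, trial_data
from .crossing import CrossingPlan

__all__ = ["AnalysisReport", "run_full_analysis", "top_entries"]

log = logging.getLogger("linetester")


@dataclass
class AnalysisReport:
    """All per-trait per-regime results of a full analysis run."""

    genotype_components: dict = field(default_factory=dict)  # (regime, trait) -> dict
    lxt_components: dict = field(default_factory=dict)       # (regime, trait) -> dict
    entry_stats: dict = field(default_factory=dict)          # (regime, trait) -> dict
    entry_means: dict = field(default_factory=dict)          # regime -> DataFrame
    combining_tables: dict = field(default_factory=dict)     # (regime, trait) -> table
    gca_summary: dict = field(default_factory=dict)
    correlations: dict = field(default_factory=dict)         # regime or "across" -> matrix
    prediction_r: dict = field(default_factory=dict)         # (regime, trait) -> dict

    def summary_dict(self) -> dict:
        def key(k):
            return f"{k[0]}:{k[1]}" if isinstance(k, tuple) else k
        return {
            "genotype_components": {key(k): v for k, v in self.genotype_components.items()},
            "lxt_components": {key(k): v for k, v in self.lxt_components.items()},
            "entry_stats": {key(k): v for k, v in self.entry_stats.items()},
            "prediction_r": {key(k): v for k, v in self.prediction_r.items()},
        }

    def to_dir(self, out_dir) -> None:
        """Serialise the report: one CSV per table plus a JSON summary."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(
            json.dumps(self.summary_dict(), indent=2, default=float))
        for regime, df in self.entry_means.items():
            df.round(3).to_csv(out / f"entry_means_{regime}.csv")
        for (regime, trait), table in self.combining_tables.items():
            table.gca_line.round(3).to_csv(out / f"gca_line_{regime}_{trait}.csv")
            table.gca_tester.round(3).to_csv(out / f"gca_tester_{regime}_{trait}.csv")
            table.sca.round(3).to_csv(out / f"sca_{regime}_{trait}.csv")
        for key, mat in self.correlations.items():
            mat.r.round(3).to_csv(out / f"correlations_{key}.csv")


def _regime_envs(df: pd.DataFrame, regime: str) -> pd.DataFrame:
    if "regime" in df:
        return df.loc[df["regime"] == regime]
    return df


def run_full_analysis(plots, plan: CrossingPlan,
                      traits: list[str] | None = None,
                      layout: trial_data.TrialLayout = trial_data.TrialLayout(),
                      component_tests: bool = False,
                      loo_cv: bool = True) -> AnalysisReport:
    """Run the complete pipeline and collect a report.

    Parameters
    ----------
    plots : DataFrame or CSV path
        Plot-level records in the standard schema.
    plan : CrossingPlan
        The realized crossing plan (for GCA/SCA estimability checks).
    traits : list of str, optional
        Traits to analyse; defaults to all recognised trait columns present.
    component_tests : bool
        Also run per-term likelihood-ratio tests on the line-by-tester
        variance components (one extra REML fit per term; slow on large data).
    loo_cv : bool
        Run leave-one-hybrid-out GCA prediction per regime and trait.
    """
    if not isinstance(plots, pd.DataFrame):
        plots = trial_data.load_plot_table(plots, layout)
    else:
        plots = trial_data.derive_traits(plots, layout)
    regimes = sorted(plots["regime"].dropna().unique()) if "regime" in plots else ["all"]
    if traits is None:
        traits = [t for t in ("GY", "AD", "SD", "ASI", "PH", "EH") if t in plots.columns]

    rep = AnalysisReport()
    for regime in regimes:
        sub = _regime_envs(plots, regime)
        n_env = int(sub["env"].nunique())
        n_rep = int(sub["rep"].nunique())
        log.info("regime %s: %d envs, %d reps, %d plots", regime, n_env, n_rep, len(sub))

        means_by_trait = {}
        for trait in traits:
            # stage 1a: combined genotype model, checks included
            fit = reml.fit_genotype_model(sub, trait)
            comps = fit.components
            entry_term = "entry"
            ge_term = "entry:env" if f"entry:env" in comps.components else None
            s2g = comps["entry"]
            s2ge = comps[ge_term] if ge_term else 0.0
            s2e = comps.residual
            h2 = combining.heritability_broad(
                sigma2_g=s2g, sigma2_ge=s2ge, sigma2_e=s2e, n_env=n_env, n_rep=n_rep)
            # stage 1b: entry BLUEs for reporting and stage 2
            blues, err_var, dfree, sed = reml.entry_blues(sub, trait)
            means_by_trait[trait] = blues
            grand = float(blues.mean())
            rep.genotype_components[(regime, trait)] = {
                "genotype": s2g, "gxe": s2ge, "residual": s2e,
                "heritability": h2,
                "cv_pct": 100.0 * float(np.sqrt(s2e)) / grand if grand else float("nan"),
                "loglik": comps.loglik, "converged": comps.converged,
            }
            rep.entry_stats[(regime, trait)] = {
                "grand_mean": grand, "min": float(blues.min()),
                "max": float(blues.max()), "sed": sed, "n_entries": int(len(blues)),
            }

            # stage 2: line-by-tester, checks excluded
            tc = sub.loc[sub["entry_kind"] == "testcross"] if "entry_kind" in sub else sub
            lxt = reml.fit_lxt_across_env(tc, trait) if n_env > 1 \
                else reml.fit_lxt_single_env(tc, trait)
            c = lxt.components
            def get(term):
                return c.components.get(term, 0.0)
            lxt_row = {
                "gca_line": get("line"), "gca_tester": get("tester"),
                "sca": get("line:tester"), "line_env": get("line:env"),
                "tester_env": get("tester:env"), "sca_env": get("line:tester:env"),
                "residual": c.residual, "loglik": c.loglik,
            }
            lxt_row["bakers_ratio"] = combining.bakers_ratio(
                lxt_row["gca_line"], lxt_row["gca_tester"], lxt_row["sca"])
            pc = combining.proportional_contribution(
                lxt_row["gca_line"], lxt_row["gca_tester"], lxt_row["sca"])
            lxt_row["contribution_pct"] = {"line": pc[0], "tester": pc[1], "sca": pc[2]}
            if component_tests:
                lxt_row["component_tests"] = _component_lrts(tc, trait, lxt)
            rep.lxt_components[(regime, trait)] = lxt_row

            # stage 3: GCA/SCA effects from testcross BLUEs
            tc_blues = blues[blues.index.isin({f"{l}:{t}" for l, t in plan.crosses})]
            table = combining.estimate_gca_sca(tc_blues, plan, err_var, dfree)
            rep.combining_tables[(regime, trait)] = table
            rep.gca_summary[(regime, trait)] = combining.gca_summary_stats(table)

            if loo_cv:
                res = prediction.loo_gca_cv(tc_blues, plan, trait=trait, regime=regime)
                rep.prediction_r[(regime, trait)] = {"r": res.r, "n": res.n}

        wide = pd.DataFrame(means_by_trait)
        if "entry_kind" in sub:
            kind = sub.drop_duplicates("entry").set_index("entry")["entry_kind"]
            wide["entry_kind"] = kind.reindex(wide.index)
        rep.entry_means[regime] = wide
        rep.correlations[regime] = relations.correlate_traits(
            wide[[t for t in traits]], traits)

    if len(rep.entry_means) > 1:
        rep.correlations["across"] = relations.correlate_traits(
            {r: df[[t for t in traits]] for r, df in rep.entry_means.items()},
            traits, mode="across_regimes")
    return rep


def _component_lrts(tc: pd.DataFrame, trait: str, full: reml.FitResult) -> dict:
    out = {}
    for term in full.spec.random_terms:
        reduced_spec = reml.ModelSpec(
            full.spec.response, full.spec.fixed_terms,
            tuple(t for t in full.spec.random_terms if t != term),
            full.spec.data_scope)
        reduced = reml.fit_reml(tc.loc[tc[trait].notna()], reduced_spec)
        out[term] = reml.lrt_variance_component(full, reduced)
    return out


def top_entries(entry_means: pd.DataFrame, k: int, trait: str,
                tie_break: str = "ASI") -> pd.DataFrame:
    """Best-k ranking for one trait, checks appended for comparison.

    Entries are sorted descending by the trait; ties are broken by the lower
    tie-break trait (ASI by default — a shorter anthesis–silking interval is
    favourable), then by entry label for a stable order.
    """
    if trait not in entry_means.columns:
        raise KeyError(f"unknown trait {trait!r}")
    df = entry_means.copy()
    is_check = df["entry_kind"].eq("check") if "entry_kind" in df else \
        pd.Series(False, index=df.index)
    cand = df.loc[~is_check].copy()
    if k > len(cand):
        raise ValueError(f"k={k} exceeds the {len(cand)} rankable entries")
    cand["_label"] = cand.index.astype(str)
    sort_cols = [trait, "_label"] if tie_break not in cand else [trait, tie_break, "_label"]
    asc = [False, True] if tie_break not in cand else [False, True, True]
    ranked = cand.sort_values(sort_cols, ascending=asc, kind="mergesort").drop(columns="_label")
    out = pd.concat([ranked.head(k), df.loc[is_check]])
    return out
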