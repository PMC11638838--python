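"""GCA and SCA effects with significance tests, and entry rankings.

Stage 1 produces adjusted entry means (BLUEs) from a fixed-entry mixed
model; stage 2 decomposes the testcross means as mu + g_line + g_tester
+ s_cross under sum-to-zero constraints and t-tests every effect.
"""

from linetester import SimulationConfig, estimate_gca_sca, gca_summary_stats, simulate_trial
from linetester.report import top_entries
from linetester.reml import entry_blues
from linetester.simulate import reference_plan

cfg = SimulationConfig(n_lines_a=20, n_lines_b=20, traits=("GY", "AD", "SD", "ASI"),
                       seed=9)
plots, _ = simulate_trial(cfg)
plan = reference_plan(cfg)

blues, err_var, dfree, sed = entry_blues(plots, "GY")
print(f"entry BLUEs: n={len(blues)}  SED={sed:.3f} t/ha  residual df={dfree}")

tc = blues[blues.index.isin({f"{l}:{t}" for l, t in plan.crosses})]
table = estimate_gca_sca(tc, plan, err_var, dfree)
print("\ntop line GCA effects for grain yield (t/ha deviation from the "
      "sub-design mean):")
print(table.gca_line.sort_values("effect", ascending=False)
      .head(5)[["effect", "se", "t", "stars"]].round(3).to_string())

s = gca_summary_stats(table)
print(f"\nlines with positive GCA: {s['line']['pct_positive']:.0f}%  "
      f"negative: {s['line']['pct_negative']:.0f}%")
print(f"SCA range: [{s['sca']['min_negative']:.3f}, {s['sca']['max_positive']:.3f}]")

wide = plots[plots[["GY", "ASI"]].notna().all(axis=1)] \
    .groupby("entry")[["GY", "ASI"]].mean()
wide["entry_kind"] = plots.drop_duplicates("entry").set_index("entry")["entry_kind"]
print("\nbest 5 entries by GY (ties broken by lower ASI; checks appended):")
print(top_entries(wide, 5, "GY").round(2).to_string())
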