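"""Generate a synthetic multi-environment line-by-tester trial.

The default configuration mirrors a 265-line maize testcross study under
managed drought: 93 group-A + 172 group-B lines, each crossed to the 3
opposite-group single-cross testers (795 testcrosses), 6 commercial checks,
3 environments x 2 replicates in alpha-lattice blocks, with published
drought variance components as the generative truth.
"""

from linetester import SimulationConfig, simulate_trial

cfg = SimulationConfig(regime="drought", seed=1)
plots, truth = simulate_trial(cfg)

testcrosses = plots[plots.entry_kind == "testcross"]
print(f"plot rows: {len(plots)}  (testcross rows: {len(testcrosses)})")
print(f"entries: {plots.entry.nunique()}  environments: {plots.env.nunique()}  "
      f"reps: {plots.rep.nunique()}  blocks/rep: {plots.block.nunique()}")
print(f"drought GY grand mean (truth): {truth['traits']['GY']['mean']} t/ha")
print(f"injected line-GCA variance (truth): "
      f"{truth['traits']['GY']['variances']['gca_line']}")
print()
print(plots.head(4).to_string())
# 4,806 rows = (795 testcrosses + 6 checks) x 3 envs x 2 reps; each row is one
# field plot carrying the additive effect structure the REML models assume.
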