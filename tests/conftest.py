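import numpy as np
import pandas as pd
import pytest

from linetester import simulate


@pytest.fixture(scope="session")
def reference_plan():
    """The study-sized crossing plan: 93+172 lines, 3+3 testers, 795 crosses."""
    return simulate.reference_plan(simulate.SimulationConfig())


@pytest.fixture(scope="session")
def small_cfg():
    return simulate.SimulationConfig(
        n_lines_a=12, n_lines_b=12, n_testers_per_group=2, testers_per_line=2,
        n_env=2, block_size=10, traits=("GY", "AD", "SD", "ASI"), seed=11)


@pytest.fixture(scope="session")
def small_trial(small_cfg):
    plots, truth = simulate.simulate_trial(small_cfg)
    return plots, truth, simulate.reference_plan(small_cfg)


def additive_entry_means(plan, seed=0, mu=5.0, sd_line=0.6, sd_tester=0.15):
    """Entry means that are exactly mu + g_line + g_tester (no SCA, no noise)."""
    rng = np.random.default_rng(seed)
    gl = dict(zip(plan.line_ids, rng.normal(0, sd_line, len(plan.line_ids))))
    gt = dict(zip(plan.tester_ids, rng.normal(0, sd_tester, len(plan.tester_ids))))
    crosses = sorted(plan.crosses)
    return pd.Series({f"{l}:{t}": mu + gl[l] + gt[t] for l, t in crosses})


@pytest.fixture(scope="session")
def additive_means(reference_plan):
    return additive_entry_means(reference_plan, seed=3)
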