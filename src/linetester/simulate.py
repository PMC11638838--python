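"""Synthetic multi-environment line-by-tester trial generator.

Generates plot-level records with exactly the additive structure the
analysis models assume: for each trait,

    y = mean + env + rep + block + g_line + g_tester + s_lt
        + (line x env) + (tester x env) + (line x tester x env) + residual

with every random effect drawn independently from a zero-mean normal at the
configured variance.  Variance presets ``"drought"`` and ``"optimum"`` carry
the published drought/optimum components for grain yield (GY), flowering
(AD, SD, ASI), and plant architecture (PH, EH) of a 265-line x 6-tester
maize testcross study, so simulations reproduce that study's design
(93 group-A + 172 group-B lines, 3 opposite-group testers per line,
795 testcrosses, 3 drought or 4 optimum environments, 2 replicates,
alpha-lattice incomplete blocks).

Silking date is derived as SD = AD + ASI at generation time, so the
anthesis-silking identity holds exactly in every simulated plot, and the
drought regime's positive mean ASI plus a configurable negative line-level
GY-ASI dependence emulate the stress syndrome of managed-drought trials.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crossing import CrossingPlan, InbredLine, Tester, build_crossing_plan
from .trial_data import TrialLayout

__all__ = ["SimulationConfig", "regime_presets", "simulate_trial", "reference_plan"]

# Published variance components per trait.  "lxt" holds the line-by-tester
# partition (line GCA, tester GCA, SCA, their environment interactions,
# residual); "genotype" holds the combined-analysis partition (genotype,
# genotype x environment, residual); "mean" is the trial grand mean.
_PRESETS = {
    "drought": {
        "GY":  {"lxt": {"gca_line": 0.36, "gca_tester": 0.00, "sca": 0.00,
                        "line_env": 0.02, "tester_env": 0.00, "sca_env": 0.00,
                        "residual": 1.01},
                "genotype": {"genotype": 0.06, "gxe": 0.28, "residual": 0.50},
                "mean": 2.15},
        "AD":  {"lxt": {"gca_line": 5.31, "gca_tester": 0.00, "sca": 0.00,
                        "line_env": 0.88, "tester_env": 0.17, "sca_env": 0.13,
                        "residual": 1.99},
                "genotype": {"genotype": 4.71, "gxe": 0.97, "residual": 2.90},
                "mean": 67.56},
        "SD":  {"lxt": {"gca_line": 6.18, "gca_tester": 0.06, "sca": 0.09,
                        "line_env": 1.32, "tester_env": 0.08, "sca_env": 0.00,
                        "residual": 3.51},
                "genotype": {"genotype": 4.98, "gxe": 1.68, "residual": 5.40},
                "mean": 70.36},
        "ASI": {"lxt": {"gca_line": 0.47, "gca_tester": 0.02, "sca": 0.00,
                        "line_env": 0.55, "tester_env": 0.06, "sca_env": 0.00,
                        "residual": 1.54},
                "genotype": {"genotype": 0.49, "gxe": 0.69, "residual": 2.20},
                "mean": 2.78},
        "PH":  {"lxt": {"gca_line": 187.18, "gca_tester": 3.22, "sca": 0.00,
                        "line_env": 60.10, "tester_env": 4.58, "sca_env": 0.00,
                        "residual": 187.48},
                "genotype": {"genotype": 140.23, "gxe": 56.48, "residual": 260.30},
                "mean": 214.71},
        "EH":  {"lxt": {"gca_line": 101.59, "gca_tester": 1.74, "sca": 0.00,
                        "line_env": 27.36, "tester_env": 1.72, "sca_env": 0.00,
                        "residual": 76.65},
                "genotype": {"genotype": 86.29, "gxe": 28.48, "residual": 103.40},
                "mean": 116.88},
    },
    "optimum": {
        "GY":  {"lxt": {"gca_line": 0.228, "gca_tester": 0.015, "sca": 0.01,
                        "line_env": 1.031, "tester_env": 0.046, "sca_env": 0.00,
                        "residual": 1.85},
                "genotype": {"genotype": 0.31, "gxe": 0.58, "residual": 2.6},
                "mean": 7.39},
        "AD":  {"lxt": {"gca_line": 4.417, "gca_tester": 0.050, "sca": 0.00,
                        "line_env": 3.467, "tester_env": 0.081, "sca_env": 0.00,
                        "residual": 4.90},
                "genotype": {"genotype": 4.35, "gxe": 1.06, "residual": 7.5},
                "mean": 68.34},
        "SD":  {"lxt": {"gca_line": 3.92, "gca_tester": 0.009, "sca": 0.00,
                        "line_env": 3.93, "tester_env": 0.23, "sca_env": 0.00,
                        "residual": 6.26},
                "genotype": {"genotype": 3.69, "gxe": 1.38, "residual": 9.5},
                "mean": 66.05},
        "ASI": {"lxt": {"gca_line": 0.203, "gca_tester": 0.000, "sca": 0.00,
                        "line_env": 0.252, "tester_env": 0.037, "sca_env": 0.00,
                        "residual": 1.38},
                "genotype": {"genotype": 0.21, "gxe": 0.19, "residual": 1.5},
                "mean": 0.70},
        "PH":  {"lxt": {"gca_line": 129.31, "gca_tester": 4.36, "sca": 1.07,
                        "line_env": 208.37, "tester_env": 4.32, "sca_env": 0.00,
                        "residual": 199.64},
                "genotype": {"genotype": 127.61, "gxe": 133.33, "residual": 316.6},
                "mean": 226.39},
        "EH":  {"lxt": {"gca_line": 49.14, "gca_tester": 10.75, "sca": 0.58,
                        "line_env": 82.91, "tester_env": 10.45, "sca_env": 0.00,
                        "residual": 102.23},
                "genotype": {"genotype": 53.21, "gxe": 74.36, "residual": 121.5},
                "mean": 112.16},
    },
}

_CHECK_NAMES = ("DH04", "DK8031", "H513", "PH3253", "Pioneer3253", "WH505")
_N_ENV_DEFAULT = {"drought": 3, "optimum": 4}
_GY_ASI_CORR_DEFAULT = {"drought": -0.5, "optimum": -0.3}


def regime_presets(name: str) -> dict:
    """The per-trait variance regime and trait means for ``drought``/``optimum``.

    Returns a deep copy; the stored presets are immutable.
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown variance regime {name!r}; known: {sorted(_PRESETS)}")
    return copy.deepcopy(_PRESETS[name])


@dataclass
class SimulationConfig:
    """Design dimensions, variance regime, and seed for one simulated trial.

    Defaults reproduce the reference study's drought design: 93 + 172 lines,
    3 single-cross testers per heterotic group, each line crossed to the 3
    opposite-group testers (795 testcrosses), 6 commercial checks, 3 drought
    environments x 2 replicates, alpha-lattice blocks of 25 plots.
    """

    regime: str = "drought"
    n_lines_a: int = 93
    n_lines_b: int = 172
    n_testers_per_group: int = 3
    testers_per_line: int = 3
    n_env: int | None = None        # default: 3 drought, 4 optimum
    n_rep: int = 2
    block_size: int = 25
    traits: tuple[str, ...] = ("GY", "AD", "SD", "ASI", "PH", "EH")
    include_checks: bool = True
    include_raw: bool = False       # also emit field weight + moisture for GY
    variance_source: str = "lxt"    # "lxt" (combining-ability partition) or "genotype"
    variances: dict = field(default_factory=dict)   # per-trait overrides
    trait_means: dict = field(default_factory=dict)
    gy_asi_corr: float | None = None
    env_var_scale: float = 1.0      # env-shift variance as multiple of residual
    rep_var_scale: float = 0.05
    block_var_scale: float = 0.05   # block variance as fraction of residual
    seed: int = 0

    def __post_init__(self):
        if self.regime not in _PRESETS:
            raise KeyError(f"unknown variance regime {self.regime!r}")
        if self.n_env is None:
            self.n_env = _N_ENV_DEFAULT[self.regime]
        if self.gy_asi_corr is None:
            self.gy_asi_corr = _GY_ASI_CORR_DEFAULT[self.regime]
        if min(self.n_lines_a + self.n_lines_b, self.n_testers_per_group,
               self.n_env, self.n_rep, self.block_size) < 1:
            raise ValueError("design dimensions must be >= 1")
        if self.variance_source not in ("lxt", "genotype"):
            raise ValueError("variance_source must be 'lxt' or 'genotype'")

    def trait_variances(self, trait: str) -> dict:
        preset = _PRESETS[self.regime].get(trait, {}).get(self.variance_source, None)
        base = dict(preset) if preset else {}
        base.update(self.variances.get(trait, {}))
        if not base:
            raise KeyError(f"no variance regime for trait {trait!r}")
        for k, v in base.items():
            if v < 0:
                raise ValueError(f"negative variance {k}={v} for trait {trait!r}")
        return base

    def trait_mean(self, trait: str) -> float:
        if trait in self.trait_means:
            return float(self.trait_means[trait])
        return float(_PRESETS[self.regime][trait]["mean"])


def reference_plan(config: SimulationConfig | None = None) -> CrossingPlan:
    """The study-sized crossing plan implied by a config (default 265 x 3)."""
    config = config or SimulationConfig()
    lines = [InbredLine(f"LA{i + 1:03d}", "A") for i in range(config.n_lines_a)] + \
            [InbredLine(f"LB{i + 1:03d}", "B") for i in range(config.n_lines_b)]
    testers = [Tester(f"TA{i + 1}", "A") for i in range(config.n_testers_per_group)] + \
              [Tester(f"TB{i + 1}", "B") for i in range(config.n_testers_per_group)]
    return build_crossing_plan(lines, testers, config.testers_per_line)


def _draw(rng, var: float, size) -> np.ndarray:
    if var <= 0:
        return np.zeros(size)
    return rng.normal(0.0, np.sqrt(var), size)


def simulate_trial(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate one multi-environment trial.

    Returns
    -------
    plots : DataFrame
        Plot table in the standard schema (env, regime, rep, block, entry,
        entry_kind, line, tester, traits); ``SD`` derived as AD + ASI when
        both are simulated.
    truth : dict
        The drawn effect vectors and the variance regime per trait, for
        parameter-recovery checks.  Bit-identical for identical seed+config.
    """
    plan = reference_plan(config)
    crosses = sorted(plan.crosses)
    entries = [f"{l}:{t}" for l, t in crosses]
    kinds = ["testcross"] * len(entries)
    lines_of = {e: c[0] for e, c in zip(entries, crosses)}
    testers_of = {e: c[1] for e, c in zip(entries, crosses)}
    if config.include_checks:
        entries = entries + list(_CHECK_NAMES)
        kinds = kinds + ["check"] * len(_CHECK_NAMES)
    n_entries = len(entries)
    env_prefix = "DS" if config.regime == "drought" else "OP"
    envs = [f"{env_prefix}{j + 1}" for j in range(config.n_env)]

    ss = np.random.SeedSequence(config.seed)
    rng_design, rng_effects = [np.random.default_rng(s) for s in ss.spawn(2)]

    # field layout: per (env, rep), a fresh permutation of entries chunked
    # into consecutive incomplete blocks (resolvable, alpha-lattice-like)
    rows = {"env": [], "regime": [], "rep": [], "block": [], "entry": [],
            "entry_kind": [], "line": [], "tester": []}
    order_index = []
    for env in envs:
        for rep in range(1, config.n_rep + 1):
            perm = rng_design.permutation(n_entries)
            for pos, ei in enumerate(perm):
                rows["env"].append(env)
                rows["regime"].append(config.regime)
                rows["rep"].append(rep)
                rows["block"].append(f"B{pos // config.block_size + 1:02d}")
                e = entries[ei]
                rows["entry"].append(e)
                rows["entry_kind"].append(kinds[ei])
                rows["line"].append(lines_of.get(e))
                rows["tester"].append(testers_of.get(e))
                order_index.append(ei)
    df = pd.DataFrame(rows)
    n_plots = len(df)
    ei = np.asarray(order_index)
    env_i = pd.Categorical(df["env"], categories=envs).codes
    rep_i = df["rep"].to_numpy() - 1

    line_ids = plan.line_ids
    tester_ids = plan.tester_ids
    li = {l: i for i, l in enumerate(line_ids)}
    ti = {t: i for i, t in enumerate(tester_ids)}
    ci = {c: i for i, c in enumerate(crosses)}
    is_check = np.array([k == "check" for k in kinds])
    # per-plot parent indices (-1 for checks)
    plot_line = np.array([li.get(l, -1) if l is not None else -1 for l in rows["line"]])
    plot_tester = np.array([ti.get(t, -1) if t is not None else -1 for t in rows["tester"]])
    plot_cross = np.array([ci.get((l, t), -1) if l is not None else -1
                           for l, t in zip(rows["line"], rows["tester"])])
    plot_entry = ei

    # latent standard-normal line/entry draws shared between GY and ASI so a
    # negative line-level dependence (drought stress syndrome) can be injected
    z_shared_line = rng_effects.standard_normal(len(line_ids))
    z_shared_entry = rng_effects.standard_normal(n_entries)

    truth: dict = {"config": config, "traits": {}}
    sim_traits = [t for t in config.traits if t != "SD"]
    for trait in sim_traits:
        v = config.trait_variances(trait)
        mean = config.trait_mean(trait)
        rho = 0.0
        if trait in ("GY", "ASI") and config.gy_asi_corr:
            # GY uses the shared latent directly; ASI mixes in the shared
            # latent with weight rho, inducing corr(GY_line, ASI_line) = rho
            rho = 1.0 if trait == "GY" else config.gy_asi_corr

        env_eff = _draw(rng_effects, config.env_var_scale * v["residual"], config.n_env)
        rep_eff = _draw(rng_effects, config.rep_var_scale * v["residual"],
                        (config.n_env, config.n_rep))
        n_blocks = -(-n_entries // config.block_size)
        block_eff = _draw(rng_effects, config.block_var_scale * v["residual"],
                          (config.n_env, config.n_rep, n_blocks))
        eps = _draw(rng_effects, v["residual"], n_plots)

        tt: dict = {"variances": dict(v), "mean": mean, "env": env_eff}
        y = np.full(n_plots, mean)
        y += env_eff[env_i] + rep_eff[env_i, rep_i]
        block_pos = np.arange(n_plots) % n_entries // config.block_size
        y += block_eff[env_i, rep_i, block_pos]

        if config.variance_source == "lxt":
            def corr_mix(rng, var, size, z_shared, w):
                if var <= 0:
                    return np.zeros(size)
                z = w * z_shared + np.sqrt(max(1.0 - w * w, 0.0)) \
                    * rng.standard_normal(size)
                return np.sqrt(var) * z

            g_line = corr_mix(rng_effects, v["gca_line"], len(line_ids),
                              z_shared_line, rho)
            g_tester = _draw(rng_effects, v["gca_tester"], len(tester_ids))
            s_lt = _draw(rng_effects, v["sca"], len(crosses))
            le = _draw(rng_effects, v["line_env"], (len(line_ids), config.n_env))
            te = _draw(rng_effects, v["tester_env"], (len(tester_ids), config.n_env))
            lte = _draw(rng_effects, v["sca_env"], (len(crosses), config.n_env))
            # checks carry an own genotypic effect of matching total variance
            g_check = _draw(rng_effects, v["gca_line"] + v["gca_tester"] + v["sca"],
                            n_entries)
            ge_check = _draw(rng_effects,
                             v["line_env"] + v["tester_env"] + v["sca_env"],
                             (n_entries, config.n_env))
            tc = plot_cross >= 0
            y[tc] += (g_line[plot_line[tc]] + g_tester[plot_tester[tc]]
                      + s_lt[plot_cross[tc]]
                      + le[plot_line[tc], env_i[tc]]
                      + te[plot_tester[tc], env_i[tc]]
                      + lte[plot_cross[tc], env_i[tc]])
            chk = ~tc
            y[chk] += g_check[plot_entry[chk]] + ge_check[plot_entry[chk], env_i[chk]]
            tt["line"] = pd.Series(g_line, index=line_ids)
            tt["tester"] = pd.Series(g_tester, index=tester_ids)
            tt["sca"] = pd.Series(s_lt, index=pd.MultiIndex.from_tuples(crosses))
        else:
            def corr_mix_e(var, w):
                if var <= 0:
                    return np.zeros(n_entries)
                z = w * z_shared_entry + np.sqrt(max(1.0 - w * w, 0.0)) \
                    * rng_effects.standard_normal(n_entries)
                return np.sqrt(var) * z

            g = corr_mix_e(v["genotype"], rho)
            ge = _draw(rng_effects, v["gxe"], (n_entries, config.n_env))
            y += g[plot_entry] + ge[plot_entry, env_i]
            tt["genotype"] = pd.Series(g, index=entries)
            tt["gxe"] = pd.DataFrame(ge, index=entries, columns=envs)

        y += eps
        df[trait] = y
        truth["traits"][trait] = tt

    if "SD" in config.traits and "AD" in df and "ASI" in df:
        df["SD"] = df["AD"] + df["ASI"]

    if config.include_raw and "GY" in df:
        layout = TrialLayout()
        moi = rng_effects.normal(13.0, 0.5, n_plots).clip(5.0, 30.0)
        gy = df["GY"].clip(lower=0.0)
        fw = gy * layout.plot_area_m2 / (layout.shelling_fraction * 10.0) \
            / ((100.0 - moi) / (100.0 - layout.standard_moisture))
        df["moisture"] = moi
        df["field_weight"] = fw
        df["GY"] = gy

    return df, truth
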