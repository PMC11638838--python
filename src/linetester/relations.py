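"""Trait–trait Pearson correlations within and across management regimes.

Correlations are computed on entry means (one value per hybrid per trait per
regime), pairwise-complete over missing cells, with two-sided t-test
p-values and the usual */**/*** significance flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .combining import significance_stars

__all__ = ["CorrelationMatrix", "correlate_traits"]

_REGIME_SUFFIX = {"drought": "DS", "optimum": "OPT"}


@dataclass
class CorrelationMatrix:
    """Symmetric r/p/n matrices over (possibly regime-suffixed) trait labels."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        return self.p.map(significance_stars)


def correlate_traits(entry_means: dict[str, pd.DataFrame] | pd.DataFrame,
                     traits: list[str] | None = None,
                     mode: str = "within_regime") -> CorrelationMatrix | dict:
    """Pearson correlation matrix of entry-mean traits.

    Parameters
    ----------
    entry_means : DataFrame or dict of regime -> DataFrame
        Entries in rows, traits in columns.  With a dict and
        ``mode="across_regimes"``, trait columns are suffixed ``_DS`` /
        ``_OPT`` and joined on the entry index so drought and optimum
        expressions of each trait correlate against each other.
    mode : {"within_regime", "across_regimes"}

    Constant traits have undefined correlations; their cells are NaN.
    """
    if isinstance(entry_means, pd.DataFrame):
        return _corr_matrix(entry_means if traits is None else entry_means[traits])
    if mode == "within_regime":
        return {reg: _corr_matrix(df if traits is None else df[traits])
                for reg, df in entry_means.items()}
    if mode == "across_regimes":
        wide = []
        for reg, df in entry_means.items():
            suffix = _REGIME_SUFFIX.get(reg, reg)
            sub = df if traits is None else df[traits]
            wide.append(sub.add_suffix(f"_{suffix}"))
        joined = pd.concat(wide, axis=1, join="outer")
        return _corr_matrix(joined)
    raise ValueError(f"unknown mode {mode!r}")


def _corr_matrix(df: pd.DataFrame) -> CorrelationMatrix:
    cols = list(df.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        xi = df[cols[i]].to_numpy(float)
        for j in range(i, k):
            xj = df[cols[j]].to_numpy(float)
            ok = ~np.isnan(xi) & ~np.isnan(xj)
            n[i, j] = n[j, i] = int(ok.sum())
            if n[i, j] < 3:
                continue
            a, b = xi[ok], xj[ok]
            if np.std(a) == 0 or np.std(b) == 0:
                continue  # constant trait: correlation undefined
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            rij, pij = pearsonr(a, b)
            r[i, j] = r[j, i] = float(rij)
            p[i, j] = p[j, i] = float(pij)
    idx = pd.Index(cols)
    return CorrelationMatrix(pd.DataFrame(r, idx, idx), pd.DataFrame(p, idx, idx),
                             pd.DataFrame(n, idx, idx))
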