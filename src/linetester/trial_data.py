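"""Plot-level trial data: loading, validation, and derived traits.

The plot table is a long-format :class:`pandas.DataFrame`, one row per plot,
with design columns (``env``, ``regime``, ``rep``, ``block``, ``entry``,
``entry_kind``, ``line``, ``tester``) and trait columns.  Raw harvest traits
are ``field_weight`` (kg of dehusked ears per plot) and ``moisture`` (% grain
moisture); ``GY`` (t/ha, moisture-adjusted) and ``ASI`` (days, silking minus
anthesis) are derived from them when absent.  Missing cells are kept as
``NaN`` — no imputation anywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrialLayout",
    "DESIGN_COLUMNS",
    "TRAIT_COLUMNS",
    "load_plot_table",
    "validate_plot_table",
    "derive_traits",
    "derive_grain_yield",
    "derive_asi",
    "plant_density",
    "write_plot_table",
]

#: design (identifier) columns of a plot table
DESIGN_COLUMNS = ("env", "regime", "rep", "block", "entry", "entry_kind", "line", "tester")

#: recognised trait columns, raw and derived
TRAIT_COLUMNS = ("field_weight", "moisture", "AD", "SD", "ASI", "PH", "EH", "GY")

REGIMES = ("drought", "optimum")
ENTRY_KINDS = ("testcross", "check")


class TrialDataError(ValueError):
    """Raised for schema, domain, or design violations in a plot table."""


@dataclass(frozen=True)
class TrialLayout:
    """Field plot geometry and grain-yield adjustment constants.

    Defaults are the trial geometry used throughout: two-row plots of 5 m,
    0.75 m between rows, 0.25 m between hills, one plant per hill after
    thinning, 80% shelling, yields standardised to 12.5% grain moisture.
    """

    row_spacing: float = 0.75       # m between rows
    hill_spacing: float = 0.25      # m between hills within a row
    rows_per_plot: int = 2
    plot_length: float = 5.0        # m
    plants_per_hill: int = 1
    shelling_fraction: float = 0.80
    standard_moisture: float = 12.5  # %

    def __post_init__(self) -> None:
        for name in ("row_spacing", "hill_spacing", "rows_per_plot", "plot_length",
                     "plants_per_hill", "shelling_fraction", "standard_moisture"):
            if getattr(self, name) <= 0:
                raise TrialDataError(f"layout parameter {name!r} must be strictly positive")
        if not 0 < self.shelling_fraction <= 1:
            raise TrialDataError("shelling_fraction must be in (0, 1]")
        if not 0 < self.standard_moisture < 100:
            raise TrialDataError("standard_moisture must be in (0, 100)")

    @property
    def plot_area_m2(self) -> float:
        """Harvested plot area: rows × length × row spacing."""
        return self.rows_per_plot * self.plot_length * self.row_spacing

    @classmethod
    def from_yaml(cls, path) -> "TrialLayout":
        """Read layout parameters from a flat key-value YAML file.

        Keys absent from the file keep their defaults.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def derive_grain_yield(field_weight, moisture, layout: TrialLayout = TrialLayout()):
    """Grain yield in t/ha from plot field weight and grain moisture.

    GY = FW × shelling × (100 − MOI) / (100 − standard MOI) × 10 / area,
    with the area in m².  Vectorised over array inputs; NaN propagates.

    Parameters
    ----------
    field_weight : float or array
        Weight of dehusked ears per plot, kg.  Must be ≥ 0.
    moisture : float or array
        Grain moisture at harvest, percent, in (0, 100).
    """
    fw = np.asarray(field_weight, dtype=float)
    moi = np.asarray(moisture, dtype=float)
    if np.any(fw[~np.isnan(fw)] < 0):
        raise TrialDataError("field_weight must be non-negative")
    bad = ~np.isnan(moi) & ((moi < 0) | (moi >= 100))
    if np.any(bad):
        raise TrialDataError("moisture must lie in [0, 100)")
    area = layout.plot_area_m2
    if area <= 0:
        raise TrialDataError("plot area must be positive")
    gy = fw * layout.shelling_fraction * (100.0 - moi) / (100.0 - layout.standard_moisture) \
        * 10.0 / area
    if np.ndim(field_weight) == 0 and np.ndim(moisture) == 0:
        return float(gy)
    return gy


def derive_asi(AD, SD):
    """Anthesis–silking interval in days: SD − AD (negative = protandry reversed).

    Missing anthesis or silking date yields a missing ASI, never an error.
    """
    ad = np.asarray(AD, dtype=float)
    sd = np.asarray(SD, dtype=float)
    asi = sd - ad
    if np.ndim(AD) == 0 and np.ndim(SD) == 0:
        return float(asi)
    return asi


def plant_density(layout: TrialLayout = TrialLayout()) -> int:
    """Plant population per hectare implied by the layout, nearest integer."""
    return int(round(layout.plants_per_hill * 10000.0 / (layout.row_spacing * layout.hill_spacing)))


def _check_ranges(df: pd.DataFrame) -> None:
    def _bad(col, mask):
        rows = df.index[mask].tolist()
        raise TrialDataError(f"column {col!r}: invalid values at rows {rows[:10]}")

    nonneg = ("field_weight", "AD", "SD", "PH", "EH", "GY")
    for col in nonneg:
        if col in df:
            vals = pd.to_numeric(df[col], errors="coerce")
            mask = df[col].notna() & (vals < 0)
            if mask.any():
                _bad(col, mask)
    if "moisture" in df:
        moi = pd.to_numeric(df["moisture"], errors="coerce")
        mask = df["moisture"].notna() & ((moi <= 0) | (moi >= 100))
        if mask.any():
            _bad("moisture", mask)
    if "PH" in df and "EH" in df:
        both = df["PH"].notna() & df["EH"].notna()
        mask = both & (df["EH"] > df["PH"])
        if mask.any():
            _bad("EH", mask)


def validate_plot_table(df: pd.DataFrame, layout: TrialLayout = TrialLayout()) -> pd.DataFrame:
    """Validate a plot table in place and return it.

    Checks the schema, value domains, the testcross/check parentage rule
    (testcrosses carry both line and tester; checks carry neither), EH ≤ PH,
    and — where both GY and its raw inputs are present — consistency of GY
    with the derivation formula to 1e-6.
    """
    missing = [c for c in ("env", "rep", "block", "entry", "entry_kind") if c not in df]
    if missing:
        raise TrialDataError(f"plot table lacks required columns: {missing}")
    kinds = set(df["entry_kind"].dropna().unique())
    unknown = kinds - set(ENTRY_KINDS)
    if unknown:
        raise TrialDataError(f"unknown entry_kind values: {sorted(unknown)}")
    if "regime" in df:
        bad = set(df["regime"].dropna().unique()) - set(REGIMES)
        if bad:
            raise TrialDataError(f"unknown regime values: {sorted(bad)}")
    reps = pd.to_numeric(df["rep"], errors="coerce")
    if (reps < 1).any() or reps.isna().any():
        raise TrialDataError("rep must be an integer >= 1 for every plot")

    is_tc = df["entry_kind"] == "testcross"
    has_line = df["line"].notna() if "line" in df else pd.Series(False, index=df.index)
    has_tester = df["tester"].notna() if "tester" in df else pd.Series(False, index=df.index)
    bad_tc = is_tc & ~(has_line & has_tester)
    if bad_tc.any():
        raise TrialDataError(
            f"testcross rows without line/tester ids at rows {df.index[bad_tc].tolist()[:10]}")
    bad_check = (df["entry_kind"] == "check") & (has_line | has_tester)
    if bad_check.any():
        raise TrialDataError(
            f"check rows carrying line/tester ids at rows {df.index[bad_check].tolist()[:10]}")

    _check_ranges(df)

    if "GY" in df and "field_weight" in df and "moisture" in df:
        have = df["GY"].notna() & df["field_weight"].notna() & df["moisture"].notna()
        if have.any():
            expect = derive_grain_yield(
                df.loc[have, "field_weight"].to_numpy(float),
                df.loc[have, "moisture"].to_numpy(float), layout)
            if np.max(np.abs(expect - df.loc[have, "GY"].to_numpy(float))) > 1e-6:
                raise TrialDataError("GY column inconsistent with field weight and moisture")
    return df


def derive_traits(df: pd.DataFrame, layout: TrialLayout = TrialLayout()) -> pd.DataFrame:
    """Fill derived trait columns (GY, ASI) where raw inputs exist.

    Existing derived columns are passed through untouched (cells already
    present are never recomputed); only missing cells backed by raw inputs
    are filled.
    """
    out = df.copy()
    if "field_weight" in out and "moisture" in out:
        have = out["field_weight"].notna() & out["moisture"].notna()
        gy = pd.Series(np.nan, index=out.index, dtype=float)
        gy[have] = derive_grain_yield(
            out.loc[have, "field_weight"].to_numpy(float),
            out.loc[have, "moisture"].to_numpy(float), layout)
        if "GY" not in out:
            out["GY"] = gy
        else:
            out["GY"] = out["GY"].where(out["GY"].notna(), gy)
    if "AD" in out and "SD" in out:
        asi = derive_asi(out["AD"].to_numpy(float), out["SD"].to_numpy(float))
        if "ASI" not in out:
            out["ASI"] = asi
        else:
            out["ASI"] = out["ASI"].where(out["ASI"].notna(), pd.Series(asi, index=out.index))
    return out


def load_plot_table(path, layout: TrialLayout = TrialLayout()) -> pd.DataFrame:
    """Read, validate, and derive a plot table from CSV.

    Comma-separated UTF-8; both ``NA`` and the empty string read as missing.
    Unknown columns are preserved untouched.  Returns the validated table
    with GY/ASI filled wherever their raw inputs exist.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    validate_plot_table(df, layout)
    df = derive_traits(df, layout)
    validate_plot_table(df, layout)
    return df


def write_plot_table(df: pd.DataFrame, path) -> None:
    """Write a plot table to CSV with ``NA`` for missing cells (round-trip safe)."""
    df.to_csv(path, index=False, na_rep="NA")
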