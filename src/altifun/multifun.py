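"""Ecosystem multifunctionality indices and ecoenzymatic stoichiometry vectors.

The multifunctionality workflow follows the averaging approach: every
function indicator is min–max standardized across plots,

    f_ij = (x_ij − min_j) / (max_j − min_j)  ∈ [0, 1],

a single-function index EF is the mean of the standardized indicators in
one function group (carbon, nitrogen, phosphorus, productivity), and the
ecosystem multifunctionality index EMF is the mean over all N indicators.
EMF is therefore algebraically the weighted mean of the group EF indices
with weights n_group/N.

Microbial nutrient limitation is summarized by the enzyme-stoichiometry
vector built from the ratios of carbon-acquiring enzyme activity (CEs,
sucrase) to phosphorus-acquiring (PEs, alkaline + acid phosphatase) and to
nitrogen-acquiring (NEs, urease) activity:

    x = CEs/PEs,  y = CEs/NEs,
    VL = sqrt(x² + y²),   VA = degrees(atan2 of the ratio pair).

A longer VL means stronger microbial carbon limitation; VA below 45°
indicates nitrogen limitation and above 45° phosphorus limitation. The
published formula is written spreadsheet-style, where ATAN2 takes (x, y)
— the reverse of the C/math-library (y, x) order — so the angle convention
is explicit and configurable here; the two conventions are complementary
(they sum to 90°) and the 45° threshold semantics survive either reading.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .exceptions import DegenerateInputError, UsageError
from .io import FunctionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "EmfResult",
    "StoichiometryResult",
    "minmax_standardize",
    "ef_index",
    "emf_index",
    "emf_result",
    "element_ratios",
    "enzyme_vector",
]


@dataclass
class EmfResult:
    standardized: pd.DataFrame  # plot × indicator, values in [0, 1]
    ef: pd.DataFrame  # plot × function group
    emf: pd.Series  # plot → multifunctionality index
    correlations: pd.DataFrame  # group → Pearson r (and p) of EF vs EMF


@dataclass
class StoichiometryResult:
    ratios: pd.DataFrame  # plot × {CP_ratio (x), CN_ratio (y)} enzyme ratios
    vector_length: pd.Series
    vector_angle: pd.DataFrame  # one column per requested convention
    limitation: pd.Series  # nitrogen-limited / phosphorus-limited / boundary
    convention: str


def minmax_standardize(fm: FunctionMatrix) -> pd.DataFrame:
    """Min–max standardize each indicator across plots into [0, 1].

    A constant indicator (max == min) is mapped to 0.5 for every plot with
    a logged warning rather than failing the whole panel.
    """
    v = fm.values
    if v.shape[0] < 2:
        raise UsageError("standardization needs at least 2 plots")
    lo, hi = v.min(axis=0), v.max(axis=0)
    span = hi - lo
    const = span == 0
    if const.any():
        log.warning("constant indicators set to 0.5: %s", list(v.columns[const]))
    span = span.replace(0, np.nan)
    out = (v - lo) / span
    out.loc[:, const] = 0.5
    return out


def ef_index(standardized: pd.DataFrame, fm: FunctionMatrix, group: str) -> pd.Series:
    """Single-function index: mean of the group's standardized indicators."""
    cols = fm.indicators_in(group)
    return standardized[cols].mean(axis=1).rename(group)


def emf_index(standardized: pd.DataFrame, fm: FunctionMatrix | None = None) -> pd.Series:
    """Multifunctionality index: mean of all standardized indicators."""
    if fm is not None:
        expected = set(fm.indicator_groups)
        missing = expected - set(standardized.columns)
        if missing:
            raise UsageError(f"missing indicators: {sorted(missing)}")
    if standardized.isna().any().any():
        bad = standardized.stack(future_stack=True)
        bad = bad[bad.isna()]
        plot, ind = bad.index[0]
        raise UsageError(f"missing value for plot {plot!r}, indicator {ind!r}")
    return standardized.mean(axis=1).rename("EMF")


def emf_result(fm: FunctionMatrix) -> EmfResult:
    """Standardize, compute per-group EF and EMF, and correlate each EF
    with EMF across plots (Pearson)."""
    std = minmax_standardize(fm)
    ef = pd.DataFrame({g: ef_index(std, fm, g) for g in fm.group_names})
    emf = emf_index(std, fm)
    corr = {}
    for g in ef.columns:
        r, p = pearsonr(ef[g], emf)
        corr[g] = {"pearson_r": float(r), "p": float(p)}
    return EmfResult(std, ef, emf, pd.DataFrame.from_dict(corr, orient="index"))


def element_ratios(chem: pd.DataFrame) -> pd.DataFrame:
    """Per-plot element mass ratios C/N, C/P, N/P from TC, TN, TP columns.

    Plots with a zero denominator are returned as NaN and logged.
    """
    for col in ("TC", "TN", "TP"):
        if col not in chem.columns:
            raise UsageError(f"missing column {col!r}")
    tn = chem["TN"].where(chem["TN"] != 0)
    tp = chem["TP"].where(chem["TP"] != 0)
    bad = chem.index[(chem["TN"] == 0) | (chem["TP"] == 0)]
    if len(bad):
        log.warning("zero TN/TP denominators for plots: %s", list(bad))
    return pd.DataFrame(
        {"C_N": chem["TC"] / tn, "C_P": chem["TC"] / tp, "N_P": tn / tp}
    )


def enzyme_vector(
    enzymes: pd.DataFrame,
    convention: str = "spreadsheet",
    log_transform: bool = False,
) -> StoichiometryResult:
    """Enzyme-stoichiometry vector length and angle per plot.

    ``enzymes`` needs columns CEs, NEs, PEs (PEs already the summed
    phosphatase activity) — or precomputed ratio columns CP_ratio
    (= CEs/PEs) and CN_ratio (= CEs/NEs). Angles:

    * ``spreadsheet``: VA = degrees(arctan(y / x)) with x = CEs/PEs,
      y = CEs/NEs — the published formula's ATAN2(x, y) ordering;
    * ``math``: the complementary degrees(arctan(x / y));
    * ``both``: report both columns (limitation labels follow the
      spreadsheet angle).

    Non-positive activities are flagged (NaN) rather than propagated.
    """
    if convention not in ("spreadsheet", "math", "both"):
        raise UsageError("convention must be spreadsheet|math|both")
    if {"CP_ratio", "CN_ratio"} <= set(enzymes.columns):
        x = enzymes["CP_ratio"].astype(float).copy()
        y = enzymes["CN_ratio"].astype(float).copy()
        bad = (x <= 0) | (y <= 0) | x.isna() | y.isna()
    else:
        for col in ("CEs", "NEs", "PEs"):
            if col not in enzymes.columns:
                raise UsageError(f"missing enzyme column {col!r}")
        act = enzymes[["CEs", "NEs", "PEs"]].astype(float)
        bad = (act <= 0).any(axis=1) | act.isna().any(axis=1)
        if log_transform:
            act = np.log(act.where(act > 0))
        x = act["CEs"] / act["PEs"]
        y = act["CEs"] / act["NEs"]
    if bad.any():
        log.warning("non-positive enzyme activities flagged: %s", list(enzymes.index[bad]))
        x = x.where(~bad)
        y = y.where(~bad)
    vl = np.sqrt(x**2 + y**2).rename("VL")
    va_spread = np.degrees(np.arctan2(y, x)).rename("VA_spreadsheet")
    va_math = np.degrees(np.arctan2(x, y)).rename("VA_math")
    if convention == "spreadsheet":
        va = pd.DataFrame({"VA": va_spread})
    elif convention == "math":
        va = pd.DataFrame({"VA": va_math})
    else:
        va = pd.DataFrame({"VA_spreadsheet": va_spread, "VA_math": va_math})
    ref = va_spread if convention in ("spreadsheet", "both") else va_math
    limitation = pd.Series(
        np.select(
            [ref.isna(), ref < 45.0, ref > 45.0],
            ["undefined", "nitrogen-limited", "phosphorus-limited"],
            default="boundary",
        ),
        index=enzymes.index,
        name="limitation",
    )
    return StoichiometryResult(
        pd.DataFrame({"CP_ratio": x, "CN_ratio": y}), vl, va, limitation, convention
    )
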