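"""Measured traits, derived root-shape indexes, correlations and year ANOVA.

Nine measured traits describe the morphology of each line (leaf length
MLL, leaf weight LW, root length RL, root shoulder/middle/tip diameters
RSD/RMD/RTD, root weight RW, plant weight PW and dry matter content DMC);
seven ratio indexes derived from them summarise root shape and biomass
allocation.  Statistics operate on line-year aggregates of the replicate
measurements (mean by default, median optional).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "MEASURED_TRAITS",
    "INDEX_DEFS",
    "line_year_means",
    "compute_indexes",
    "correlation_matrix",
    "year_anova",
    "render_correlation_table",
]

MEASURED_TRAITS = ["MLL", "LW", "RL", "RSD", "RMD", "RTD", "RW", "PW", "DMC"]

#: index name -> (numerator trait, denominator trait)
INDEX_DEFS = {
    "iLR": ("LW", "RW"),
    "iSM": ("RSD", "RMD"),
    "iST": ("RSD", "RTD"),
    "iMT": ("RMD", "RTD"),
    "iSL": ("RSD", "RL"),
    "iML": ("RMD", "RL"),
    "iTL": ("RTD", "RL"),
}


def line_year_means(tt: pd.DataFrame, stat: str = "mean") -> pd.DataFrame:
    """Aggregate the long trait table to a (line, year) x trait wide frame."""
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    wide = tt.pivot_table(
        index=["line", "year"], columns="trait", values="value", aggfunc=stat
    )
    wide.columns.name = None
    return wide


def compute_indexes(tt: pd.DataFrame, stat: str = "mean") -> pd.DataFrame:
    """The seven ratio indexes per line-year, from aggregated trait means.

    Zero denominators yield a missing index for that line-year (logged).
    Accepts either the long trait table or an already-aggregated wide frame.
    """
    wide = tt if isinstance(tt.index, pd.MultiIndex) else line_year_means(tt, stat)
    out = pd.DataFrame(index=wide.index)
    n_zero = 0
    for name, (num, den) in INDEX_DEFS.items():
        if num not in wide.columns or den in (None,) or den not in wide.columns:
            continue
        d = wide[den]
        zero = d == 0
        n_zero += int(zero.sum())
        out[name] = np.where(zero, np.nan, wide[num] / d.replace(0, np.nan))
    if n_zero:
        log.info("compute_indexes: %d zero denominators -> missing", n_zero)
    return out


def correlation_matrix(
    tt: pd.DataFrame, year: int, traits: list[str] | None = None, stat: str = "mean"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of line means in one year.

    Returns ``(r, p, stars)``; stars are '***', '**', '*' at the 0.001,
    0.01 and 0.05 two-sided levels.  Constant traits get missing r for all
    their pairs (logged).  Requires >= 3 complete pairs.
    """
    wide = tt if isinstance(tt.index, pd.MultiIndex) else line_year_means(tt, stat)
    sub = wide.xs(year, level="year")
    traits = traits or [t for t in MEASURED_TRAITS if t in sub.columns]
    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    for i in range(k):
        for j in range(i + 1, k):
            pair = sub[[traits[i], traits[j]]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"fewer than 3 complete lines for {traits[i]}/{traits[j]}"
                )
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.std() == 0 or y.std() == 0:
                log.info("constant trait in pair %s/%s; r missing", traits[i], traits[j])
                rr, pp = np.nan, np.nan
            else:
                rr, pp = stats.pearsonr(x, y)
            r.iloc[i, j] = r.iloc[j, i] = rr
            p.iloc[i, j] = p.iloc[j, i] = pp
    stars = p.map(star_code)
    np.fill_diagonal(stars.values, "")
    return r, p, stars


def star_code(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def year_anova(tt: pd.DataFrame, trait: str, alpha: float = 0.01, stat: str = "mean"):
    """One-way ANOVA of line means between the two years.

    Returns ``(F, p, flagged)`` with ``flagged = p < alpha``.  Raises when a
    year is absent or a year has fewer than 2 lines.
    """
    wide = tt if isinstance(tt.index, pd.MultiIndex) else line_year_means(tt, stat)
    years = sorted(wide.index.get_level_values("year").unique())
    if len(years) < 2:
        raise ValueError("both years must be present")
    groups = [wide.xs(y, level="year")[trait].dropna() for y in years]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each year needs at least 2 lines")
    F, p = stats.f_oneway(*groups)
    return float(F), float(p), bool(p < alpha)


def render_correlation_table(
    r1: pd.DataFrame, s1: pd.DataFrame, r2: pd.DataFrame, s2: pd.DataFrame
) -> pd.DataFrame:
    """Two-year correlation table: lower triangle year 1, upper year 2."""
    traits = list(r1.columns)
    out = pd.DataFrame("", index=traits, columns=traits)
    for i, ti in enumerate(traits):
        for j, tj in enumerate(traits):
            if i > j:
                out.iloc[i, j] = f"{r1.iloc[i, j]:.2f} {s1.iloc[i, j]}".strip()
            elif i < j:
                out.iloc[i, j] = f"{r2.iloc[i, j]:.2f} {s2.iloc[i, j]}".strip()
    return out
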