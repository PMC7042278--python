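"""Climate-growth correlation functions over a lagged monthly window.

The chronology for growth year t is correlated, month by month, with climate
variables from the previous (-1), current (0) and following (+1) calendar
year; the default window runs October(t-1) through September(t+1), matching
a southern-hemisphere-style growth season that starts around October of the
ring's label year.  Significance per cell uses the two-sided critical value
of Pearson's r at alpha, with no multiple-testing correction — a deliberately
liberal, per-cell screen (see docs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chronology import Chronology
from .io_formats import ClimateTable


class UnknownVariableError(KeyError):
    pass


@dataclass(frozen=True, order=True)
class MonthKey:
    """A month relative to the growth year: (month 1-12, year offset -1/0/+1)."""

    year_offset: int
    month: int

    def __post_init__(self) -> None:
        if self.year_offset not in (-1, 0, 1):
            raise ValueError("year_offset must be -1, 0 or +1")
        if not 1 <= self.month <= 12:
            raise ValueError("month must be in 1..12")

    def label(self) -> str:
        name = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
                "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"][self.month - 1]
        suffix = {-1: "(-1)", 0: "", 1: "(+1)"}[self.year_offset]
        return name + suffix


def default_window() -> list[MonthKey]:
    """Oct(-1) .. Sep(+1): the 24 months bracketing the growth season."""
    keys = [MonthKey(-1, m) for m in range(10, 13)]
    keys += [MonthKey(0, m) for m in range(1, 13)]
    keys += [MonthKey(1, m) for m in range(1, 10)]
    return keys


@dataclass
class CorrelationResult:
    variable: str
    key: MonthKey
    r: float
    n: int
    significant: bool

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r must lie in [-1, 1]")


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical Pearson r: r_crit = t_c / sqrt(n - 2 + t_c^2)."""
    if n < 4:
        raise ValueError("critical r needs n >= 4")
    t_c = stats.t.ppf(1 - alpha / 2, df=n - 2)
    return float(t_c / np.sqrt(n - 2 + t_c**2))


def monthly_correlations(chron: Chronology, climate: ClimateTable,
                         variables: list[str] | None = None,
                         window: list[MonthKey] | None = None,
                         alpha: float = 0.05,
                         min_overlap: int = 10) -> list[CorrelationResult]:
    """Pearson r of the chronology against each (variable, month) cell.

    Ring year t pairs with the climate value of (t + year_offset, month).
    Cells are flagged significant when |r| exceeds the critical r at alpha.
    """
    variables = variables or climate.variables()
    window = window or default_window()
    years = np.asarray(chron.years)
    index = chron.index.to_numpy(dtype=float)

    out: list[CorrelationResult] = []
    for var in variables:
        try:
            mat = climate.matrix(var)
        except KeyError:
            raise UnknownVariableError(var) from None
        for key in window:
            clim_years = years + key.year_offset
            if key.month not in mat.columns:
                vals = np.full(len(years), np.nan)
            else:
                col = mat[key.month]
                vals = col.reindex(clim_years).to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            n = int(ok.sum())
            if n < min_overlap:
                raise InsufficientOverlapError(
                    f"{var} {key.label()}: overlap {n} < minimum {min_overlap}")
            r = float(np.corrcoef(index[ok], vals[ok])[0, 1])
            out.append(CorrelationResult(
                variable=var, key=key, r=r, n=n,
                significant=abs(r) > critical_r(n, alpha)))
    return out


class InsufficientOverlapError(ValueError):
    pass


def seasonal_aggregate(climate: ClimateTable, variable: str,
                       months: list[MonthKey], stat: str = "sum") -> pd.Series:
    """Aggregate the named months into one value per growth year.

    Growth year t collects the values at (t + offset, month) for each key;
    ``stat`` is "sum" or "mean".  Years with any missing month are dropped.
    """
    if not months:
        raise ValueError("empty month set")
    if stat not in ("sum", "mean"):
        raise ValueError(f"unknown stat {stat!r}")
    mat = climate.matrix(variable)
    years = mat.index.to_numpy()
    growth_years = np.arange(years.min() + 1, years.max())  # both offsets resolvable
    rows = {}
    for t in growth_years:
        vals = []
        for key in months:
            yr = t + key.year_offset
            if yr in mat.index and key.month in mat.columns:
                v = mat.loc[yr, key.month]
                if not np.isnan(v):
                    vals.append(float(v))
                    continue
            vals = None
            break
        if vals is not None:
            rows[int(t)] = sum(vals) if stat == "sum" else float(np.mean(vals))
    return pd.Series(rows, name=f"{variable}_{stat}").sort_index()


def results_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tidy table (variable, month, offset, r, n, significant) for CSV output."""
    return pd.DataFrame([{
        "variable": c.variable, "month": c.key.month,
        "year_offset": c.key.year_offset, "label": c.key.label(),
        "r": c.r, "n": c.n, "significant": c.significant,
    } for c in results])


def plot_correlations(results: list[CorrelationResult], variable: str,
                      alpha: float = 0.05, ax=None):
    """Bar chart of monthly correlations for one variable with the dashed
    significance line convention."""
    import matplotlib.pyplot as plt

    sub = [c for c in results if c.variable == variable]
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    labels = [c.key.label() for c in sub]
    ax.bar(range(len(sub)), [c.r for c in sub],
           color=["tab:red" if c.significant else "tab:gray" for c in sub])
    rc = critical_r(sub[0].n, alpha) if sub else 0
    ax.axhline(rc, ls="--", c="k", lw=0.8)
    ax.axhline(-rc, ls="--", c="k", lw=0.8)
    ax.axhline(0, c="k", lw=0.8)
    ax.set_xticks(range(len(sub)), labels, rotation=90, fontsize=7)
    ax.set_ylabel("r")
    ax.set_title(variable)
    return ax
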