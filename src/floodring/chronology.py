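"""Growth-index standardization and master-chronology construction.

Raw ring widths carry a size/age trend; dividing each width by a centered
five-year moving average converts the series to dimensionless growth indices
centred near 1, which are then averaged across trees into the master
chronology.  Mean sensitivity summarizes the year-to-year variability that
makes a series usable for climate work (values above 0.40 are conventionally
called "high").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import RingSeries

#: mean-sensitivity level conventionally reported as "high"
HIGH_SENSITIVITY = 0.40


class TooShortError(ValueError):
    """Series shorter than the standardization window."""


@dataclass
class Chronology:
    """Year-indexed mean growth index with per-year sample depth."""

    index: pd.Series          # growth index per year, > 0
    sample_depth: pd.Series   # number of series contributing per year
    mean_sensitivity: float | None = None

    def __post_init__(self) -> None:
        if (self.sample_depth < 1).any():
            raise ValueError("sample_depth must be >= 1 wherever an index exists")
        if (self.index <= 0).any():
            raise ValueError("chronology index must be > 0")

    @property
    def years(self) -> np.ndarray:
        return self.index.index.to_numpy()

    @property
    def span(self) -> tuple[int, int]:
        return int(self.index.index.min()), int(self.index.index.max())

    @property
    def high_sensitivity(self) -> bool | None:
        if self.mean_sensitivity is None:
            return None
        return self.mean_sensitivity > HIGH_SENSITIVITY


def moving_average(x: np.ndarray, window: int = 5, edge: str = "shrink") -> np.ndarray:
    """Centered moving average.

    ``edge="shrink"`` uses the shrinking centered window near the ends (3- and
    4-term means for a 5-year window); ``edge="truncate"`` returns NaN there.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    half = window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if edge == "shrink" or (hi - lo) == window:
            out[i] = x[lo:hi].mean()
    return out


def index_series(widths, window: int = 5, edge: str = "shrink") -> np.ndarray:
    """Convert raw widths to growth indices: width / centered moving average.

    Scale-invariant by construction.  Requires at least ``window`` values.
    """
    x = np.asarray(widths, dtype=float)
    if len(x) < window:
        raise TooShortError(f"need >= {window} values to index, got {len(x)}")
    ma = moving_average(x, window=window, edge=edge)
    with np.errstate(invalid="ignore"):
        return x / ma


def index_ring_series(series: RingSeries, window: int = 5,
                      edge: str = "shrink") -> pd.Series:
    """Indexed version of a RingSeries as a year-indexed pandas Series."""
    idx = index_series(series.widths, window=window, edge=edge)
    s = pd.Series(idx, index=series.years, name=series.series_id)
    return s.dropna()


def build_chronology(indexed: list[pd.Series], robust: bool = False) -> Chronology:
    """Average aligned index series into a master chronology.

    Per-year unweighted arithmetic mean of the available indices (the default),
    or Tukey's biweight robust mean with ``robust=True``; sample depth records
    how many series contribute to each year.
    """
    if not indexed:
        raise ValueError("cannot build a chronology from an empty series list")
    frame = pd.concat(indexed, axis=1)
    depth = frame.notna().sum(axis=1)
    keep = depth >= 1
    frame, depth = frame[keep], depth[keep]
    if robust:
        mean = frame.apply(_biweight_mean, axis=1)
    else:
        mean = frame.mean(axis=1)
    mean.index = mean.index.astype(int)
    depth.index = depth.index.astype(int)
    return Chronology(index=mean.sort_index(), sample_depth=depth.sort_index())


def _biweight_mean(row: pd.Series, c: float = 9.0, eps: float = 1e-12) -> float:
    x = row.dropna().to_numpy(dtype=float)
    if len(x) <= 2:
        return float(np.mean(x))
    m = np.median(x)
    mad = np.median(np.abs(x - m))
    if mad < eps:
        return float(m)
    u = (x - m) / (c * mad)
    w = (1 - u**2) ** 2
    w[np.abs(u) >= 1] = 0.0
    return float(np.sum(w * x) / np.sum(w))


def mean_sensitivity(widths) -> float:
    """Mean absolute relative difference between consecutive values.

    MS = (1/(n-1)) * sum |2 (x_i - x_{i-1}) / (x_i + x_{i-1})|; lies in [0, 2)
    for positive series and is scale-invariant.
    """
    x = np.asarray(widths, dtype=float)
    if len(x) < 2:
        raise ValueError("mean sensitivity needs at least 2 values")
    s = x[1:] + x[:-1]
    if np.any(s == 0):
        raise ValueError("adjacent pair sums to zero")
    return float(np.mean(np.abs(2 * (x[1:] - x[:-1]) / s)))


def mdi(series: RingSeries) -> float:
    """Mean diameter increment in mm/year: twice the mean radial ring width."""
    return 2.0 * float(np.mean(series.widths))
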