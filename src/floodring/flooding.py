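"""Plot flood-duration estimation from water marks and the daily gauge record.

Because the floodplain between the gauge and the plots is flat and
tributary-free, the water surface is treated as horizontal: a plot's
elevation on the gauge datum is the year's maximum gauge reading minus the
water mark measured on its trunks, and its flood duration is the mean number
of days per year the gauge exceeds that elevation over a reference window
(ten years by default).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GaugeSeries, PlotRecord
from .population_structure import FloodCategory

logger = logging.getLogger("floodring")

#: gaps up to this many days are linearly interpolated; longer gaps are
#: excluded from the day-count denominator
MAX_INTERP_GAP_DAYS = 5


class DegenerateSplitError(ValueError):
    """All plots share one flood duration: no gradient to split."""


def plot_elevation(water_mark_cm: float, gauge_annual_max_cm: float) -> float:
    """Plot ground elevation on the gauge datum: annual max minus water mark."""
    if water_mark_cm < 0 or gauge_annual_max_cm < 0:
        raise ValueError("water mark and gauge maximum must be >= 0")
    if water_mark_cm > gauge_annual_max_cm:
        raise ValueError("water mark cannot exceed the year's gauge maximum")
    return gauge_annual_max_cm - water_mark_cm


def flood_days(elevation_cm: float, gauge: GaugeSeries,
               years: tuple[int, int] | None = None,
               window: int = 10) -> float:
    """Mean days per year the gauge level exceeds a plot's elevation.

    ``years`` is an inclusive (first, last) span; by default the last
    ``window`` complete years of the record.  Gaps up to
    :data:`MAX_INTERP_GAP_DAYS` are linearly interpolated; days in longer
    gaps are removed from the denominator and the above-count scaled to a
    full year.
    """
    s = gauge.data.set_index("date")["level_cm"]
    all_years = gauge.years()
    if years is None:
        last = int(all_years.max())
        years = (last - window + 1, last)
    y0, y1 = years
    if y0 < all_years.min() or y1 > all_years.max():
        raise ValueError(f"span {y0}-{y1} not covered by the gauge record")
    per_year = []
    for y in range(y0, y1 + 1):
        full = pd.date_range(f"{y}-01-01", f"{y}-12-31", freq="D")
        lv = s.reindex(full)
        lv = lv.interpolate(method="linear", limit=MAX_INTERP_GAP_DAYS,
                            limit_area="inside")
        valid = lv.notna()
        n_valid = int(valid.sum())
        if n_valid == 0:
            logger.warning("flood_days: year %d has no usable gauge days", y)
            continue
        above = int((lv[valid] > elevation_cm).sum())
        per_year.append(above * len(full) / n_valid)
    if not per_year:
        raise ValueError("no usable years in the requested span")
    return float(np.mean(per_year))


def attach_flood_days(plots: list[PlotRecord], gauge: GaugeSeries,
                      survey_year: int, window: int = 10) -> list[PlotRecord]:
    """Fill elevation and flood-days fields of each plot in place."""
    ann_max = gauge.annual_stat("max")
    gmax = float(ann_max[survey_year])
    for p in plots:
        p.elevation_cm_gauge_datum = plot_elevation(p.water_mark_cm, gmax)
        p.flood_days_per_year = flood_days(
            p.elevation_cm_gauge_datum, gauge,
            years=(survey_year - window, survey_year - 1))
    return plots


def split_categories(plots: list[PlotRecord],
                     tree_counts: dict[str, int] | None = None
                     ) -> tuple[FloodCategory, FloodCategory]:
    """Split plots at the midpoint of the observed flood-duration gradient.

    The boundary is (min + max)/2 of the plot flood durations; plots exactly
    at the boundary join the lower (shorter-flooded) category.
    """
    if len(plots) < 2:
        raise ValueError("need at least 2 plots")
    days = np.array([p.flood_days_per_year for p in plots], dtype=float)
    if np.isnan(days).any():
        raise ValueError("all plots need flood_days_per_year (run attach_flood_days)")
    lo, hi = float(days.min()), float(days.max())
    if lo == hi:
        raise DegenerateSplitError("all plots share one flood duration")
    boundary = (lo + hi) / 2.0
    short = [p for p in plots if p.flood_days_per_year <= boundary]
    long_ = [p for p in plots if p.flood_days_per_year > boundary]

    def build(label, members):
        d = [p.flood_days_per_year for p in members]
        n = sum(tree_counts.get(p.plot_id, 0) for p in members) if tree_counts else 0
        return FloodCategory(label=label,
                             flood_day_range=(float(min(d)), float(max(d))),
                             plot_ids=[p.plot_id for p in members], tree_count=n)

    return build("short_flood", short), build("long_flood", long_)


def annual_min_trend_test(gauge: GaugeSeries, breakpoint_year: int
                          ) -> tuple[float, float]:
    """Welch two-sample t-test on annual minimum levels before/after a year.

    "After" includes the breakpoint year.  Returns (t, p); requires at least
    three years on each side and non-degenerate variance.
    """
    mins = gauge.annual_stat("min")
    before = mins[mins.index < breakpoint_year].to_numpy(dtype=float)
    after = mins[mins.index >= breakpoint_year].to_numpy(dtype=float)
    if len(before) < 3 or len(after) < 3:
        raise ValueError("need >= 3 annual minima on each side of the breakpoint")
    if np.std(before) == 0 and np.std(after) == 0:
        raise ValueError("zero variance on both sides: test undefined")
    t, p = stats.ttest_ind(before, after, equal_var=False)
    return float(t), float(p)
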