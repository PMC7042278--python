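"""Cross-dating statistics: sign agreement (Gleichlaeufigkeit), the
Baillie-Pilcher t-value, lag search, missing-ring estimation and the
iterative admission of series to a chronology.

GLK counts year-to-year intervals in which two series move in the same
direction; the t-value transforms the Pearson correlation of detrended,
log-transformed overlapping segments into a Student-t deviate.  Both are the
classical cross-dating quality statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .chronology import build_chronology, index_ring_series, index_series
from .io_formats import RingSeries

#: cap applied to the t-value when r -> 1 (perfect correlation guard)
T_CAP = 100.0


class InsufficientOverlapError(ValueError):
    """Overlap shorter than the configured minimum."""


class UndefinedStatisticError(ValueError):
    """Zero variance makes the correlation (hence t) undefined."""


class DegenerateChronologyError(ValueError):
    """Fewer than two series survive admission."""


@dataclass
class CrossdateConfig:
    """Thresholds for admission to the chronology.

    The classical literature gives no universal cut-offs; GLK >= 60 % and
    t >= 2.0 are common working values and remain explicit configuration.
    """

    min_overlap: int = 10
    glk_min: float = 60.0
    t_min: float = 2.0
    max_shift: int = 0
    missing_ring_k: int = 5   # innermost rings averaged for pith-offset estimation


@dataclass
class CrossdateReport:
    series_a: str
    series_b: str
    overlap_years: int
    glk_percent: float
    t_value: float
    best_lag: int = 0
    admitted: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.glk_percent <= 100.0):
            raise ValueError("glk_percent must lie in [0, 100]")


# ---------------------------------------------------------------------------
# pairwise statistics
# ---------------------------------------------------------------------------

def glk(x, y) -> float:
    """Gleichlaeufigkeit in percent over the aligned overlap of two series.

    Each of the n-1 year-to-year intervals scores 1 when both series move in
    the same direction (both up, both down, or both unchanged), 0 when they
    move oppositely, and 1/2 when exactly one is unchanged (the classical
    Eckstein-Bauch tie convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("glk requires aligned series of equal length")
    if len(x) < 2:
        raise InsufficientOverlapError("glk needs an overlap of >= 2 years")
    sx = np.sign(np.diff(x))
    sy = np.sign(np.diff(y))
    score = np.where(sx == sy, 1.0, np.where(sx * sy == 0, 0.5, 0.0))
    return float(100.0 * score.mean())


def bp_transform(widths, window: int = 5) -> np.ndarray:
    """Baillie-Pilcher detrending: 5-year moving-average index, then log."""
    return np.log(index_series(widths, window=window))


def t_from_r(r: float, n: int) -> float:
    """Student-t deviate of a Pearson correlation: t = r sqrt((n-2)/(1-r^2))."""
    if n < 4:
        raise InsufficientOverlapError("t-value needs overlap n >= 4")
    denom = 1.0 - r * r
    if denom <= 1e-12:
        return float(np.sign(r)) * T_CAP if r != 0 else 0.0
    return float(np.clip(r * np.sqrt((n - 2) / denom), -T_CAP, T_CAP))


def t_value_bp(x, y) -> float:
    """Baillie-Pilcher t of two aligned, already-detrended segments.

    Computes the Pearson correlation of the segments and applies
    :func:`t_from_r`; capped at +/-100 as r -> 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("t_value_bp requires aligned series of equal length")
    n = len(x)
    if n < 4:
        raise InsufficientOverlapError("t-value needs overlap n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("zero variance in a transformed segment")
    r = float(np.corrcoef(x, y)[0, 1])
    return t_from_r(r, n)


def t_value_bp_series(a: RingSeries, b: RingSeries, lag: int = 0) -> tuple[float, int]:
    """BP t-value of two dated series (b shifted by ``lag`` years), with n."""
    ta = pd.Series(bp_transform(a.widths), index=a.years)
    tb = pd.Series(bp_transform(b.widths), index=b.years + lag)
    joined = pd.concat([ta, tb], axis=1).dropna()
    return t_value_bp(joined.iloc[:, 0], joined.iloc[:, 1]), len(joined)


def _aligned_raw(a: RingSeries, b: RingSeries, lag: int) -> tuple[np.ndarray, np.ndarray]:
    sa = pd.Series(a.widths, index=a.years)
    sb = pd.Series(b.widths, index=b.years + lag)
    joined = pd.concat([sa, sb], axis=1).dropna()
    return joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()


def best_lag(a: RingSeries, b: RingSeries, max_shift: int,
             min_overlap: int = 10) -> tuple[int, CrossdateReport]:
    """Search the shift of ``b`` that best matches ``a``.

    A lag of +k means series ``b`` fits best when its years are shifted k
    years later.  Candidate shifts in [-max_shift, +max_shift] are ranked by
    GLK, ties broken by t-value, then deterministically toward smaller |lag|
    (and the more negative lag among equal |lag|).
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    candidates = []
    for lag in range(-max_shift, max_shift + 1):
        xa, xb = _aligned_raw(a, b, lag)
        if len(xa) < max(min_overlap, 2):
            continue
        g = glk(xa, xb)
        try:
            t, n = t_value_bp_series(a, b, lag)
        except (InsufficientOverlapError, UndefinedStatisticError):
            t, n = float("-inf"), len(xa)
        candidates.append((g, t, -abs(lag), -lag, lag, len(xa)))
    if not candidates:
        raise InsufficientOverlapError(
            f"no shift within +/-{max_shift} reaches overlap {min_overlap}")
    g, t, _, _, lag, n = max(candidates)
    report = CrossdateReport(series_a=a.series_id, series_b=b.series_id,
                             overlap_years=n, glk_percent=g,
                             t_value=t if np.isfinite(t) else float("nan"),
                             best_lag=lag)
    return lag, report


def estimate_missing_rings(series: RingSeries, pith_distance_mm: float,
                           k: int = 5) -> int:
    """Estimated count of unmeasured inner rings from the distance to pith.

    round-half-up(pith_distance / mean width of the k innermost rings).
    """
    if pith_distance_mm < 0:
        raise ValueError("pith distance must be >= 0")
    inner = np.asarray(series.widths[:k], dtype=float)
    return int(np.floor(pith_distance_mm / inner.mean() + 0.5))


# ---------------------------------------------------------------------------
# iterative admission
# ---------------------------------------------------------------------------

def _loo_scores(active: list[RingSeries], min_overlap: int) -> dict[str, tuple[float, float]]:
    """Leave-one-out (GLK, t) of each series against the mean of the others."""
    indexed = {s.series_id: index_ring_series(s) for s in active}
    scores: dict[str, tuple[float, float]] = {}
    for s in active:
        others = [idx for sid, idx in indexed.items() if sid != s.series_id]
        chron = build_chronology(others).index
        joined = pd.concat([indexed[s.series_id], chron], axis=1).dropna()
        if len(joined) < max(min_overlap, 4):
            scores[s.series_id] = (0.0, float("-inf"))
            continue
        g = glk(joined.iloc[:, 0], joined.iloc[:, 1])
        try:
            t = t_value_bp(np.log(joined.iloc[:, 0]), np.log(joined.iloc[:, 1]))
        except UndefinedStatisticError:
            t = float("-inf")
        scores[s.series_id] = (g, t)
    return scores


def crossdate_set(series: list[RingSeries],
                  config: CrossdateConfig | None = None
                  ) -> tuple[list[RingSeries], list[CrossdateReport]]:
    """Admit series to the chronology by iterative leave-one-out rejection.

    Each series is scored against the mean index chronology of the remaining
    ones; while any series falls below the GLK and t thresholds, the worst
    offender is dropped and the scores recomputed.  Returns the admitted
    series and the full pairwise report matrix (all input pairs at lag 0).
    """
    cfg = config or CrossdateConfig()
    if len(series) < 2:
        raise DegenerateChronologyError("cross-dating needs at least 2 series")

    active = list(series)
    while len(active) >= 2:
        scores = _loo_scores(active, cfg.min_overlap)
        failing = [sid for sid, (g, t) in scores.items()
                   if g < cfg.glk_min or t < cfg.t_min]
        if not failing:
            break
        worst = min(failing, key=lambda sid: scores[sid])
        active = [s for s in active if s.series_id != worst]
    if len(active) < 2:
        raise DegenerateChronologyError("fewer than 2 series pass the thresholds")

    admitted_ids = {s.series_id for s in active}
    reports: list[CrossdateReport] = []
    for a, b in combinations(series, 2):
        xa, xb = _aligned_raw(a, b, 0)
        if len(xa) < 2:
            continue
        g = glk(xa, xb)
        try:
            t, n = t_value_bp_series(a, b, 0)
        except (InsufficientOverlapError, UndefinedStatisticError):
            t, n = float("nan"), len(xa)
        reports.append(CrossdateReport(
            series_a=a.series_id, series_b=b.series_id, overlap_years=n,
            glk_percent=g, t_value=t, best_lag=0,
            admitted=a.series_id in admitted_ids and b.series_id in admitted_ids))
    return active, reports


def reports_to_frame(reports: list[CrossdateReport]) -> pd.DataFrame:
    """Tabulate a report list for CSV output."""
    return pd.DataFrame([r.__dict__ for r in reports])
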