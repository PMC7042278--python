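"""Diameter classing, age assignment and recruitment-vs-flood comparisons.

The inventory's DBH values are binned into K equal-width classes with K from
Sturges' rule (K = 1 + 3.3 log10 N, rounded half-up) and width (max - min)/K;
ages come from the inverted sigmoidal growth model.  Recruitment differences
between flood categories are tested with a Pearson chi-square on the
category x class contingency table, and per-class establishment-year spans
feed one-way ANOVA / Tukey HSD comparisons of flood and precipitation levels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .growth_model import GrowthModelFit, age_from_dbh
from .io_formats import ClimateTable, GaugeSeries, TreeRecord

logger = logging.getLogger("floodring")

#: inventory inclusion threshold: circumference at breast height, cm
CBH_THRESHOLD_CM = 15.0


class DegenerateBreadthError(ValueError):
    """All DBH values identical: class width would be zero."""


@dataclass
class DiameterClassing:
    """Equal-width diameter classes with counts and (optional) age spans."""

    n: int
    breadth: float                 # max - min DBH, cm
    k: int                         # Sturges class count
    edges: np.ndarray              # K+1 ascending boundaries, cm
    counts: np.ndarray             # per-class tree counts
    age_spans: list[tuple[float, float]] | None = None  # via growth model

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("class edges must be strictly increasing")
        if int(self.counts.sum()) != self.n:
            raise ValueError("class counts must sum to N")

    @property
    def width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def labels(self) -> list[str]:
        return [f"{self.edges[i]:.2f}-{self.edges[i+1]:.2f}"
                for i in range(self.k)]


@dataclass
class FloodCategory:
    """One half of the flood-duration gradient."""

    label: str
    flood_day_range: tuple[float, float]
    plot_ids: list[str] = field(default_factory=list)
    tree_count: int = 0


# ---------------------------------------------------------------------------
# inclusion & classing
# ---------------------------------------------------------------------------

def cbh_to_dbh(cbh_cm: float) -> float:
    """DBH = CBH / pi."""
    if cbh_cm <= 0:
        raise ValueError("CBH must be > 0")
    return cbh_cm / math.pi


def apply_inclusion(trees: list[TreeRecord],
                    min_cbh_cm: float = CBH_THRESHOLD_CM
                    ) -> tuple[list[TreeRecord], list[TreeRecord]]:
    """Split trees into (included, excluded) by the CBH inclusion threshold.

    Trees carrying only DBH are compared on the equivalent scale
    (DBH >= min_cbh / pi).  Exclusions are logged with the reason.
    """
    min_dbh = min_cbh_cm / math.pi
    included, excluded = [], []
    for t in trees:
        cbh = t.cbh_cm if t.cbh_cm is not None else t.dbh_cm * math.pi
        if cbh >= min_cbh_cm - 1e-9:
            included.append(t)
        else:
            excluded.append(t)
            logger.info("tree %s excluded: CBH %.2f cm < threshold %.1f cm "
                        "(DBH equivalent %.2f cm)", t.tree_id, cbh, min_cbh_cm, min_dbh)
    return included, excluded


def sturges_k(n: int) -> int:
    """Sturges' class count, rounded half-up: K = round(1 + 3.3 log10 N)."""
    if n < 2:
        raise ValueError("need N >= 2")
    return int(math.floor(1 + 3.3 * math.log10(n) + 0.5))


def make_classes(dbh_values, k: int | None = None,
                 fit: GrowthModelFit | None = None) -> DiameterClassing:
    """Equal-width diameter classing by Sturges' rule.

    Classes are half-open [lo, hi) except the last, which closes at the
    maximum.  When a growth-model fit is supplied, each class also gets the
    age span obtained by inverting its DBH boundaries (boundaries at or above
    the asymptote are clamped just below it).
    """
    d = np.sort(np.asarray(dbh_values, dtype=float))
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 values")
    breadth = float(d[-1] - d[0])
    if breadth == 0:
        raise DegenerateBreadthError("all DBH values are equal")
    kk = k if k is not None else sturges_k(n)
    edges = d[0] + np.arange(kk + 1) * (breadth / kk)
    edges[-1] = d[-1]  # guard fp drift so the max lands in the last class
    counts = np.histogram(d, bins=edges)[0]  # last bin closed, matching the rule
    spans = None
    if fit is not None:
        spans = []
        hi_invertible = min(d[-1], fit.beta0 * (1 - 1e-9))
        for i in range(kk):
            lo = min(edges[i], hi_invertible)
            hi = min(edges[i + 1], hi_invertible)
            a_lo = float(age_from_dbh(fit, lo)) if lo > 0 else 0.0
            a_hi = float(age_from_dbh(fit, hi))
            spans.append((a_lo, a_hi))
    return DiameterClassing(n=n, breadth=breadth, k=kk, edges=edges,
                            counts=counts, age_spans=spans)


def assign_ages(records: list[TreeRecord], fit: GrowthModelFit) -> list[TreeRecord]:
    """Assign an age to every record by inverting the growth model.

    Records with DBH at or above the asymptote cannot be inverted; they are
    flagged and assigned the age of the oldest invertible DBH in the sample.
    """
    invertible = [t for t in records if t.dbh_cm < fit.beta0]
    if not invertible:
        raise ValueError("no record has DBH below the asymptote")
    max_age = max(float(age_from_dbh(fit, t.dbh_cm)) for t in invertible)
    flagged = 0
    for t in records:
        if t.dbh_cm < fit.beta0:
            t.age_years = float(age_from_dbh(fit, t.dbh_cm))
            t.age_flagged = False
        else:
            t.age_years = max_age
            t.age_flagged = True
            flagged += 1
    if flagged:
        logger.warning("assign_ages: %d record(s) at/above the asymptote flagged", flagged)
    return records


# ---------------------------------------------------------------------------
# recruitment vs flood regime
# ---------------------------------------------------------------------------

def flood_class_chisq(counts_by_category: dict[str, np.ndarray],
                      min_expected: float = 1.0) -> tuple[float, int, float]:
    """Pearson chi-square on the flood-category x diameter-class table.

    Classes whose expected count falls below ``min_expected`` are pooled into
    their left neighbour (the first class pools rightward); pooling is logged.
    Returns (chi2, df, p).
    """
    table = np.vstack([np.asarray(v, dtype=float)
                       for v in counts_by_category.values()])
    if table.shape[0] != 2:
        raise ValueError("exactly two flood categories are required")

    def expected(tab):
        return np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()

    while table.shape[1] > 1:
        exp = expected(table)
        bad = np.where((exp < min_expected).any(axis=0))[0]
        if len(bad) == 0:
            break
        j = int(bad[0])
        tgt = j - 1 if j > 0 else j + 1
        logger.info("flood_class_chisq: pooling class %d into %d (expected < %.1f)",
                    j, tgt, min_expected)
        table[:, tgt] += table[:, j]
        table = np.delete(table, j, axis=1)
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def oneway_f(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and p across groups (between/within variance ratio)."""
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def _grouping_letters(means: pd.Series, distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: groups not separated by Tukey share a letter."""
    order = list(means.sort_values(ascending=False).index)
    letters: dict[str, str] = {g: "" for g in order}
    groups: list[set[str]] = []  # each set = members sharing one letter
    for g in order:
        placed = False
        for grp in groups:
            if all((min(g, o), max(g, o)) not in distinct for o in grp):
                grp.add(g)
                placed = True
        if not placed:
            groups.append({g})
    for i, grp in enumerate(groups):
        ch = chr(ord("a") + i)
        for g in grp:
            letters[g] += ch
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def climate_by_age_class(classing: DiameterClassing,
                         climate: ClimateTable,
                         gauge: GaugeSeries,
                         survey_year: int,
                         n_classes: int = 5,
                         min_count: int = 5,
                         alpha: float = 0.05) -> pd.DataFrame:
    """ANOVA + Tukey of environmental history across establishment cohorts.

    For each of the first ``n_classes`` diameter classes (each required to
    hold more than ``min_count`` individuals), the class's age span (from the
    growth model) maps to an establishment-year span before ``survey_year``.
    For the years of each span we collect the annual maximum flood level,
    annual minimum flood level and total precipitation, run a one-way ANOVA
    per variable across classes, and — where significant — a Tukey HSD at
    ``alpha`` with compact grouping letters.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if classing.age_spans is None:
        raise ValueError("classing must carry age spans (pass fit= to make_classes)")
    use = list(range(min(n_classes, classing.k)))
    for i in use:
        if classing.counts[i] <= min_count:
            raise ValueError(f"class {i} has <= {min_count} individuals")

    ann_max = gauge.annual_stat("max")
    ann_min = gauge.annual_stat("min")
    precip = (climate.matrix("precipitation_mm").sum(axis=1))

    rows = []
    for i in use:
        a_lo, a_hi = classing.age_spans[i]
        y_lo = survey_year - int(round(a_hi))
        y_hi = survey_year - int(round(a_lo))
        years = [y for y in range(y_lo, y_hi + 1)
                 if y in ann_max.index and y in precip.index]
        if not years:
            raise ValueError(f"class {i}: establishment span {y_lo}-{y_hi} "
                             "not covered by gauge/climate records")
        for y in years:
            rows.append({"class": f"C{i+1}", "year": y,
                         "flood_max_cm": float(ann_max[y]),
                         "flood_min_cm": float(ann_min[y]),
                         "precip_total_mm": float(precip[y])})
    long = pd.DataFrame(rows)

    out = []
    for var in ("flood_max_cm", "flood_min_cm", "precip_total_mm"):
        groups = [g[var].to_numpy() for _, g in long.groupby("class")]
        names = sorted(long["class"].unique())
        f, p = oneway_f(groups)
        letters = {g: "a" for g in names}
        if p < alpha:
            tk = pairwise_tukeyhsd(long[var], long["class"], alpha=alpha)
            distinct = {(min(a, b), max(a, b))
                        for (a, b), rej in zip(
                            [(tk.groupsunique[i], tk.groupsunique[j])
                             for i, j in zip(*np.triu_indices(len(tk.groupsunique), 1))],
                            tk.reject) if rej}
            means = long.groupby("class")[var].mean()
            letters = _grouping_letters(means, distinct)
        for g in names:
            sub = long[long["class"] == g][var]
            out.append({"variable": var, "class": g, "mean": float(sub.mean()),
                        "sd": float(sub.std(ddof=1)), "n_years": len(sub),
                        "F": float(f), "p": float(p), "letters": letters[g]})
    return pd.DataFrame(out)
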