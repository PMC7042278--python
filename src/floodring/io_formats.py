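"""File formats and domain containers for the flood-pulse dendroecology pipeline.

Ring-width series travel in the Tucson/RWL decadal archive format, everything
else (monthly climate, daily river gauge, tree/plot inventory) in long-form
RFC-4180 CSV.  Parsing is strict: malformed input raises rather than being
silently dropped, and every reader reconciles its row counts in a parse report.

Calendar convention used throughout the package: a ring is labelled by the
calendar year in which its growth season *starts* (the season starts around
October, with wood formation beginning December-January).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("floodring")

#: climate variables accepted by :class:`ClimateTable`
CLIMATE_VARIABLES = frozenset(
    {"precipitation_mm", "nino12", "nino3", "nino34", "nino4", "soi", "pdo",
     "gauge_level_cm"}
)


class ParseError(ValueError):
    """Malformed content in an input file (carries the offending line number)."""


class StructuralError(ValueError):
    """Well-formed lines that violate a structural invariant (e.g. decades out of order)."""


class DuplicateKeyError(ValueError):
    """Two rows claim the same (year, month, variable) cell."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RingSeries:
    """One tree's dated annual radial increments, oldest to youngest.

    Parameters
    ----------
    series_id : str
        Identifier of the measured radius/core (max 8 chars in RWL output).
    tree_id : str
        Identifier of the tree the radius belongs to.
    first_year : int
        Calendar year of the innermost *measured* ring.
    widths : list of float
        Radial increments in mm, 0.01 mm resolution, strictly positive.
    pith_offset : int
        Estimated count of unmeasured innermost rings (core missed the pith).
    method : str
        ``"destructive"`` (stem disc) or ``"core"`` (increment borer).
    """

    series_id: str
    tree_id: str
    first_year: int
    widths: list[float] = field(default_factory=list)
    pith_offset: int = 0
    method: str = "core"

    def __post_init__(self) -> None:
        self.widths = [float(w) for w in self.widths]
        if not self.widths:
            raise ValueError(f"series {self.series_id!r}: widths must be non-empty")
        if any(w <= 0 for w in self.widths):
            raise ValueError(f"series {self.series_id!r}: all widths must be > 0")
        if self.pith_offset < 0:
            raise ValueError(f"series {self.series_id!r}: pith_offset must be >= 0")
        if self.method not in ("destructive", "core"):
            raise ValueError(f"series {self.series_id!r}: unknown method {self.method!r}")

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def __len__(self) -> int:
        return len(self.widths)

    def to_series(self) -> pd.Series:
        """Widths as a year-indexed pandas Series (mm)."""
        return pd.Series(self.widths, index=self.years, name=self.series_id)


@dataclass
class ClimateTable:
    """Monthly environmental series keyed by (year, month, variable).

    Backed by a tidy DataFrame with columns ``year, month, variable, value``;
    one value per key, contiguous year coverage per variable.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"year", "month", "variable", "value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"climate table needs columns {sorted(required)}")
        bad = set(self.data["variable"]) - CLIMATE_VARIABLES
        if bad:
            raise ValueError(f"unknown climate variables: {sorted(bad)}")
        if ((self.data["month"] < 1) | (self.data["month"] > 12)).any():
            raise ValueError("month must be in 1..12")
        dup = self.data.duplicated(subset=["year", "month", "variable"])
        if dup.any():
            row = self.data[dup].iloc[0]
            raise DuplicateKeyError(
                f"duplicate climate cell ({row['year']}, {row['month']}, {row['variable']})"
            )
        # gaps inside the covered span are tolerated but logged
        for var, grp in self.data.groupby("variable"):
            span = (grp["year"].max() - grp["year"].min() + 1) * 12
            have = len(grp)
            first = grp.sort_values(["year", "month"]).iloc[0]
            last = grp.sort_values(["year", "month"]).iloc[-1]
            span = span - (first["month"] - 1) - (12 - last["month"])
            if have < span:
                logger.warning("climate variable %s: %d missing months inside span",
                               var, span - have)

    def variables(self) -> list[str]:
        return sorted(self.data["variable"].unique())

    def matrix(self, variable: str) -> pd.DataFrame:
        """Year x month value matrix for one variable (years as rows)."""
        sub = self.data[self.data["variable"] == variable]
        if sub.empty:
            raise KeyError(f"unknown variable {variable!r}")
        return sub.pivot(index="year", columns="month", values="value")

    def get(self, variable: str, year: int, month: int) -> float:
        m = self.matrix(variable)
        return float(m.loc[year, month])


@dataclass
class GaugeSeries:
    """Daily river level (cm above gauge zero) with strictly increasing dates."""

    data: pd.DataFrame  # columns: date (datetime64), level_cm

    def __post_init__(self) -> None:
        if not {"date", "level_cm"}.issubset(self.data.columns):
            raise ValueError("gauge series needs columns date, level_cm")
        self.data = self.data.copy()
        self.data["date"] = pd.to_datetime(self.data["date"])
        d = self.data["date"]
        if not d.is_monotonic_increasing or d.duplicated().any():
            raise StructuralError("gauge dates must be strictly increasing")
        gaps = d.diff().dt.days.dropna()
        n_gaps = int((gaps > 1).sum())
        if n_gaps:
            logger.warning("gauge series: %d gaps in daily coverage", n_gaps)

    def years(self) -> np.ndarray:
        return np.unique(self.data["date"].dt.year)

    def annual_stat(self, stat: str) -> pd.Series:
        """Per-calendar-year max/min of the daily level."""
        g = self.data.set_index("date")["level_cm"].groupby(lambda d: d.year)
        if stat == "max":
            return g.max()
        if stat == "min":
            return g.min()
        raise ValueError(f"unknown stat {stat!r}")


@dataclass
class TreeRecord:
    """One inventoried stem: tree/plot ids, CBH and/or DBH (cm), height (m)."""

    tree_id: str
    plot_id: str
    dbh_cm: float
    cbh_cm: float | None = None
    height_m: float | None = None
    age_years: float | None = None       # filled by population_structure.assign_ages
    age_flagged: bool = False            # dbh at/above the fitted asymptote

    def __post_init__(self) -> None:
        if self.dbh_cm <= 0:
            raise ValueError(f"tree {self.tree_id!r}: dbh_cm must be > 0")
        if self.cbh_cm is not None:
            if abs(self.dbh_cm - self.cbh_cm / math.pi) > 0.01 * self.dbh_cm + 0.01:
                raise ValueError(
                    f"tree {self.tree_id!r}: dbh_cm inconsistent with cbh_cm/pi")


@dataclass
class PlotRecord:
    """One 50 x 5 m inventory plot with its flood-mark measurement."""

    plot_id: str
    water_mark_cm: float
    area_m2: float = 250.0
    elevation_cm_gauge_datum: float | None = None
    flood_days_per_year: float | None = None

    def __post_init__(self) -> None:
        if self.water_mark_cm < 0:
            raise ValueError(f"plot {self.plot_id!r}: water_mark_cm must be >= 0")
        if self.area_m2 <= 0:
            raise ValueError(f"plot {self.plot_id!r}: area_m2 must be > 0")


# ---------------------------------------------------------------------------
# Tucson / RWL decadal format
# ---------------------------------------------------------------------------
# Layout: 8-char series id, decade start year, up to 10 integer values per
# line.  End-of-series sentinel 999 marks the 0.01 mm dialect, -9999 the
# 0.001 mm dialect.  We emit the 0.01 mm dialect and accept both on read.

_SENTINELS = {999: 0.01, -9999: 0.001}


def read_rwl(path) -> list[RingSeries]:
    """Parse a Tucson/RWL decadal ring-width archive.

    Returns one :class:`RingSeries` per series in file order, widths in mm.
    Raises :class:`ParseError` for malformed lines (naming the line number)
    and :class:`StructuralError` for non-monotone decades.
    """
    raw: dict[str, list[tuple[int, list[int]]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if not sid or not rest:
                raise ParseError(f"{path}: line {lineno}: missing series id or year")
            try:
                year = int(rest[0])
                vals = [int(v) for v in rest[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if len(vals) > 10:
                raise ParseError(f"{path}: line {lineno}: more than 10 values")
            raw.setdefault(sid, []).append((year, vals))
            if sid not in order:
                order.append(sid)

    out: list[RingSeries] = []
    for sid in order:
        chunks = raw[sid]
        decades = [c[0] for c in chunks]
        if decades != sorted(decades) or len(set(decades)) != len(decades):
            raise StructuralError(f"{path}: series {sid!r}: decade years not increasing")
        values: list[int] = []
        for _, vals in chunks:
            values.extend(vals)
        sentinel = values[-1] if values else None
        if sentinel not in _SENTINELS:
            raise ParseError(f"{path}: series {sid!r}: missing end-of-series sentinel")
        scale = _SENTINELS[sentinel]
        body = values[:-1]
        if not body:
            raise ParseError(f"{path}: series {sid!r}: no measured values")
        first_year = chunks[0][0]
        # verify contiguity: each decade line after the first starts where the
        # previous left off
        pos = first_year
        for i, (year, vals) in enumerate(chunks):
            if i > 0 and year != pos:
                raise StructuralError(
                    f"{path}: series {sid!r}: decade {year} not contiguous (expected {pos})")
            n = len(vals) - (1 if i == len(chunks) - 1 else 0)
            pos = year + n
        widths = [v * scale for v in body]
        out.append(RingSeries(series_id=sid, tree_id=sid, first_year=first_year,
                              widths=widths))
    logger.info("read_rwl: %s -> %d series, %d rings", path, len(out),
                sum(len(s) for s in out))
    return out


def write_rwl(series: list[RingSeries], path) -> None:
    """Write series as Tucson/RWL decadal lines, 0.01 mm dialect, sentinel 999."""
    with open(path, "w") as fh:
        for s in series:
            vals = []
            for w in s.widths:
                v = round(w * 100)
                if not (0 < v <= 9999):
                    raise OverflowError(
                        f"series {s.series_id!r}: width {w} mm exceeds 4-digit field")
                vals.append(v)
            vals.append(999)  # sentinel occupies the slot after the last ring
            year = s.first_year
            i = 0
            while i < len(vals):
                # each line covers to the end of the current decade
                n = 10 - (year % 10)
                chunk = vals[i:i + n]
                fh.write(f"{s.series_id:<8}{year:>4}" +
                         "".join(f"{v:>6}" for v in chunk) + "\n")
                i += n
                year += len(chunk)


# ---------------------------------------------------------------------------
# CSV readers (long-form schemas)
# ---------------------------------------------------------------------------

def read_climate_csv(path) -> ClimateTable:
    """Read a long-form climate CSV with columns year,month,variable,value."""
    df = pd.read_csv(path)
    missing = {"year", "month", "variable", "value"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df = df.astype({"year": int, "month": int, "value": float})
    return ClimateTable(df)


def write_climate_csv(table: ClimateTable, path) -> None:
    table.data.to_csv(path, index=False)


def read_gauge_csv(path) -> GaugeSeries:
    """Read a daily gauge CSV with columns date,level_cm."""
    df = pd.read_csv(path)
    missing = {"date", "level_cm"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return GaugeSeries(df[["date", "level_cm"]].copy())


def write_gauge_csv(gauge: GaugeSeries, path) -> None:
    out = gauge.data.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_inventory_csv(path) -> tuple[list[TreeRecord], list[PlotRecord]]:
    """Read a combined inventory CSV.

    Expected columns: ``row_type`` (tree|plot); for trees ``tree_id, plot_id``
    and at least one of ``cbh_cm``/``dbh_cm`` plus optional ``height_m``; for
    plots ``plot_id, water_mark_cm`` and optional ``area_m2``.  A CBH-only tree
    row gets ``dbh_cm = cbh_cm / pi``.
    """
    df = pd.read_csv(path)
    if "row_type" not in df.columns:
        raise ParseError(f"{path}: missing column row_type")
    trees: list[TreeRecord] = []
    plots: list[PlotRecord] = []
    for _, row in df.iterrows():
        if row["row_type"] == "tree":
            cbh = row.get("cbh_cm")
            cbh = None if pd.isna(cbh) else float(cbh)
            dbh = row.get("dbh_cm")
            if pd.isna(dbh):
                if cbh is None:
                    raise ParseError(f"{path}: tree {row['tree_id']}: no CBH or DBH")
                dbh = cbh / math.pi
            h = row.get("height_m")
            trees.append(TreeRecord(
                tree_id=str(row["tree_id"]), plot_id=str(row["plot_id"]),
                dbh_cm=float(dbh), cbh_cm=cbh,
                height_m=None if pd.isna(h) else float(h)))
        elif row["row_type"] == "plot":
            area = row.get("area_m2")
            plots.append(PlotRecord(
                plot_id=str(row["plot_id"]),
                water_mark_cm=float(row["water_mark_cm"]),
                area_m2=250.0 if pd.isna(area) else float(area)))
        else:
            raise ParseError(f"{path}: unknown row_type {row['row_type']!r}")
    n_rows = len(df)
    if len(trees) + len(plots) != n_rows:
        raise ParseError(f"{path}: parsed {len(trees)+len(plots)} of {n_rows} rows")
    logger.info("read_inventory_csv: %s -> %d trees, %d plots", path, len(trees), len(plots))
    return trees, plots


def write_inventory_csv(trees: list[TreeRecord], plots: list[PlotRecord], path) -> None:
    rows = []
    for t in trees:
        rows.append({"row_type": "tree", "tree_id": t.tree_id, "plot_id": t.plot_id,
                     "cbh_cm": t.cbh_cm, "dbh_cm": t.dbh_cm, "height_m": t.height_m,
                     "water_mark_cm": None, "area_m2": None})
    for p in plots:
        rows.append({"row_type": "plot", "tree_id": None, "plot_id": p.plot_id,
                     "cbh_cm": None, "dbh_cm": None, "height_m": None,
                     "water_mark_cm": p.water_mark_cm, "area_m2": p.area_m2})
    pd.DataFrame(rows).to_csv(path, index=False)
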