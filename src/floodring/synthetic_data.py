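"""Synthetic study generator with planted ground truth.

Emulates a ~34-year monodominant floodplain stand study: a cohort of cored
trees whose ring widths share a positive December(-1) precipitation signal
and a negative ENSO signal; a monomodal annual flood pulse with a recent
decline in annual minima; and a plot inventory whose DBH/age structure
follows the sigmoidal growth model, with a recruitment deficit planted in
the short-flood plots during the final years.

Every generator is a pure function of (config, seed): each draws from its
own named substream of the config seed, so outputs are bit-identical per
seed and independent of call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .growth_model import GrowthModelFit, dbh_from_age
from .io_formats import ClimateTable, GaugeSeries, PlotRecord, RingSeries, TreeRecord

#: long-term monthly mean precipitation (mm), wet season roughly Oct-Mar
DEFAULT_PRECIP_PROFILE = (210.0, 190.0, 160.0, 100.0, 50.0, 25.0,
                          15.0, 20.0, 55.0, 110.0, 160.0, 200.0)


@dataclass
class SimConfig:
    """Design of the synthetic study.  Defaults mirror the emulated field
    design: a 1981-2014 chronology of 36 trees, a 153-tree inventory in 24
    plots of 250 m^2 (0.6 ha) spanning a 42-117 days/yr flood gradient."""

    seed: int = 0
    # chronology design
    start_year: int = 1981          # first ring year of the chronology span
    n_years: int = 34               # chronology span (1981..2014)
    n_trees_chronology: int = 36
    n_destructive: int = 7
    min_series_length: int = 10
    # population design
    n_trees_population: int = 153
    n_plots: int = 24
    plot_area_m2: float = 250.0
    survey_year: int = 2015
    max_tree_age: int = 54
    recruit_survival_tau: float = 15.0  # e-folding age of the standing cohort
    decline_years: int = 9          # final-period recruitment window
    decline_factor: float = 0.10    # short-flood recruitment multiplier in it
    # growth truth
    beta0: float = 80.0             # asymptotic DBH, cm
    beta1: float = 20.0             # age at half-asymptote, yr
    beta2: float = 1.8
    dbh_noise_sd_cm: float = 1.0
    height_a: float = 22.0          # asymptotic height, m
    height_b: float = 15.0          # half-saturation DBH, cm
    height_noise_sd_m: float = 1.0
    field_dbh_error_sd: float = 0.04   # multiplicative, absorbs bark/off-centre
    # climate truth
    climate_start_year: int = 1968
    precip_profile: tuple = DEFAULT_PRECIP_PROFILE
    precip_noise_sigma: float = 0.30   # lognormal sigma of monthly precip
    precip_enso_coupling: float = 0.15 # El Nino years are dry
    enso_ar1: float = 0.7
    # ring response truth: a strongly climate-sensitive floodplain pioneer —
    # log ring width moves ~20% per sd of pre-season precipitation, with the
    # individual noise level set so the series mean sensitivity lands near
    # the "high" (>0.40) regime the emulated stand shows
    b_precip: float = 0.22          # per z of Dec(-1) precipitation, > 0
    b_enso: float = -0.18           # per z of planted-month Nino anomaly, < 0
    b_flood: float = 0.0            # per z of wet-season gauge level
    ring_noise_sd: float = 0.30     # lognormal sigma of ring widths
    pith_offset_max: int = 3        # cores may miss up to this many rings
    # gauge truth
    gauge_base_cm: float = 250.0
    gauge_amplitude_cm: float = 160.0
    gauge_peak_doy: int = 60        # flood peak around 1 March
    gauge_noise_sd_cm: float = 8.0
    gauge_noise_ar1: float = 0.9
    min_decline_cm: float = 60.0    # drop in annual minima after the breakpoint
    flood_days_range: tuple = (42.0, 117.0)

    def growth_fit(self) -> GrowthModelFit:
        return GrowthModelFit(beta0=self.beta0, beta1=self.beta1, beta2=self.beta2)

    @property
    def end_year(self) -> int:
        return self.start_year + self.n_years - 1

    @property
    def breakpoint_year(self) -> int:
        return self.survey_year - self.decline_years + 1

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

def _ar1(rng, n, phi, sd=1.0):
    """AR(1) series with unit-variance marginal scaled to sd."""
    innov_sd = math.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.normal()
    for i in range(1, n):
        x[i] = phi * x[i - 1] + rng.normal(0.0, innov_sd)
    return sd * x


def simulate_climate(cfg: SimConfig) -> ClimateTable:
    """Monthly climate from climate_start_year through survey_year.

    Nino indices load on a shared AR(1) ENSO factor (SOI with negative
    loading, PDO independent and slow); monthly precipitation is the seasonal
    profile times lognormal noise, reduced in proportion to the positive part
    of the ENSO factor so El Nino years come out dry.
    """
    rng = _rng(cfg, 1)
    years = np.arange(cfg.climate_start_year, cfg.survey_year + 1)
    n = len(years) * 12
    factor = _ar1(rng, n, cfg.enso_ar1)

    def loaded(load, phi):
        own = _ar1(rng, n, phi)
        return load * factor + math.sqrt(max(0.0, 1 - load * load)) * own

    series = {
        "nino12": loaded(0.85, cfg.enso_ar1),
        "nino3": loaded(0.90, cfg.enso_ar1),
        "nino34": loaded(0.90, cfg.enso_ar1),
        "nino4": loaded(0.80, cfg.enso_ar1),
        "soi": loaded(-0.80, cfg.enso_ar1),
        "pdo": _ar1(rng, n, 0.95),
    }
    sig = cfg.precip_noise_sigma
    noise = rng.lognormal(mean=-sig * sig / 2.0, sigma=sig, size=n)
    profile = np.tile(np.asarray(cfg.precip_profile), len(years))
    enso_dry = np.clip(1.0 - cfg.precip_enso_coupling * np.maximum(factor, 0.0),
                       0.05, None)
    series["precipitation_mm"] = profile * noise * enso_dry

    rows = []
    ym_year = np.repeat(years, 12)
    ym_month = np.tile(np.arange(1, 13), len(years))
    for var, vals in series.items():
        rows.append(pd.DataFrame({"year": ym_year, "month": ym_month,
                                  "variable": var, "value": vals}))
    return ClimateTable(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# gauge
# ---------------------------------------------------------------------------

def simulate_gauge(cfg: SimConfig) -> GaugeSeries:
    """Daily monomodal flood pulse with AR(1) noise.

    After the breakpoint year the low-water trough is lowered by
    ``min_decline_cm`` (weighted toward the trough so maxima are untouched),
    planting the decline in annual minima the trend test should detect.
    """
    rng = _rng(cfg, 2)
    dates = pd.date_range(f"{cfg.climate_start_year}-01-01",
                          f"{cfg.survey_year}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    phase = 2.0 * math.pi * (doy - cfg.gauge_peak_doy) / 365.25
    level = cfg.gauge_base_cm + cfg.gauge_amplitude_cm * np.cos(phase)
    level = level + _ar1(rng, len(dates), cfg.gauge_noise_ar1, cfg.gauge_noise_sd_cm)
    recent = dates.year.to_numpy() >= cfg.breakpoint_year
    trough_weight = np.maximum(-np.cos(phase), 0.0)  # 1 at low water, 0 at peak
    level = level - cfg.min_decline_cm * trough_weight * recent
    return GaugeSeries(pd.DataFrame({"date": dates, "level_cm": level}))


def gauge_to_monthly(gauge: GaugeSeries) -> pd.DataFrame:
    """Monthly mean gauge level in the long climate schema."""
    s = gauge.data.set_index("date")["level_cm"]
    m = s.groupby([s.index.year, s.index.month]).mean()
    return pd.DataFrame({"year": [i[0] for i in m.index],
                         "month": [i[1] for i in m.index],
                         "variable": "gauge_level_cm", "value": m.to_numpy()})


def merge_gauge_into_climate(climate: ClimateTable, gauge: GaugeSeries) -> ClimateTable:
    """Climate table extended with the monthly-mean gauge level."""
    return ClimateTable(pd.concat(
        [climate.data, gauge_to_monthly(gauge)], ignore_index=True))


# ---------------------------------------------------------------------------
# ring series
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def planted_signals(cfg: SimConfig, climate: ClimateTable,
                    years: np.ndarray) -> dict[str, np.ndarray]:
    """Per-ring-year standardized climate drivers used by the ring model.

    z_precip: December of the previous calendar year; z_enso: Jan-Feb mean of
    Nino 1+2 and Nino 3 of the ring year; z_flood: wet-season (Jan-Apr) mean
    gauge level of the ring year (only used when b_flood != 0).
    """
    pmat = climate.matrix("precipitation_mm")
    z_p = _standardize(pmat.loc[years - 1, 12].to_numpy(dtype=float))
    e12 = climate.matrix("nino12")
    e3 = climate.matrix("nino3")
    enso = np.stack([e12.loc[years, m].to_numpy(dtype=float) for m in (1, 2)] +
                    [e3.loc[years, m].to_numpy(dtype=float) for m in (1, 2)])
    z_e = _standardize(enso.mean(axis=0))
    out = {"z_precip": z_p, "z_enso": z_e}
    if "gauge_level_cm" in climate.variables():
        g = climate.matrix("gauge_level_cm")
        lv = np.stack([g.loc[years, m].to_numpy(dtype=float) for m in (1, 2, 3, 4)])
        out["z_flood"] = _standardize(lv.mean(axis=0))
    return out


def simulate_ring_series(cfg: SimConfig, climate: ClimateTable
                         ) -> tuple[list[RingSeries], dict]:
    """Dated ring-width series for the chronology sample.

    Expected radial width of a tree at cambial age a in ring year t is the
    growth model's annual diameter increment at a (halved, mm), multiplied by
    exp(b_precip z_precip(t) + b_enso z_enso(t) [+ b_flood z_flood(t)]) and
    lognormal noise.  Germination years are drawn so the set of series spans
    exactly the configured chronology window.  Returns the series and a
    ground-truth manifest (germination years, pith offsets, field DBHs).
    """
    rng = _rng(cfg, 3)
    fit = cfg.growth_fit()
    years = np.arange(cfg.start_year, cfg.end_year + 1)
    sig = planted_signals(cfg, climate, years)
    log_climate = cfg.b_precip * sig["z_precip"] + cfg.b_enso * sig["z_enso"]
    if cfg.b_flood != 0.0:
        log_climate = log_climate + cfg.b_flood * sig["z_flood"]

    n = cfg.n_trees_chronology
    latest_start = cfg.end_year - cfg.min_series_length + 1
    # germination skewed early (u^1.5) so sample depth builds up quickly and
    # the chronology robustly spans the whole window
    span = latest_start - cfg.start_year + 1
    germ = cfg.start_year + np.floor(rng.random(n) ** 1.5 * span).astype(int)
    germ[0] = cfg.start_year  # anchor: the chronology spans the full window
    ages_grid = np.arange(0, cfg.n_years + cfg.pith_offset_max + 1)
    dbh_grid = np.concatenate([[0.0], dbh_from_age(fit, ages_grid[1:])])
    annual_radial_mm = np.diff(dbh_grid) * 10.0 / 2.0  # cm diameter -> mm radius

    series: list[RingSeries] = []
    truth = {"germination_year": {}, "pith_offset": {}, "field_dbh_cm": {},
             "height_m": {}, "method": {}}
    for i in range(n):
        g = int(germ[i])
        sid = f"EF{i+1:02d}"
        method = "destructive" if i < cfg.n_destructive else "core"
        pith = 0 if method == "destructive" else int(rng.integers(0, cfg.pith_offset_max + 1))
        yrs = np.arange(g, cfg.end_year + 1)
        ages = yrs - g + 1 + pith       # cambial age of each measured ring
        base = annual_radial_mm[ages - 1]
        noise = rng.lognormal(mean=-cfg.ring_noise_sd**2 / 2.0,
                              sigma=cfg.ring_noise_sd, size=len(yrs))
        idx = yrs - cfg.start_year
        widths = base * np.exp(log_climate[idx]) * noise
        widths = np.round(np.maximum(widths, 0.02), 2)  # 0.01 mm bench, > 0
        series.append(RingSeries(series_id=sid, tree_id=sid, first_year=g,
                                 widths=list(widths), pith_offset=pith,
                                 method=method))
        true_dbh = float(dbh_from_age(fit, ages[-1]))
        fdbh = true_dbh * float(rng.normal(1.0, cfg.field_dbh_error_sd))
        h = cfg.height_a * fdbh / (cfg.height_b + fdbh) + rng.normal(0, cfg.height_noise_sd_m)
        truth["germination_year"][sid] = g
        truth["pith_offset"][sid] = pith
        truth["field_dbh_cm"][sid] = fdbh
        truth["height_m"][sid] = max(float(h), 1.5)
        truth["method"][sid] = method
    return series, truth


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def simulate_population(cfg: SimConfig, fit: GrowthModelFit | None = None,
                        gauge: GaugeSeries | None = None
                        ) -> tuple[list[TreeRecord], list[PlotRecord]]:
    """Plot inventory with the planted recruitment deficit.

    Plot elevations are placed so flood durations span the configured
    gradient (via quantiles of the simulated gauge record when given,
    otherwise of the analytic pulse).  Establishment ages follow steady
    recruitment thinned by exponential survivorship — a young-heavy standing
    cohort; trees established within the final
    ``decline_years`` join short-flood plots with probability downweighted by
    ``decline_factor``.  DBH is the growth model plus noise; records whose
    CBH would fall below 15 cm are dropped, and draws continue until the
    configured population size is reached.
    """
    rng = _rng(cfg, 4)
    fit = fit or cfg.growth_fit()

    # plot elevations from target flood-day quantiles of the daily levels
    targets = np.linspace(cfg.flood_days_range[1], cfg.flood_days_range[0],
                          cfg.n_plots)
    if gauge is None:
        gauge = simulate_gauge(cfg)
    recent = gauge.data[gauge.data["date"].dt.year.between(
        cfg.survey_year - 10, cfg.survey_year - 1)]
    levels = recent["level_cm"].to_numpy()
    elevations = np.quantile(levels, 1.0 - targets / 365.25)
    gmax_survey = float(gauge.annual_stat("max")[cfg.survey_year])
    plots = [PlotRecord(plot_id=f"P{i+1:02d}",
                        water_mark_cm=max(gmax_survey - float(e), 0.0),
                        area_m2=cfg.plot_area_m2)
             for i, e in enumerate(elevations)]
    # lower elevation = longer flooding; first half of `targets` is long-flood
    long_ids = [p.plot_id for p in plots[:cfg.n_plots // 2]]
    short_ids = [p.plot_id for p in plots[cfg.n_plots // 2:]]

    # standing-cohort age distribution: steady recruitment thinned by
    # exponential survivorship with e-folding age recruit_survival_tau
    ages_support = np.arange(2, cfg.max_tree_age + 1)
    w = np.exp(-ages_support / cfg.recruit_survival_tau)
    w /= w.sum()
    min_dbh = 15.0 / math.pi

    trees: list[TreeRecord] = []
    k = 0
    while len(trees) < cfg.n_trees_population:
        age = int(rng.choice(ages_support, p=w))
        dbh = float(dbh_from_age(fit, age)) + float(rng.normal(0, cfg.dbh_noise_sd_cm))
        if dbh < min_dbh:
            continue  # below the CBH-15 cm inclusion threshold
        recent_recruit = age <= cfg.decline_years
        p_short = (cfg.decline_factor / (1.0 + cfg.decline_factor)
                   if recent_recruit else 0.5)
        pool = short_ids if rng.random() < p_short else long_ids
        plot_id = pool[int(rng.integers(0, len(pool)))]
        h = cfg.height_a * dbh / (cfg.height_b + dbh) + float(
            rng.normal(0, cfg.height_noise_sd_m))
        k += 1
        trees.append(TreeRecord(tree_id=f"I{k:03d}", plot_id=plot_id,
                                dbh_cm=dbh, cbh_cm=dbh * math.pi,
                                height_m=max(h, 1.5)))
    return trees, plots


# ---------------------------------------------------------------------------
# one-call study
# ---------------------------------------------------------------------------

def simulate_study(cfg: SimConfig) -> dict:
    """Generate every input of the synthetic study.

    Returns a dict with keys ``climate`` (gauge-merged ClimateTable),
    ``gauge``, ``rings``, ``ring_truth``, ``trees``, ``plots`` and ``config``.
    """
    climate = simulate_climate(cfg)
    gauge = simulate_gauge(cfg)
    climate = merge_gauge_into_climate(climate, gauge)
    rings, truth = simulate_ring_series(cfg, climate)
    trees, plots = simulate_population(cfg, cfg.growth_fit(), gauge)
    return {"climate": climate, "gauge": gauge, "rings": rings,
            "ring_truth": truth, "trees": trees, "plots": plots, "config": cfg}
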