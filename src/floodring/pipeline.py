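"""End-to-end orchestration: synthetic study or on-disk inputs through
cross-dating, chronology, climate correlation, growth modelling, population
structure and flood-duration analysis, into one JSON-serializable report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .chronology import build_chronology, index_ring_series, mdi, mean_sensitivity
from .climate_corr import monthly_correlations, results_to_frame
from .crossdating import CrossdateConfig, crossdate_set, reports_to_frame
from .flooding import annual_min_trend_test, attach_flood_days, split_categories
from .growth_model import (cumulative_curve, fit_height_model, fit_sigmoidal,
                           increment_curve)
from .io_formats import (read_climate_csv, read_gauge_csv, read_inventory_csv,
                         read_rwl, write_climate_csv, write_gauge_csv,
                         write_inventory_csv, write_rwl)
from .population_structure import (apply_inclusion, assign_ages,
                                   climate_by_age_class, flood_class_chisq,
                                   make_classes)
from .synthetic_data import SimConfig, simulate_study

logger = logging.getLogger("floodring")


def _setup_logging(logfile: str | None = None) -> None:
    handlers = [logging.StreamHandler()]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s",
                        handlers=handlers, force=True)


def fit_growth_from_rings(rings, field_dbh: dict[str, float],
                          per_age_mean: bool = True):
    """Pool cumulative curves of all dated trees and fit the sigmoid."""
    pts = [cumulative_curve(s, field_dbh[s.series_id]) for s in rings
           if s.series_id in field_dbh]
    if not pts:
        raise ValueError("no series has a field DBH")
    return fit_sigmoidal(np.vstack(pts), per_age_mean=per_age_mean), pts


def run_study(data: dict, crossdate_cfg: CrossdateConfig | None = None,
              alpha: float = 0.05, flood_window: int = 10) -> dict:
    """Run every analysis stage on an input bundle.

    ``data`` carries ``rings``, ``climate``, ``gauge``, ``trees``, ``plots``,
    a ``field_dbh`` mapping (or a ``ring_truth`` manifest) and the survey
    year.  Returns a nested plain-python report.
    """
    rings = data["rings"]
    climate = data["climate"]
    gauge = data["gauge"]
    survey_year = data.get("survey_year",
                           getattr(data.get("config"), "survey_year", None))
    if survey_year is None:
        raise ValueError("survey_year missing from the input bundle")
    field_dbh = data.get("field_dbh") or data.get("ring_truth", {}).get("field_dbh_cm")

    report: dict = {"version": __version__}

    # -- cross-dating ------------------------------------------------------
    admitted, xreports = crossdate_set(rings, crossdate_cfg)
    report["crossdating"] = {
        "n_input": len(rings), "n_admitted": len(admitted),
        "rejected": sorted({s.series_id for s in rings} -
                           {s.series_id for s in admitted}),
    }

    # -- chronology --------------------------------------------------------
    indexed = [index_ring_series(s) for s in admitted]
    chron = build_chronology(indexed)
    chron.mean_sensitivity = mean_sensitivity(chron.index.to_numpy())
    ms_series = float(np.mean([mean_sensitivity(s.widths) for s in admitted]))
    report["chronology"] = {
        "span": list(chron.span), "n_series": len(admitted),
        "mean_sensitivity_chronology": chron.mean_sensitivity,
        "mean_sensitivity_series_mean": ms_series,
        "high_sensitivity": bool(ms_series > 0.40),
        "mdi_mm_per_year_mean": float(np.mean([mdi(s) for s in admitted])),
    }

    # -- climate correlations ---------------------------------------------
    corr = monthly_correlations(chron, climate, alpha=alpha)
    report["correlations"] = results_to_frame(corr).to_dict(orient="records")

    # -- growth model ------------------------------------------------------
    if field_dbh is None:
        raise ValueError("no field DBH available for the ring sample")
    fit, _ = fit_growth_from_rings(admitted, field_dbh, per_age_mean=True)
    fit_pooled, _ = fit_growth_from_rings(admitted, field_dbh, per_age_mean=False)
    inc_age, inc_val, at_boundary = increment_curve(fit)
    report["growth_model"] = {
        "beta0_cm": fit.beta0, "beta1_yr": fit.beta1, "beta2": fit.beta2,
        "r2_mean_curve": fit.r2, "r2_pooled": fit_pooled.r2,
        "residual_sd_cm": fit.residual_sd,
        "max_increment_cm_per_yr": inc_val, "max_increment_age_yr": inc_age,
        "max_increment_at_boundary": at_boundary,
    }

    # -- population structure ---------------------------------------------
    trees_all = data["trees"]
    trees, excluded = apply_inclusion(trees_all)
    hfit = fit_height_model(trees)
    report["height_model"] = {"a_m": hfit.a, "b_cm": hfit.b, "r2": hfit.r2}

    assign_ages(trees, fit)
    dbh = np.array([t.dbh_cm for t in trees])
    classing = make_classes(dbh, fit=fit)
    ages = np.array([t.age_years for t in trees])
    report["population"] = {
        "n_included": len(trees), "n_excluded": len(excluded),
        "k_classes": classing.k, "class_width_cm": classing.width,
        "class_edges_cm": classing.edges.tolist(),
        "class_counts": classing.counts.tolist(),
        "age_min_yr": float(ages.min()), "age_max_yr": float(ages.max()),
        "n_age_flagged": int(sum(t.age_flagged for t in trees)),
    }

    # -- flooding ----------------------------------------------------------
    plots = attach_flood_days(data["plots"], gauge, survey_year,
                              window=flood_window)
    counts_per_plot = {p.plot_id: sum(t.plot_id == p.plot_id for t in trees)
                       for p in plots}
    short, long_ = split_categories(plots, counts_per_plot)
    cat_counts = {}
    for cat in (short, long_):
        sub = np.array([t.dbh_cm for t in trees if t.plot_id in cat.plot_ids])
        cat_counts[cat.label] = np.histogram(sub, bins=classing.edges)[0]
    chi2, dof, p = flood_class_chisq(cat_counts)
    report["flooding"] = {
        "categories": [{
            "label": c.label, "flood_day_range": list(c.flood_day_range),
            "n_plots": len(c.plot_ids), "n_trees": c.tree_count,
        } for c in (short, long_)],
        "boundary_days": float((min(p_.flood_days_per_year for p_ in plots) +
                                max(p_.flood_days_per_year for p_ in plots)) / 2),
        "first_class_counts": {c.label: int(cat_counts[c.label][0])
                               for c in (short, long_)},
        "chi2": chi2, "chi2_df": dof, "chi2_p": p,
    }

    t_stat, t_p = annual_min_trend_test(gauge, survey_year - 9 + 1)
    report["flooding"]["annual_min_trend"] = {
        "breakpoint_year": survey_year - 9 + 1, "welch_t": t_stat, "p": t_p}

    # -- climate by age class ---------------------------------------------
    try:
        anova = climate_by_age_class(classing, climate, gauge, survey_year,
                                     alpha=alpha)
        report["climate_by_age_class"] = anova.to_dict(orient="records")
    except ValueError as exc:
        report["climate_by_age_class"] = {"error": str(exc)}

    return report


def run_synthetic_study(cfg: SimConfig, **kwargs) -> dict:
    """Simulate the default study and analyse it; report gains a ``truth``
    section with the planted parameters for comparison."""
    data = simulate_study(cfg)
    report = run_study(data, **kwargs)
    report["truth"] = {
        "beta0_cm": cfg.beta0, "beta1_yr": cfg.beta1, "beta2": cfg.beta2,
        "b_precip": cfg.b_precip, "b_enso": cfg.b_enso, "b_flood": cfg.b_flood,
        "decline_factor": cfg.decline_factor, "seed": cfg.seed,
    }
    return report


# ---------------------------------------------------------------------------
# config-file front door
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def load_inputs(cfg: dict) -> dict:
    """Build an input bundle from a config mapping.

    ``mode: synthetic`` simulates everything (``sim:`` overrides SimConfig
    fields); ``mode: files`` reads ``rwl``, ``climate_csv``, ``gauge_csv``,
    ``inventory_csv`` and ``field_dbh_csv`` paths.
    """
    mode = cfg.get("mode", "synthetic")
    if mode == "synthetic":
        sim = SimConfig(**cfg.get("sim", {}))
        data = simulate_study(sim)
        data["survey_year"] = sim.survey_year
        return data
    if mode == "files":
        paths = cfg["inputs"]
        rings = read_rwl(paths["rwl"])
        trees, plots = read_inventory_csv(paths["inventory_csv"])
        field_dbh = None
        if "field_dbh_csv" in paths:
            import pandas as pd
            df = pd.read_csv(paths["field_dbh_csv"])
            field_dbh = dict(zip(df["series_id"], df["dbh_cm"]))
        return {"rings": rings, "climate": read_climate_csv(paths["climate_csv"]),
                "gauge": read_gauge_csv(paths["gauge_csv"]),
                "trees": trees, "plots": plots, "field_dbh": field_dbh,
                "survey_year": int(cfg["survey_year"])}
    raise ValueError(f"unknown mode {mode!r}")


def run_all(config_path, outdir=None) -> dict:
    """Front door: read a YAML config, run every stage, write the report."""
    cfg = load_config(config_path)
    _setup_logging(cfg.get("logfile"))
    data = load_inputs(cfg)
    xcfg = CrossdateConfig(**cfg.get("crossdating", {}))
    report = run_study(data, crossdate_cfg=xcfg,
                       alpha=float(cfg.get("alpha", 0.05)),
                       flood_window=int(cfg.get("flood_window", 10)))
    with open(config_path, "rb") as fh:
        report["config_sha256"] = hashlib.sha256(fh.read()).hexdigest()
    if "config" in data:
        report["sim_config"] = asdict(data["config"])
    out = Path(outdir or cfg.get("outdir", "."))
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    _write_artifacts(data, out)
    logger.info("report written to %s", out / "report.json")
    return report


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _write_artifacts(data: dict, out: Path) -> None:
    write_rwl(data["rings"], out / "rings.rwl")
    write_climate_csv(data["climate"], out / "climate.csv")
    write_gauge_csv(data["gauge"], out / "gauge.csv")
    write_inventory_csv(data["trees"], data["plots"], out / "inventory.csv")
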