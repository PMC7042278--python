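import math

import numpy as np
import pandas as pd
import pytest

from floodring.flooding import flood_days
from floodring.synthetic_data import (SimConfig, merge_gauge_into_climate,
                                      planted_signals, simulate_climate,
                                      simulate_gauge, simulate_population,
                                      simulate_ring_series, simulate_study)


class TestDeterminism:
    def test_climate_bit_identical(self):
        cfg = SimConfig(seed=7)
        a = simulate_climate(cfg).data
        b = simulate_climate(cfg).data
        pd.testing.assert_frame_equal(a, b)

    def test_rings_bit_identical(self):
        cfg = SimConfig(seed=7)
        climate = simulate_climate(cfg)
        r1, _ = simulate_ring_series(cfg, climate)
        r2, _ = simulate_ring_series(cfg, climate)
        assert all(a.widths == b.widths and a.first_year == b.first_year
                   for a, b in zip(r1, r2))

    def test_seeds_differ(self):
        a = simulate_gauge(SimConfig(seed=1)).data["level_cm"]
        b = simulate_gauge(SimConfig(seed=2)).data["level_cm"]
        assert not np.allclose(a, b)


class TestClimate:
    def test_zero_noise_gives_seasonal_profile(self):
        cfg = SimConfig(seed=3, precip_noise_sigma=0.0, precip_enso_coupling=0.0)
        mat = simulate_climate(cfg).matrix("precipitation_mm")
        np.testing.assert_allclose(mat.iloc[0], cfg.precip_profile, rtol=1e-12)
        np.testing.assert_allclose(mat.iloc[-1], cfg.precip_profile, rtol=1e-12)

    def test_zero_coupling_decouples_precip_from_enso(self):
        cfg = SimConfig(seed=3, precip_enso_coupling=0.0, n_years=34)
        table = simulate_climate(cfg)
        p = table.matrix("precipitation_mm").to_numpy().ravel()
        e = table.matrix("nino3").to_numpy().ravel()
        assert abs(np.corrcoef(np.log(p) - np.log(
            np.tile(cfg.precip_profile, len(p) // 12)), e)[0, 1]) < 0.1

    def test_coupling_makes_el_nino_dry(self):
        cfg = SimConfig(seed=3, precip_enso_coupling=0.3)
        table = simulate_climate(cfg)
        p = np.log(table.matrix("precipitation_mm").to_numpy().ravel())
        season = np.log(np.tile(cfg.precip_profile, len(p) // 12))
        e = table.matrix("nino3").to_numpy().ravel()
        assert np.corrcoef(p - season, e)[0, 1] < -0.2


class TestRings:
    def test_zero_effects_zero_noise_gives_age_trend(self):
        cfg = SimConfig(seed=5, b_precip=0.0, b_enso=0.0, ring_noise_sd=0.0,
                        pith_offset_max=0, field_dbh_error_sd=0.0)
        climate = simulate_climate(cfg)
        rings, _ = simulate_ring_series(cfg, climate)
        from floodring.growth_model import dbh_from_age
        fit = cfg.growth_fit()
        for s in rings[:5]:
            ages = np.arange(1, len(s.widths) + 1)
            expected = (np.asarray(dbh_from_age(fit, ages)) -
                        np.concatenate([[0.0], dbh_from_age(fit, ages[:-1])])) * 5
            np.testing.assert_allclose(s.widths, np.round(expected, 2), atol=0.011)

    def test_series_span_matches_design(self, default_study):
        cfg = default_study["config"]
        rings = default_study["rings"]
        assert min(s.first_year for s in rings) == cfg.start_year
        assert all(s.last_year == cfg.end_year for s in rings)
        assert all(len(s) >= cfg.min_series_length for s in rings)
        assert len(rings) == cfg.n_trees_chronology

    def test_planted_precip_signal_visible_in_mean_log_width(self, default_study):
        cfg = default_study["config"]
        rings = default_study["rings"]
        years = np.arange(cfg.start_year, cfg.end_year + 1)
        sig = planted_signals(cfg, default_study["climate"], years)
        logw = pd.concat([np.log(s.to_series()) for s in rings], axis=1).mean(axis=1)
        r = np.corrcoef(logw.loc[years], sig["z_precip"])[0, 1]
        assert r > 0.3


class TestGauge:
    def test_zero_amplitude_constant_level(self):
        cfg = SimConfig(seed=4, gauge_amplitude_cm=0.0, gauge_noise_sd_cm=0.0,
                        min_decline_cm=0.0)
        g = simulate_gauge(cfg)
        assert g.data["level_cm"].nunique() == 1

    def test_noiseless_sinusoid_crossing_count_analytic(self):
        """Days above a threshold match the arccos crossing formula."""
        cfg = SimConfig(seed=4, gauge_noise_sd_cm=0.0, min_decline_cm=0.0)
        g = simulate_gauge(cfg)
        threshold = cfg.gauge_base_cm + 0.5 * cfg.gauge_amplitude_cm
        # cos(phase) > 0.5 over a fraction arccos(0.5)/pi of the year
        expected = 365.25 * math.acos(0.5) / math.pi
        got = flood_days(threshold, g, years=(1990, 2004))
        assert got == pytest.approx(expected, abs=1.5)

    def test_minima_decline_planted(self):
        cfg = SimConfig(seed=4)
        g = simulate_gauge(cfg)
        mins = g.annual_stat("min")
        before = mins[mins.index < cfg.breakpoint_year].mean()
        after = mins[(mins.index >= cfg.breakpoint_year) &
                     (mins.index <= cfg.survey_year)].mean()
        assert before - after == pytest.approx(cfg.min_decline_cm, rel=0.25)


class TestPopulation:
    def test_size_and_threshold(self, default_study):
        trees = default_study["trees"]
        cfg = default_study["config"]
        assert len(trees) == cfg.n_trees_population
        assert all(t.dbh_cm >= 15.0 / math.pi for t in trees)

    def test_plots_cover_gradient(self, default_study):
        assert len(default_study["plots"]) == default_study["config"].n_plots

    def test_no_decline_balances_first_class(self):
        """decline_factor 1 removes the planted deficit: recent recruits
        split roughly evenly between categories."""
        cfg = SimConfig(seed=11, decline_factor=1.0)
        gauge = simulate_gauge(cfg)
        counts = {"short": 0, "long": 0}
        for s in range(8):
            trees, plots = simulate_population(cfg.with_seed(100 + s),
                                               gauge=gauge)
            short_ids = {p.plot_id for p in plots[cfg.n_plots // 2:]}
            for t in trees:
                if t.dbh_cm < 13.0:  # young recruits
                    counts["short" if t.plot_id in short_ids else "long"] += 1
        total = counts["short"] + counts["long"]
        assert abs(counts["short"] / total - 0.5) < 0.12

    def test_decline_plants_deficit(self, default_study):
        cfg = default_study["config"]
        trees, plots = default_study["trees"], default_study["plots"]
        short_ids = {p.plot_id for p in plots[cfg.n_plots // 2:]}
        young_short = sum(t.dbh_cm < 13.0 and t.plot_id in short_ids
                          for t in trees)
        young_long = sum(t.dbh_cm < 13.0 and t.plot_id not in short_ids
                         for t in trees)
        assert young_short < 0.5 * young_long


def test_study_bundle_complete(default_study):
    assert set(default_study) >= {"climate", "gauge", "rings", "ring_truth",
                                  "trees", "plots", "config"}
    assert "gauge_level_cm" in default_study["climate"].variables()
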