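import math

import numpy as np
import pandas as pd
import pytest

from floodring.growth_model import GrowthModelFit, dbh_from_age
from floodring.io_formats import ClimateTable, GaugeSeries, TreeRecord
from floodring.population_structure import (DegenerateBreadthError,
                                            apply_inclusion, assign_ages,
                                            cbh_to_dbh, climate_by_age_class,
                                            flood_class_chisq, make_classes,
                                            oneway_f, sturges_k)


class TestCBH:
    def test_division_by_pi(self):
        assert cbh_to_dbh(15.0) == pytest.approx(15.0 / math.pi)
        assert cbh_to_dbh(math.pi * 10) == pytest.approx(10.0)

    def test_threshold_filter(self):
        trees = [TreeRecord("A", "P", dbh_cm=cbh_to_dbh(15.0), cbh_cm=15.0),
                 TreeRecord("B", "P", dbh_cm=cbh_to_dbh(14.9), cbh_cm=14.9)]
        inc, exc = apply_inclusion(trees)
        assert [t.tree_id for t in inc] == ["A"]
        assert [t.tree_id for t in exc] == ["B"]


class TestClassing:
    def test_sturges_rounding(self):
        # N=100: 1 + 3.3 * 2 = 7.6 -> 8
        assert sturges_k(100) == 8
        assert sturges_k(153) == 8

    def test_emulated_stand_first_class(self, rng):
        """N=153 spanning 5.41-97.89 cm gives width 11.56 and a first class
        of 5.41-16.97 cm."""
        vals = np.concatenate([[5.41, 97.89],
                               rng.uniform(5.41, 97.89, size=151)])
        c = make_classes(vals)
        assert c.k == 8
        assert c.width == pytest.approx(11.56, abs=0.005)
        assert c.edges[0] == pytest.approx(5.41)
        assert c.edges[1] == pytest.approx(16.97, abs=0.005)

    def test_forced_single_class(self):
        c = make_classes([1.0, 2.0], k=1)
        assert list(c.counts) == [2]

    def test_partition_property(self, rng):
        for _ in range(20):
            vals = rng.lognormal(mean=2.5, sigma=0.5, size=int(rng.integers(5, 300)))
            c = make_classes(vals)
            assert int(c.counts.sum()) == len(vals)

    def test_degenerate_breadth(self):
        with pytest.raises(DegenerateBreadthError):
            make_classes([7.0, 7.0, 7.0])


class TestAssignAges:
    def test_midpoint_age(self, growth_fit):
        recs = [TreeRecord("A", "P", dbh_cm=30.0),
                TreeRecord("B", "P", dbh_cm=12.0)]
        assign_ages(recs, growth_fit)
        assert recs[0].age_years == pytest.approx(20.0)
        assert recs[1].age_years == pytest.approx(10.0)

    def test_population_round_trip(self, growth_fit, rng):
        ages = rng.uniform(3, 50, size=60)
        recs = [TreeRecord(f"T{i}", "P", dbh_cm=float(dbh_from_age(growth_fit, a)))
                for i, a in enumerate(ages)]
        assign_ages(recs, growth_fit)
        np.testing.assert_allclose([r.age_years for r in recs], ages, rtol=1e-9)

    def test_above_asymptote_flagged(self, growth_fit):
        recs = [TreeRecord("A", "P", dbh_cm=30.0),
                TreeRecord("B", "P", dbh_cm=65.0)]
        assign_ages(recs, growth_fit)
        assert recs[1].age_flagged
        assert recs[1].age_years == recs[0].age_years  # oldest invertible


class TestChiSquare:
    def test_identical_counts_zero(self):
        counts = {"a": np.array([10, 20, 30]), "b": np.array([10, 20, 30])}
        chi2, df, p = flood_class_chisq(counts)
        assert chi2 == pytest.approx(0.0)
        assert df == 2

    def test_hand_computed_2x2(self):
        chi2, df, _ = flood_class_chisq({"a": np.array([10, 20]),
                                         "b": np.array([20, 10])})
        assert chi2 == pytest.approx(20 / 3)
        assert df == 1

    def test_pooling_reduces_df(self):
        counts = {"a": np.array([30, 30, 1]), "b": np.array([30, 30, 0])}
        _, df, _ = flood_class_chisq(counts)
        assert df == 1  # 3 classes pooled to 2

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            t = rng.integers(5, 60, size=(2, int(rng.integers(2, 8)))).astype(float)
            chi2, df, _ = flood_class_chisq({"a": t[0], "b": t[1]})
            exp = np.outer(t.sum(1), t.sum(0)) / t.sum()
            assert chi2 == pytest.approx(((t - exp) ** 2 / exp).sum(), rel=1e-9)


def _flat_gauge(years, level_by_year):
    frames = []
    for y in years:
        d = pd.date_range(f"{y}-01-01", f"{y}-12-31", freq="D")
        frames.append(pd.DataFrame({"date": d, "level_cm": level_by_year(y)}))
    return GaugeSeries(pd.concat(frames, ignore_index=True))


def _flat_climate(years, rng):
    rows = [{"year": y, "month": m, "variable": "precipitation_mm",
             "value": 100.0 + rng.normal(0, 5)}
            for y in years for m in range(1, 13)]
    return ClimateTable(pd.DataFrame(rows))


class TestClimateByAgeClass:
    def _setup(self, rng, shift_class=None, fit=None):
        fit = fit or GrowthModelFit(beta0=80, beta1=20, beta2=1.8)
        ages = rng.uniform(3, 40, size=200)
        dbh = np.asarray(dbh_from_age(fit, ages))
        classing = make_classes(dbh, fit=fit)
        years = range(1950, 2015)
        base = lambda y: 400.0 + rng.normal(0, 3)
        if shift_class is not None:
            lo, hi = classing.age_spans[shift_class]
            span = set(range(2014 - int(round(hi)), 2014 - int(round(lo)) + 1))
            base = lambda y: 400.0 + rng.normal(0, 3) - (60.0 if y in span else 0.0)
        gauge = _flat_gauge(years, base)
        climate = _flat_climate(years, rng)
        return classing, climate, gauge

    def test_identical_distributions_one_group(self, rng):
        classing, climate, gauge = self._setup(rng)
        table = climate_by_age_class(classing, climate, gauge, 2014)
        flood = table[table["variable"] == "flood_max_cm"]
        assert (flood["p"] > 0.05).all()
        assert set(flood["letters"]) == {"a"}

    def test_planted_shift_separated_by_tukey(self, rng):
        classing, climate, gauge = self._setup(rng, shift_class=1)
        table = climate_by_age_class(classing, climate, gauge, 2014)
        flood = table[table["variable"] == "flood_min_cm"]
        assert (flood["p"] < 0.05).all()
        shifted = flood[flood["class"] == "C2"]["letters"].iloc[0]
        others = set(flood[flood["class"] != "C2"]["letters"])
        assert all(shifted != o for o in others)


class TestOnewayF:
    def test_matches_brute_force(self, rng):
        for _ in range(100):
            groups = [rng.normal(size=int(rng.integers(4, 12)))
                      for _ in range(int(rng.integers(3, 6)))]
            f, _ = oneway_f(groups)
            all_ = np.concatenate(groups)
            gm = all_.mean()
            ssb = sum(len(g) * (g.mean() - gm) ** 2 for g in groups)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            dfb, dfw = len(groups) - 1, len(all_) - len(groups)
            assert f == pytest.approx((ssb / dfb) / (ssw / dfw), rel=1e-9)
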