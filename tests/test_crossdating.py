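import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from floodring.crossdating import (CrossdateConfig, DegenerateChronologyError,
                                   InsufficientOverlapError, T_CAP,
                                   UndefinedStatisticError, best_lag,
                                   bp_transform, crossdate_set,
                                   estimate_missing_rings, glk, t_from_r,
                                   t_value_bp)
from floodring.io_formats import RingSeries


def brute_glk(x, y):
    """Independent enumeration of the sign-agreement score."""
    total = 0.0
    for i in range(1, len(x)):
        dx, dy = float(x[i] - x[i - 1]), float(y[i] - y[i - 1])
        sx = int(dx > 0) - int(dx < 0)
        sy = int(dy > 0) - int(dy < 0)
        if sx == sy:
            total += 1.0
        elif sx == 0 or sy == 0:
            total += 0.5
    return 100.0 * total / (len(x) - 1)


class TestGLK:
    @pytest.mark.parametrize("x, y, expected", [
        ([1, 2, 3, 4], [2, 3, 4, 5], 100.0),   # identical movement
        ([1, 2, 1, 2], [2, 1, 2, 1], 0.0),     # strictly opposite
        ([1, 2, 2], [1, 2, 3], 75.0),          # one-sided tie scores 1/2
    ])
    def test_boundary_cases(self, x, y, expected):
        assert glk(x, y) == pytest.approx(expected)

    def test_self_agreement_and_symmetry(self, rng):
        x = rng.lognormal(size=30)
        y = rng.lognormal(size=30)
        assert glk(x, x) == 100.0
        assert glk(x, y) == glk(y, x)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(1, 1000), min_size=2, max_size=40),
           st.data())
    def test_monotone_transform_invariance_and_oracle(self, x, data):
        # coarse 0.1-spaced grid keeps movement directions numerically exact
        y = data.draw(st.lists(st.integers(1, 1000),
                               min_size=len(x), max_size=len(x)))
        x, y = np.array(x) / 10.0, np.array(y) / 10.0
        assert glk(x, y) == pytest.approx(brute_glk(x, y))
        # strictly increasing transform preserves all movement directions
        assert glk(np.exp(0.1 * x), np.exp(0.1 * y)) == pytest.approx(glk(x, y))

    def test_overlap_too_short(self):
        with pytest.raises(InsufficientOverlapError):
            glk([1.0], [2.0])


class TestTValue:
    def test_zero_correlation_gives_zero(self, rng):
        assert t_from_r(0.0, 20) == 0.0

    def test_closed_form_value(self):
        # r = 0.5, n = 27: t = 0.5 sqrt(25 / 0.75)
        assert t_from_r(0.5, 27) == pytest.approx(2.8868, abs=1e-4)

    def test_perfect_correlation_capped(self, rng):
        x = bp_transform(rng.lognormal(size=30))
        assert t_value_bp(x, x) == T_CAP

    def test_zero_variance_errors(self):
        with pytest.raises(UndefinedStatisticError):
            t_value_bp(np.zeros(10), np.arange(10.0))

    def test_matches_brute_force_pearson(self, rng):
        """t equals the Pearson-then-closed-form computation (oracle)."""
        for _ in range(200):
            n = int(rng.integers(4, 30))
            x, y = rng.normal(size=n), rng.normal(size=n)
            mx, my = x - x.mean(), y - y.mean()
            r = float((mx * my).sum() /
                      np.sqrt((mx**2).sum() * (my**2).sum()))
            expected = r * np.sqrt((n - 2) / (1 - r * r))
            assert t_value_bp(x, y) == pytest.approx(expected, rel=1e-9)


class TestBestLag:
    def _series(self, widths, first_year, sid="A"):
        return RingSeries(sid, sid, first_year, list(widths))

    def test_planted_shift_recovered(self, rng):
        w = rng.lognormal(sigma=0.4, size=40)
        a = self._series(w, 1980, "A")
        b = self._series(w, 1977, "B")  # dated 3 years too early
        lag, report = best_lag(a, b, max_shift=5)
        assert lag == 3
        assert report.glk_percent == 100.0

    def test_identity_gives_zero_lag(self, rng):
        w = rng.lognormal(sigma=0.4, size=40)
        a = self._series(w, 1980, "A")
        lag, _ = best_lag(a, self._series(w, 1980, "B"), max_shift=5)
        assert lag == 0

    def test_antisymmetric_on_noiseless_shifts(self, rng):
        w = rng.lognormal(sigma=0.4, size=50)
        a = self._series(w, 1980, "A")
        b = self._series(w, 1976, "B")
        assert best_lag(a, b, 6)[0] == -best_lag(b, a, 6)[0]

    def test_noisy_offset_recovered(self, rng):
        """A 10%-noise copy misdated by 2 years is re-dated correctly."""
        w = rng.lognormal(sigma=0.5, size=45)
        noisy = w * rng.lognormal(sigma=0.1, size=45)
        a = self._series(w, 1980, "A")
        b = self._series(noisy, 1982, "B")  # dated 2 years too late
        lag, _ = best_lag(a, b, max_shift=4)
        assert lag == -2

    def test_no_overlap_errors(self):
        a = self._series([1, 2, 3] * 5, 1900)
        b = self._series([1, 2, 3] * 5, 2000, "B")
        with pytest.raises(InsufficientOverlapError):
            best_lag(a, b, max_shift=3)


class TestMissingRings:
    @pytest.mark.parametrize("distance, widths, expected", [
        (10.0, [2, 2, 2, 2, 2], 5),        # 10 / 2
        (0.0, [1, 1, 1, 1, 1], 0),
        (7.0, [1, 2, 3, 2, 2], 4),         # round(7 / 2) = 4 half-up
    ])
    def test_examples(self, distance, widths, expected, make_series):
        s = make_series(widths)
        assert estimate_missing_rings(s, distance) == expected

    def test_negative_distance(self, make_series):
        with pytest.raises(ValueError):
            estimate_missing_rings(make_series([1, 2]), -1.0)


class TestCrossdateSet:
    def _coherent_set(self, rng, n=10, years=34, noise=0.15):
        signal = rng.normal(size=years)
        out = []
        for i in range(n):
            w = np.exp(0.4 * signal + rng.normal(0, noise, size=years)) * 2.0
            out.append(RingSeries(f"S{i}", f"S{i}", 1981, list(w)))
        return out

    def test_strong_common_signal_all_admitted(self, rng):
        series = self._coherent_set(rng)
        admitted, reports = crossdate_set(series)
        assert len(admitted) == len(series)
        assert all(r.admitted for r in reports)

    def test_pure_noise_series_rejected(self, rng):
        series = self._coherent_set(rng, n=9)
        noise = RingSeries("NOISE", "NOISE", 1981,
                           list(rng.lognormal(sigma=0.4, size=34) * 2))
        admitted, _ = crossdate_set(series + [noise])
        ids = {s.series_id for s in admitted}
        assert "NOISE" not in ids
        assert ids == {s.series_id for s in series}

    def test_two_identical_series_admitted(self, rng):
        w = list(rng.lognormal(sigma=0.4, size=30) + 0.5)
        pair = [RingSeries("A", "A", 1980, w), RingSeries("B", "B", 1980, w)]
        admitted, reports = crossdate_set(pair)
        assert len(admitted) == 2
        assert reports[0].glk_percent == 100.0

    def test_single_series_is_degenerate(self, make_series):
        with pytest.raises(DegenerateChronologyError):
            crossdate_set([make_series([1, 2, 3])])
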