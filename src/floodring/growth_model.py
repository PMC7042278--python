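"""Sigmoidal age-diameter growth model and the diameter-height model.

The cumulative diameter curve of each tree (twice the running sum of its ring
widths, proportionally rescaled to the field DBH) yields (cambial age, DBH)
points; their per-age mean curve is fitted to the three-parameter sigmoid

    DBH(age) = beta0 / (1 + (beta1/age)^beta2)

where beta0 is the asymptotic DBH (cm), beta1 the age at half the asymptote
(years) and beta2 a dimensionless shape exponent.  The model inverts in
closed form, age = beta1 / (beta0/DBH - 1)^(1/beta2), which is how ages are
assigned to inventoried trees.  Tree height follows the saturating hyperbola
H = a DBH / (b + DBH).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io_formats import RingSeries


class FitError(RuntimeError):
    """Nonlinear fit failed or the input is degenerate."""


class DomainError(ValueError):
    """Argument outside the model's valid domain."""


@dataclass
class GrowthModelFit:
    beta0: float  # asymptotic DBH, cm
    beta1: float  # age at half-asymptote, years
    beta2: float  # shape exponent
    r2: float = float("nan")
    residual_sd: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.beta0, self.beta1, self.beta2) <= 0:
            raise ValueError("beta0, beta1, beta2 must all be > 0")


@dataclass
class HeightModelFit:
    a: float   # asymptotic height, m
    b: float   # half-saturation DBH, cm
    r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be > 0")

    def predict(self, dbh_cm) -> np.ndarray:
        d = np.asarray(dbh_cm, dtype=float)
        return self.a * d / (self.b + d)


# ---------------------------------------------------------------------------
# forward / inverse evaluation
# ---------------------------------------------------------------------------

def dbh_from_age(fit: GrowthModelFit, age) -> np.ndarray | float:
    """Evaluate the sigmoid: DBH = beta0 / (1 + (beta1/age)^beta2)."""
    a = np.asarray(age, dtype=float)
    if np.any(a <= 0):
        raise DomainError("age must be > 0")
    out = fit.beta0 / (1.0 + (fit.beta1 / a) ** fit.beta2)
    return float(out) if np.isscalar(age) else out


def age_from_dbh(fit: GrowthModelFit, dbh) -> np.ndarray | float:
    """Closed-form inversion: age = beta1 / (beta0/dbh - 1)^(1/beta2).

    Defined for 0 < dbh < beta0; at or above the asymptote the age is
    undefined and a :class:`DomainError` is raised.
    """
    d = np.asarray(dbh, dtype=float)
    if np.any(d <= 0) or np.any(d >= fit.beta0):
        raise DomainError("dbh must lie strictly between 0 and beta0")
    out = fit.beta1 / (fit.beta0 / d - 1.0) ** (1.0 / fit.beta2)
    return float(out) if np.isscalar(dbh) else out


def cumulative_curve(series: RingSeries, field_dbh_cm: float
                     ) -> np.ndarray:
    """(cambial age, cumulative DBH cm) pairs for one tree.

    Cumulative diameter is twice the running sum of radial widths (mm -> cm),
    proportionally rescaled so the final value equals the field DBH — the
    multiplicative correction absorbs bark thickness and off-centre pith bias.
    Ages are offset by the series' pith_offset.
    """
    if field_dbh_cm <= 0:
        raise DomainError("field DBH must be > 0")
    widths_cm = np.asarray(series.widths, dtype=float) / 10.0
    cum = 2.0 * np.cumsum(widths_cm)
    scale = field_dbh_cm / cum[-1]
    ages = np.arange(1, len(cum) + 1) + series.pith_offset
    return np.column_stack([ages, cum * scale])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _sigmoid(age, b0, b1, b2):
    return b0 / (1.0 + (b1 / age) ** b2)


def fit_sigmoidal(points: np.ndarray, per_age_mean: bool = True,
                  maxfev: int = 10000, xtol: float = 1e-10) -> GrowthModelFit:
    """Nonlinear least-squares fit of the sigmoid to pooled (age, DBH) points.

    By default the points are first collapsed to the mean diameter growth
    curve (per-age mean DBH across trees) and the sigmoid fitted to that
    curve; ``per_age_mean=False`` fits the pooled points directly.
    Initialization: beta0 <- 1.2 x max DBH, beta1 <- age whose mean DBH is
    nearest half of that, beta2 <- 1.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (age, dbh)")
    ages_all, dbh_all = pts[:, 0], pts[:, 1]
    if len(np.unique(ages_all)) < 3:
        raise FitError("need at least 3 distinct ages")
    if np.ptp(dbh_all) == 0 or np.ptp(ages_all) == 0:
        raise FitError("degenerate input: no variation in age or DBH")

    if per_age_mean:
        uniq = np.unique(ages_all)
        mean_dbh = np.array([dbh_all[ages_all == a].mean() for a in uniq])
        x, y = uniq, mean_dbh
    else:
        x, y = ages_all, dbh_all

    b0_init = 1.2 * y.max()
    b1_init = float(x[np.argmin(np.abs(y - b0_init / 2.0))])
    b1_init = max(b1_init, 1e-3)
    p0 = [b0_init, b1_init, 1.0]
    try:
        popt, _ = curve_fit(_sigmoid, x, y, p0=p0, maxfev=maxfev, xtol=xtol,
                            bounds=([1e-6, 1e-6, 1e-6], [np.inf, np.inf, np.inf]))
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"sigmoidal fit did not converge: {exc}") from exc

    resid = y - _sigmoid(x, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    dof = max(len(y) - 3, 1)
    return GrowthModelFit(beta0=float(popt[0]), beta1=float(popt[1]),
                          beta2=float(popt[2]), r2=r2,
                          residual_sd=float(np.sqrt(ss_res / dof)))


def increment_curve(fit: GrowthModelFit, age_max: float | None = None,
                    step: float = 0.01) -> tuple[float, float, bool]:
    """Age and value of the maximum annual diameter increment.

    Maximizes the analytic derivative dDBH/dage on an age grid of the given
    step, tie-broken to the smallest age.  Returns (age, increment cm/yr,
    at_boundary); for beta2 <= 1 the increment decreases monotonically and
    the maximum sits at the grid's lower boundary, flagged via at_boundary.
    """
    if age_max is None:
        age_max = 5.0 * fit.beta1
    ages = np.arange(step, age_max + step / 2, step)
    u = (fit.beta1 / ages) ** fit.beta2
    deriv = fit.beta0 * fit.beta2 * u / (ages * (1.0 + u) ** 2)
    i = int(np.argmax(deriv))  # np.argmax returns the first (smallest-age) max
    at_boundary = i == 0 or i == len(ages) - 1
    return float(ages[i]), float(deriv[i]), at_boundary


def fit_height_model(records, maxfev: int = 10000) -> HeightModelFit:
    """Fit H = a DBH / (b + DBH) to inventory records carrying heights."""
    pts = [(t.dbh_cm, t.height_m) for t in records if t.height_m is not None]
    if len(pts) < 3:
        raise FitError("need at least 3 records with height")
    d = np.array([p[0] for p in pts])
    h = np.array([p[1] for p in pts])
    if np.ptp(d) == 0:
        raise FitError("degenerate input: a single DBH value")

    def hyper(x, a, b):
        return a * x / (b + x)

    p0 = [1.2 * h.max(), float(np.median(d))]
    try:
        popt, _ = curve_fit(hyper, d, h, p0=p0, maxfev=maxfev,
                            bounds=([1e-6, 1e-6], [np.inf, np.inf]))
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"height fit did not converge: {exc}") from exc
    resid = h - hyper(d, *popt)
    ss_tot = float(np.sum((h - h.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return HeightModelFit(a=float(popt[0]), b=float(popt[1]), r2=r2)
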