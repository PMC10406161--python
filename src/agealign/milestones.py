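"""Time points from gradual change: growth milestones, peaks, attainment.

Gradual traits (body or brain volume, time spent riding the mother,
ossified carpal counts, birth seasonality) do not come with an intrinsic
event age.  Three extractors mint one:

* percent-of-adult milestones from a sigmoidal growth fit (the age at
  which the fitted curve reaches, say, 90% of its asymptote);
* peak ages from a smoothing-spline fit (e.g. age of peak births);
* attainment ages for integer count series (first age at which a
  monotone fit reaches the adult count).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize
from scipy.interpolate import PchipInterpolator, make_smoothing_spline
from sklearn.isotonic import IsotonicRegression

from .synthetic import gompertz_curve, logistic_curve

#: pct=100 is operationalized as reaching (1 - ASYMPTOTE_TOL) x asymptote,
#: because sigmoids approach their asymptote only in the limit.
ASYMPTOTE_TOL = 0.01


@dataclass
class GrowthFit:
    """One fitted growth family with its least-squares diagnostics."""

    family: str  # logistic | gompertz | monotone_spline | constant
    params: dict[str, float]
    asymptote: float
    rss: float
    aic: float
    predict: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float]
    warnings: list[str] = field(default_factory=list)
    degenerate: bool = False


def _aic(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k


def _fit_parametric(ages, values, family: str) -> GrowthFit | None:
    curve = logistic_curve if family == "logistic" else gompertz_curve
    a0 = float(values.max())
    t0 = float(np.median(ages))
    span = float(ages.max() - ages.min()) or 1.0
    k0 = 4.0 / span
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                curve,
                ages,
                values,
                p0=[a0, k0, t0],
                bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
    except (RuntimeError, ValueError):
        return None
    resid = values - curve(ages, *popt)
    rss = float(resid @ resid)
    return GrowthFit(
        family=family,
        params={"asymptote": float(popt[0]), "rate": float(popt[1]), "inflection": float(popt[2])},
        asymptote=float(popt[0]),
        rss=rss,
        aic=_aic(rss, len(ages), 3),
        predict=lambda t, p=popt: curve(t, *p),
        domain=(float(ages.min()), float(ages.max())),
    )


def _fit_monotone_spline(ages, values, notes: list[str]) -> GrowthFit:
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(ages, values)
    # collapse ties so PCHIP gets strictly increasing knots
    uniq_ages, idx = np.unique(ages, return_inverse=True)
    uniq_fit = np.array([fitted[idx == i].mean() for i in range(len(uniq_ages))])
    if len(uniq_ages) >= 2:
        interp = PchipInterpolator(uniq_ages, uniq_fit, extrapolate=False)

        def predict(t, lo=uniq_ages[0], hi=uniq_ages[-1], f=interp, ylo=uniq_fit[0], yhi=uniq_fit[-1]):
            t = np.asarray(t, dtype=float)
            return np.where(t <= lo, ylo, np.where(t >= hi, yhi, f(np.clip(t, lo, hi))))

    else:  # pragma: no cover - blocked by the >=6 points precondition
        def predict(t):
            return np.full_like(np.asarray(t, dtype=float), uniq_fit[0])

    resid = values - predict(ages)
    rss = float(resid @ resid)
    return GrowthFit(
        family="monotone_spline",
        params={},
        asymptote=float(uniq_fit[-1]),
        rss=rss,
        aic=_aic(rss, len(ages), len(uniq_ages)),
        predict=predict,
        domain=(float(ages.min()), float(ages.max())),
        warnings=notes,
    )


def fit_growth(
    ages: np.ndarray,
    values: np.ndarray,
    families: tuple[str, ...] = ("logistic", "gompertz"),
) -> GrowthFit:
    """Least-squares growth fit; the lowest-AIC family wins.

    Falls back to an isotonic-regression + PCHIP monotone spline when no
    parametric family converges or when the series is not increasing
    overall (with a warning either way).  A constant series yields a
    degenerate fit whose asymptote is the constant.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(ages) < 6:
        raise ValueError("need at least 6 points to fit growth")
    if (ages <= 0).any():
        raise ValueError("ages must be positive")
    order = np.argsort(ages, kind="stable")
    ages, values = ages[order], values[order]

    if np.ptp(values) == 0:
        return GrowthFit(
            family="constant",
            params={"asymptote": float(values[0])},
            asymptote=float(values[0]),
            rss=0.0,
            aic=-math.inf,
            predict=lambda t, v=float(values[0]): np.full_like(np.asarray(t, dtype=float), v),
            domain=(float(ages.min()), float(ages.max())),
            warnings=["constant series: rate is undefined"],
            degenerate=True,
        )

    if values[-1] < values[0]:
        msg = "series decreases overall; growth families skipped, monotone spline used"
        warnings.warn(msg, stacklevel=2)
        return _fit_monotone_spline(ages, values, [msg])

    fits = [f for fam in families if (f := _fit_parametric(ages, values, fam)) is not None]
    if not fits:
        msg = "no parametric growth family converged; monotone spline fallback"
        warnings.warn(msg, stacklevel=2)
        return _fit_monotone_spline(ages, values, [msg])
    return min(fits, key=lambda f: f.aic)


def milestone_age(fit: GrowthFit, pct: float) -> float:
    """Age at which the fitted curve reaches pct% of its adult asymptote.

    pct=100 uses (1 - 0.01) x asymptote.  Closed forms for the logistic
    and Gompertz families; a bracketing root search otherwise.
    """
    if not 0 < pct <= 100:
        raise ValueError("pct must lie in (0, 100]")
    frac = (1.0 - ASYMPTOTE_TOL) if pct == 100 else pct / 100.0
    target = frac * fit.asymptote

    if fit.family == "logistic":
        a, k, t0 = fit.params["asymptote"], fit.params["rate"], fit.params["inflection"]
        # a / (1 + exp(-k (t - t0))) = target
        return t0 - math.log(a / target - 1.0) / k if target < a else math.inf
    if fit.family == "gompertz":
        a, k, t0 = fit.params["asymptote"], fit.params["rate"], fit.params["inflection"]
        if not 0 < target < a:
            raise ValueError("threshold outside the Gompertz range")
        return t0 - math.log(-math.log(target / a)) / k
    if fit.family == "constant":
        return fit.domain[0]  # already at its asymptote everywhere

    lo, hi = fit.domain
    grid = np.linspace(lo, hi, 2001)
    vals = np.asarray(fit.predict(grid), dtype=float)
    above = vals >= target
    if not above.any():
        raise ValueError(
            f"curve never reaches {pct}% of asymptote within the observed ages"
        )
    i = int(np.argmax(above))
    if i == 0:
        return float(grid[0])
    f = lambda t: float(fit.predict(np.array([t]))[0]) - target
    return float(optimize.brentq(f, grid[i - 1], grid[i]))


@dataclass
class PeakAge:
    age: float
    value: float
    censored: bool  # peak at the domain boundary: the true peak may lie outside


def peak_age(
    ages: np.ndarray, values: np.ndarray, smoothing: float | None = None
) -> PeakAge:
    """Age of the maximum of a smoothing-spline fit.

    ``smoothing`` is the spline's penalty parameter; when None it is
    chosen by generalized cross-validation.  A maximum at the first or
    last observed age is flagged censored.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(ages) < 5:
        raise ValueError("need at least 5 points")
    order = np.argsort(ages, kind="stable")
    ages, values = ages[order], values[order]
    uniq, idx = np.unique(ages, return_inverse=True)
    vals = np.array([values[idx == i].mean() for i in range(len(uniq))])
    if len(uniq) < 5:
        raise ValueError("need at least 5 distinct ages")
    spline = make_smoothing_spline(uniq, vals, lam=smoothing)
    grid = np.linspace(uniq[0], uniq[-1], 4001)
    fitted = spline(grid)
    i = int(np.argmax(fitted))
    censored = i in (0, len(grid) - 1)
    return PeakAge(age=float(grid[i]), value=float(fitted[i]), censored=censored)


def attainment_age(
    ages: np.ndarray, counts: np.ndarray, adult_value: float
) -> float:
    """First age at which a monotone fit of a count series reaches adult level.

    Counts are fitted by isotonic regression (a non-decreasing step
    function); the attainment threshold is adult_value - 0.5, since
    integer counts round to the adult value from there on.  The answer
    is the first observed age whose fitted value clears the threshold --
    a step up between two sampling ages is dated to the age at which it
    is first seen, not interpolated backwards into the gap, so a clean
    0 -> adult step at age a returns exactly a.  If the fitted curve
    never reaches the threshold inside the observed age range the
    extrapolation is refused.
    """
    ages = np.asarray(ages, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    if adult_value <= 0:
        raise ValueError("adult_value must be positive")
    order = np.argsort(ages, kind="stable")
    ages, counts = ages[order], counts[order]
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(ages, counts)
    uniq, idx = np.unique(ages, return_inverse=True)
    fit_u = np.array([fitted[idx == i].mean() for i in range(len(uniq))])
    thr = adult_value - 0.5
    reached = fit_u >= thr
    if not reached.any():
        raise ValueError(
            f"adult value {adult_value} not reached within the observed ages "
            f"(fitted maximum {fit_u.max():.2f}); refusing to extrapolate"
        )
    return float(uniq[int(np.argmax(reached))])
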