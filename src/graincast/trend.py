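"""Trend regression of yield on ordinal year.

Five classical trendline families are supported — linear, logarithmic,
second-degree polynomial, exponential and power — fitted by least squares on
the scale on which each family is linear (log scale for exponential/power,
spreadsheet-trendline style).  The ordinal predictor is x = year - origin + 1,
so the first fitted year maps to x = 1.  R-squared is reported on the
estimation scale and used for form selection; RMSE is always on the original
kg/ha scale so it is comparable with the ARIMA candidates.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .series import YieldSeries

TREND_FORMS = ("linear", "logarithmic", "polynomial2", "exponential", "power")

_NPARAMS = {
    "linear": 2,
    "logarithmic": 2,
    "polynomial2": 3,
    "exponential": 2,
    "power": 2,
}

__all__ = ["TREND_FORMS", "FittingError", "TrendResults", "TrendModel",
           "fit_trend", "select_trend", "extrapolate"]


class FittingError(RuntimeError):
    """Raised for singular or otherwise unfittable designs."""


def _eval_form(form: str, params: Sequence[float], x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if form == "linear":
        b0, b1 = params
        return b0 + b1 * x
    if form == "logarithmic":
        b0, b1 = params
        return b0 + b1 * np.log(x)
    if form == "polynomial2":
        b0, b1, b2 = params
        return b0 + b1 * x + b2 * x * x
    if form == "exponential":
        b0, b1 = params
        return b0 * np.exp(b1 * x)
    if form == "power":
        b0, b1 = params
        return b0 * np.power(x, b1)
    raise ValueError(f"unknown trend form {form!r}")


def _equation_text(form: str, params: Sequence[float]) -> str:
    p = [float(v) for v in params]
    if form == "linear":
        return f"y = {p[1]:.6g}x + {p[0]:.6g}"
    if form == "logarithmic":
        return f"y = {p[1]:.6g}ln(x) + {p[0]:.6g}"
    if form == "polynomial2":
        return f"y = {p[2]:.6g}x^2 + {p[1]:.6g}x + {p[0]:.6g}"
    if form == "exponential":
        return f"y = {p[0]:.6g}e^({p[1]:.6g}x)"
    if form == "power":
        return f"y = {p[0]:.6g}x^{p[1]:.6g}"
    raise ValueError(form)


@dataclass(frozen=True)
class TrendResults:
    """A fitted (or externally supplied) trend form on ordinal years."""

    form: str
    params: tuple[float, ...]
    origin: int                      # calendar year mapped to x = 1
    rsquared: float = float("nan")   # on the estimation scale
    rmse: float = float("nan")       # kg/ha, original scale, fitting window
    fitting_window: tuple[int, int] | None = None
    nobs: int = 0

    @property
    def nparams(self) -> int:
        return len(self.params)

    def ordinal(self, years: Iterable[int] | int) -> np.ndarray:
        return np.asarray(years, dtype=float) - self.origin + 1

    def predict(self, years: Iterable[int]) -> dict[int, float]:
        """Evaluate the fitted form at calendar ``years`` (kg/ha)."""
        years = [int(y) for y in np.atleast_1d(years)]
        vals = _eval_form(self.form, self.params, self.ordinal(years))
        return dict(zip(years, (float(v) for v in np.atleast_1d(vals))))

    def equation(self) -> str:
        return _equation_text(self.form, self.params)

    def summary(self) -> str:
        win = f"{self.fitting_window[0]}-{self.fitting_window[1]}" if self.fitting_window else "n/a"
        return (
            f"Trend regression [{self.form}]  window {win}  (x=1 at {self.origin})\n"
            f"  {self.equation()}\n"
            f"  R^2 = {self.rsquared:.4f}   RMSE = {self.rmse:.4f} kg/ha   n = {self.nobs}"
        )

    @classmethod
    def from_params(cls, form, params, origin=1961, rmse=float("nan"),
                    rsquared=float("nan"), fitting_window=None) -> "TrendResults":
        """Build results from known coefficients (e.g. a published equation)."""
        return cls(form=form, params=tuple(float(p) for p in params), origin=origin,
                   rsquared=rsquared, rmse=rmse, fitting_window=fitting_window)


class TrendModel:
    """Least-squares trend model of yields on ordinal year.

    Parameters
    ----------
    y : array-like of yields (kg/ha), parallel to ``years``
    years : calendar years
    form : one of TREND_FORMS
    origin : calendar year mapped to x = 1 (defaults to the first year)
    """

    def __init__(self, y, years, form: str = "polynomial2", origin: int | None = None):
        if form not in TREND_FORMS:
            raise ValueError(f"unknown trend form {form!r}")
        self.y = np.asarray(y, dtype=float)
        self.years = np.asarray(years, dtype=int)
        if self.y.shape != self.years.shape:
            raise ValueError("y and years must be parallel")
        if self.y.size < 4:
            raise FittingError("trend fitting needs at least 4 points")
        self.form = form
        self.origin = int(origin) if origin is not None else int(self.years.min())

    @classmethod
    def from_series(cls, series: YieldSeries, form: str = "polynomial2",
                    window: tuple[int, int] | None = None,
                    origin: int | None = None) -> "TrendModel":
        if window is not None:
            series = series.window(*window)
        ys = series.years
        return cls([series.values[y] for y in ys], ys, form=form, origin=origin)

    def fit(self) -> TrendResults:
        x = self.years.astype(float) - self.origin + 1
        if np.ptp(x) == 0:
            raise FittingError("constant ordinal predictor: singular design")
        y = self.y
        form = self.form
        log_target = form in ("exponential", "power")
        if log_target and np.any(y <= 0):
            raise FittingError(f"{form} trend requires positive yields")
        target = np.log(y) if log_target else y
        if form in ("linear", "exponential"):
            X = sm.add_constant(x)
        elif form in ("logarithmic", "power"):
            X = sm.add_constant(np.log(x))
        else:  # polynomial2
            X = sm.add_constant(np.column_stack([x, x * x]))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise FittingError(f"singular design for {form} trend")
        res = sm.OLS(target, X).fit()
        beta = np.asarray(res.params, dtype=float)
        if form in ("exponential", "power"):
            params = (float(np.exp(beta[0])), float(beta[1]))
        else:
            params = tuple(float(b) for b in beta)
        fitted = _eval_form(form, params, x)
        rmse = float(np.sqrt(np.mean((y - fitted) ** 2)))
        r2 = float(res.rsquared)
        if not np.isfinite(r2):  # constant target: no explainable variance
            r2 = 0.0
        return TrendResults(
            form=form,
            params=params,
            origin=self.origin,
            rsquared=min(max(r2, 0.0), 1.0),
            rmse=rmse,
            fitting_window=(int(self.years.min()), int(self.years.max())),
            nobs=int(y.size),
        )


def fit_trend(series: YieldSeries, form: str,
              window: tuple[int, int] | None = None) -> TrendResults:
    """Fit one trend form to a yield series over ``window`` (calendar years)."""
    return TrendModel.from_series(series, form=form, window=window).fit()


def select_trend(series_or_y, years=None,
                 window: tuple[int, int] | None = None,
                 forms: Sequence[str] = TREND_FORMS) -> TrendResults:
    """Fit every trend family and return the one with maximal R-squared.

    Exact R-squared ties are broken toward the form with fewer parameters
    (then by family order), so a noiseless linear series selects the linear
    form even though the quadratic interpolates it equally well.
    """
    if isinstance(series_or_y, YieldSeries):
        models = [TrendModel.from_series(series_or_y, form=f, window=window) for f in forms]
    else:
        models = [TrendModel(series_or_y, years, form=f) for f in forms]
    fits, errors = [], []
    for m in models:
        try:
            fits.append(m.fit())
        except FittingError as e:
            errors.append(str(e))
    if not fits:
        raise FittingError("no trend form could be fitted: " + "; ".join(errors))
    return max(fits, key=lambda f: (f.rsquared, -f.nparams))


def extrapolate(fit: TrendResults, years: Iterable[int]) -> dict[int, float]:
    """Evaluate a fitted trend at future calendar years (x = year - origin + 1)."""
    years = [int(y) for y in np.atleast_1d(years)]
    bad = [y for y in years if y < fit.origin]
    if bad:
        raise ValueError(f"years before the ordinal origin {fit.origin}: {bad}")
    return fit.predict(years)
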