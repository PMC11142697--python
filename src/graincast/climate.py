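"""Climate-response curve estimation and the 'Carbon Peak' arithmetic.

Eleven classical unary regression forms are fitted to (x, y) pairs —
typically x = global mean temperature (deg C) or annual land precipitation
(mm), y = a crop yield (kg/ha) — with each form estimated by ordinary least
squares on the scale on which it is linear:

    linear       y = b0 + b1 x
    logarithmic  y = b0 + b1 ln x
    inverse      y = b0 + b1 / x
    quadratic    y = b0 + b1 x + b2 x^2
    cubic        y = b0 + b1 x + b2 x^2 + b3 x^3
    compound     y = b0 b1^x              (log scale)
    power        y = b0 x^b1              (log scale)
    s            y = exp(b0 + b1 / x)     (log scale)
    growth       y = exp(b0 + b1 x)       (log scale)
    exponential  y = b0 exp(b1 x)         (log scale)
    logistic     y = 1 / (1/u + b0 b1^x)  (estimated on ln(1/y - 1/u))

R-squared, the overall F statistic and its p-value are reported on the
estimation scale.  Forms are ranked by R-squared, with F as the tie-breaker
and a parsimony rule for near-identical fits.  The module also provides the
quadratic temperature-trend prediction for a target year and the Paris
Agreement 'Carbon Peak' warming-retardation arithmetic.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from . import reference
from ._util import round_half_up
from .series import ClimateSeries
from .trend import TREND_FORMS, TrendModel

CURVE_FORMS = ("linear", "logarithmic", "inverse", "quadratic", "cubic",
               "compound", "power", "s", "growth", "exponential", "logistic")

#: forms estimated with a log-transformed response
_LOG_TARGET = frozenset({"compound", "power", "s", "growth", "exponential"})
#: forms whose predictor transform needs x > 0
_NEEDS_POSITIVE_X = frozenset({"logarithmic", "inverse", "power", "s"})

_NREGRESSORS = {"linear": 1, "logarithmic": 1, "inverse": 1, "quadratic": 2,
                "cubic": 3, "compound": 1, "power": 1, "s": 1, "growth": 1,
                "exponential": 1, "logistic": 1}

#: ranking treats R-squared differences below this as ties (parsimony rule)
RSQ_TIE_TOL = 1e-6

__all__ = ["CURVE_FORMS", "CurveModel", "CurveResults", "fit_curve",
           "scan_curves", "predict_temperature_trend", "TemperatureTrend",
           "CarbonPeakParams", "carbon_peak_retardation", "ceiling_temperature"]


@dataclass(frozen=True)
class CurveResults:
    """One fitted curve-estimation form."""

    form: str
    params: tuple[float, ...]     # (b0, b1[, b2[, b3]]) in the classical parameterization
    rsquared: float
    fvalue: float
    f_pvalue: float
    nobs: int
    upper: float | None = None    # logistic upper bound u

    @property
    def nparams(self) -> int:
        return len(self.params) + (1 if self.form == "logistic" else 0)

    @property
    def df_model(self) -> int:
        return _NREGRESSORS[self.form]

    @property
    def df_resid(self) -> int:
        return self.nobs - self.df_model - 1

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        f, p = self.form, self.params
        if f == "linear":
            return p[0] + p[1] * x
        if f == "logarithmic":
            return p[0] + p[1] * np.log(x)
        if f == "inverse":
            return p[0] + p[1] / x
        if f == "quadratic":
            return p[0] + p[1] * x + p[2] * x ** 2
        if f == "cubic":
            return p[0] + p[1] * x + p[2] * x ** 2 + p[3] * x ** 3
        if f == "compound":
            return p[0] * np.power(p[1], x)
        if f == "power":
            return p[0] * np.power(x, p[1])
        if f == "s":
            return np.exp(p[0] + p[1] / x)
        if f == "growth":
            return np.exp(p[0] + p[1] * x)
        if f == "exponential":
            return p[0] * np.exp(p[1] * x)
        if f == "logistic":
            return 1.0 / (1.0 / self.upper + p[0] * np.power(p[1], x))
        raise ValueError(f)

    def summary(self) -> str:
        coefs = "  ".join(f"b{i}={v:.6g}" for i, v in enumerate(self.params))
        stars = ("***" if self.f_pvalue < 0.001 else "**" if self.f_pvalue < 0.01
                 else "*" if self.f_pvalue < 0.05 else "")
        return (f"{self.form:<12} R^2={self.rsquared:.3f}  F={self.fvalue:.3f}"
                f"  p={self.f_pvalue:.3g}{stars}  {coefs}  n={self.nobs}")


class CurveModel:
    """One unary curve-estimation form fitted by least squares.

    Multiplicative forms are estimated on the log scale; the logistic form on
    ln(1/y - 1/u) with ``u`` finite (default 1.1 x max(y))."""

    def __init__(self, y, x, form: str, logistic_upper: float | None = None):
        if form not in CURVE_FORMS:
            raise ValueError(f"unknown curve form {form!r}")
        self.y = np.asarray(y, dtype=float)
        self.x = np.asarray(x, dtype=float)
        if self.y.shape != self.x.shape:
            raise ValueError("x and y must be parallel")
        self.form = form
        n, k = self.y.size, _NREGRESSORS[form]
        if n < k + 2:
            raise ValueError(f"{form}: needs at least {k + 2} observations, got {n}")
        if form in _NEEDS_POSITIVE_X and np.any(self.x <= 0):
            raise ValueError(f"{form}: requires strictly positive x")
        if form in _LOG_TARGET and np.any(self.y <= 0):
            raise ValueError(f"{form}: requires strictly positive y")
        if form == "logistic":
            if np.any(self.y <= 0):
                raise ValueError("logistic: requires strictly positive y")
            self.upper = float(logistic_upper) if logistic_upper is not None \
                else 1.1 * float(self.y.max())
            if np.any(self.y >= self.upper):
                raise ValueError("logistic: upper bound must exceed every y")
        else:
            self.upper = None

    def _design(self):
        x, y, f = self.x, self.y, self.form
        if f in ("linear", "quadratic", "cubic"):
            deg = {"linear": 1, "quadratic": 2, "cubic": 3}[f]
            X = np.column_stack([x ** i for i in range(1, deg + 1)])
            t = y
        elif f == "logarithmic":
            X, t = np.log(x)[:, None], y
        elif f == "inverse":
            X, t = (1.0 / x)[:, None], y
        elif f in ("compound", "growth", "exponential"):
            X, t = x[:, None], np.log(y)
        elif f == "power":
            X, t = np.log(x)[:, None], np.log(y)
        elif f == "s":
            X, t = (1.0 / x)[:, None], np.log(y)
        else:  # logistic
            X, t = x[:, None], np.log(1.0 / y - 1.0 / self.upper)
        return sm.add_constant(X), t

    def fit(self) -> CurveResults:
        X, t = self._design()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"{self.form}: singular design")
        if np.ptp(t) == 0.0:
            # constant response: nothing to explain on this scale
            beta0 = np.zeros(X.shape[1])
            beta0[0] = t[0]
            return self._package(beta0, rsquared=0.0, fvalue=0.0, pvalue=1.0)
        res = sm.OLS(t, X).fit()
        r2, fv, pv = float(res.rsquared), float(res.fvalue), float(res.f_pvalue)
        if not np.isfinite(r2):  # degenerate response
            r2, fv, pv = 0.0, 0.0, 1.0
        return self._package(np.asarray(res.params, dtype=float),
                             rsquared=r2, fvalue=fv, pvalue=pv)

    def _package(self, beta, rsquared, fvalue, pvalue) -> CurveResults:
        f = self.form
        if f in ("compound", "exponential"):
            params = (float(np.exp(beta[0])),
                      float(np.exp(beta[1])) if f == "compound" else float(beta[1]))
        elif f == "power":
            params = (float(np.exp(beta[0])), float(beta[1]))
        elif f in ("s", "growth"):
            params = (float(beta[0]), float(beta[1]))
        elif f == "logistic":
            params = (float(np.exp(beta[0])), float(np.exp(beta[1])))
        else:
            params = tuple(float(b) for b in beta)
        return CurveResults(form=f, params=params,
                            rsquared=min(max(rsquared, 0.0), 1.0),
                            fvalue=max(fvalue, 0.0) if np.isfinite(fvalue) else 0.0,
                            f_pvalue=pvalue if np.isfinite(pvalue) else 1.0,
                            nobs=int(self.y.size), upper=self.upper)


def fit_curve(x, y, form: str, logistic_upper: float | None = None) -> CurveResults:
    """Fit one of the eleven forms of y on x."""
    return CurveModel(y, x, form, logistic_upper=logistic_upper).fit()


def scan_curves(x, y, forms: Sequence[str] = CURVE_FORMS,
                logistic_upper: float | None = None):
    """Fit all feasible forms and rank them.

    Ranking is by R-squared; fits whose R-squared differ by less than
    ``RSQ_TIE_TOL`` are treated as tied and ordered by parameter count
    (parsimony) and then by F.  Returns ``(ranked fits, skipped)`` where
    ``skipped`` maps infeasible forms to the reason.
    """
    fits: list[CurveResults] = []
    skipped: dict[str, str] = {}
    for form in forms:
        try:
            fits.append(fit_curve(x, y, form, logistic_upper=logistic_upper))
        except ValueError as e:
            skipped[form] = str(e)
    if not fits:
        raise ValueError("no curve form was feasible: " + "; ".join(skipped.values()))
    fits.sort(key=lambda f: -f.rsquared)
    ranked: list[CurveResults] = []
    i = 0
    while i < len(fits):
        j = i
        while j + 1 < len(fits) and fits[i].rsquared - fits[j + 1].rsquared < RSQ_TIE_TOL:
            j += 1
        ranked.extend(sorted(fits[i:j + 1], key=lambda f: (f.nparams, -f.fvalue)))
        i = j + 1
    return ranked, skipped


@dataclass(frozen=True)
class TemperatureTrend:
    """Quadratic temperature-trend prediction plus the trend-family R^2 table."""

    prediction: float               # deg C at the target year
    target_year: int
    rsquared_by_form: dict[str, float]

    def summary(self) -> str:
        table = "  ".join(f"{f}={r:.4f}" for f, r in self.rsquared_by_form.items())
        return (f"Temperature trend: {self.prediction:.1f} deg C at "
                f"{self.target_year}\n  trend R^2: {table}")


def predict_temperature_trend(climate: ClimateSeries, year: int) -> TemperatureTrend:
    """Quadratic trend of global mean temperature on ordinal year, evaluated
    at ``year``; also reports R-squared across the five trend families."""
    years = climate.years
    if len(years) < 10:
        raise ValueError("temperature-trend prediction needs at least 10 years")
    t = [climate.temperature[y] for y in years]
    r2 = {}
    for form in TREND_FORMS:
        try:
            r2[form] = TrendModel(t, years, form=form).fit().rsquared
        except Exception:
            pass
    fit = TrendModel(t, years, form="polynomial2").fit()
    return TemperatureTrend(prediction=float(fit.predict([year])[year]),
                            target_year=int(year), rsquared_by_form=r2)


@dataclass(frozen=True)
class CarbonPeakParams:
    """Warming-target parameters: pre-industrial global mean temperature,
    the projected temperature at the horizon year, and the Paris-Agreement
    warming band (floor/ceiling above pre-industrial)."""

    t_predicted_2030: float
    t_pre_industrial: float = reference.T_PRE_INDUSTRIAL
    warming_floor: float = reference.WARMING_FLOOR
    warming_ceiling: float = reference.WARMING_CEILING

    def __post_init__(self):
        if not self.warming_ceiling > self.warming_floor > 0:
            raise ValueError("need ceiling > floor > 0")
        if not self.t_predicted_2030 > self.t_pre_industrial:
            raise ValueError("predicted temperature must exceed pre-industrial")


def carbon_peak_retardation(params: CarbonPeakParams) -> float:
    """Maximum relative retardation of warming under the emissions-peaking
    target: (T_pred - T_pre - floor) / T_pred x 100, as a percent to 0.1."""
    pct = ((params.t_predicted_2030 - params.t_pre_industrial - params.warming_floor)
           / params.t_predicted_2030 * 100.0)
    return round_half_up(pct, 1)


def ceiling_temperature(params: CarbonPeakParams) -> float:
    """The warming-band ceiling in absolute terms: T_pre + ceiling (deg C)."""
    return round_half_up(params.t_pre_industrial + params.warming_ceiling, 1)
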