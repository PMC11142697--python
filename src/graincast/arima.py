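"""ARIMA candidates on log yields.

World yield series are modelled on the log scale (logs remove the
heteroscedasticity of growing series).  The differencing order d is the
smallest d in {0, 1, 2} for which the d-times differenced log series passes
an augmented Dickey-Fuller test at the 5% level; five ARMA structures
(p, q) in {(1,2), (1,1), (1,0), (0,2), (0,1)} with a drift constant are then
fitted by maximum likelihood to the differenced logs and compared by their
one-step-ahead in-sample RMSE back-transformed to kg/ha.  Forecasts are mean
log-scale forecasts integrated d times and exponentiated without a variance
(smearing) correction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.statespace.sarimax import SARIMAX
from statsmodels.tsa.stattools import adfuller

CANDIDATE_PQ = ((1, 2), (1, 1), (1, 0), (0, 2), (0, 1))

__all__ = ["CANDIDATE_PQ", "choose_differencing", "LogArima", "LogArimaResults",
           "fit_candidates"]


def choose_differencing(log_series, max_d: int = 2, alpha: float = 0.05) -> int:
    """Smallest d in {0..max_d} whose d-differenced series is ADF-stationary.

    The ADF regression includes a constant and no deterministic trend; lag
    order is chosen by AIC.  If even ``max_d`` differences fail the test,
    ``max_d`` is returned with a warning.
    """
    x = np.asarray(log_series, dtype=float)
    if x.size < 10:
        raise ValueError("stationarity testing needs at least 10 observations")
    for d in range(max_d + 1):
        w = np.diff(x, n=d)
        try:
            pvalue = adfuller(w, regression="c", autolag="AIC")[1]
        except Exception:
            # e.g. a (near-)constant differenced series: flat is stationary
            pvalue = 0.0 if np.ptp(w) < 1e-12 else 1.0
        if pvalue < alpha:
            return d
    warnings.warn(
        f"series still non-stationary after {max_d} differences; using d={max_d}",
        stacklevel=2,
    )
    return max_d


@dataclass(frozen=True)
class LogArimaResults:
    """A fitted ARIMA(p,d,q)-with-drift structure on log yields."""

    order: tuple[int, int, int]
    drift: float                     # constant on the d-differenced log scale
    ar_coefficients: tuple[float, ...]
    ma_coefficients: tuple[float, ...]
    rmse: float                      # kg/ha, original scale, one-step in-sample
    sigma2: float                    # innovation variance, log scale
    nobs: int
    converged: bool
    admissible: bool                 # AR and MA roots outside the unit circle
    _y: tuple[float, ...] = ()       # fitting data (original scale), for forecasting
    _res: object = None              # underlying statespace results

    @property
    def label(self) -> str:
        p, d, q = self.order
        return f"ARIMA({p},{d},{q})"

    def forecast(self, horizon: int) -> np.ndarray:
        """Mean forecasts for the next ``horizon`` years, kg/ha.

        Log-scale ARMA forecasts of the differenced series are integrated d
        times from the last observed log levels and exponentiated.
        """
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        z = np.log(np.asarray(self._y, dtype=float))
        d = self.order[1]
        wf = np.asarray(self._res.forecast(horizon), dtype=float)
        if d == 0:
            zf = wf
        elif d == 1:
            zf = z[-1] + np.cumsum(wf)
        else:  # d == 2
            d1 = (z[-1] - z[-2]) + np.cumsum(wf)
            zf = z[-1] + np.cumsum(d1)
        return np.exp(zf)

    def forecast_years(self, horizon_years) -> dict[int, float]:
        """Forecast indexed by calendar year, assuming the fit window ends the
        year before the first requested year and years are consecutive."""
        horizon_years = [int(y) for y in horizon_years]
        f = self.forecast(len(horizon_years))
        return dict(zip(horizon_years, (float(v) for v in f)))

    def summary(self) -> str:
        flags = []
        if not self.converged:
            flags.append("NOT CONVERGED")
        if not self.admissible:
            flags.append("NON-ADMISSIBLE ROOTS")
        return (
            f"{self.label} on log yields  drift={self.drift:.6f}  "
            f"AR={tuple(round(c, 6) for c in self.ar_coefficients)}  "
            f"MA={tuple(round(c, 6) for c in self.ma_coefficients)}  "
            f"RMSE={self.rmse:.4f} kg/ha  n={self.nobs}"
            + (("  [" + ", ".join(flags) + "]") if flags else "")
        )


class LogArima:
    """ARIMA(p,d,q) with drift, estimated on the logs of a yield series.

    Parameters
    ----------
    y : positive yields (kg/ha) in year order
    order : (p, d, q); the ARMA part is fitted to the d-differenced logs with
        a constant (the drift)
    """

    def __init__(self, y, order: tuple[int, int, int]):
        self.y = np.asarray(y, dtype=float)
        if np.any(self.y <= 0):
            raise ValueError("log-scale ARIMA requires positive yields")
        p, d, q = order
        if min(p, d, q) < 0:
            raise ValueError("orders must be non-negative")
        self.order = (int(p), int(d), int(q))

    def fit(self) -> LogArimaResults:
        p, d, q = self.order
        z = np.log(self.y)
        w = np.diff(z, n=d)
        model = SARIMAX(w, order=(p, 0, q), trend="c")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0)
        converged = bool(res.mle_retvals.get("converged", True))
        arp = tuple(float(c) for c in res.arparams)
        map_ = tuple(float(c) for c in res.maparams)
        admissible = True
        if arp and np.any(np.abs(res.arroots) <= 1.0):
            admissible = False
        if map_ and np.any(np.abs(res.maroots) <= 1.0):
            admissible = False
        # one-step-ahead fitted values of w -> fitted log levels using actual
        # past observations, then back to kg/ha
        what = np.asarray(res.fittedvalues, dtype=float)
        zhat = what + (z[d:] - w)  # add back the subtracted lag terms
        yhat = np.exp(zhat)
        rmse = float(np.sqrt(np.mean((self.y[d:] - yhat) ** 2)))
        return LogArimaResults(
            order=self.order,
            drift=float(res.params[0]),
            ar_coefficients=arp,
            ma_coefficients=map_,
            rmse=rmse,
            sigma2=float(res.params[-1]),
            nobs=int(self.y.size),
            converged=converged,
            admissible=admissible,
            _y=tuple(self.y),
            _res=res,
        )


def fit_candidates(y, d: int | None = None,
                   candidates=CANDIDATE_PQ) -> list[LogArimaResults]:
    """Fit the candidate ARMA structures on d-differenced log yields.

    ``d=None`` chooses d by :func:`choose_differencing`.  Candidates that fail
    to estimate are dropped with a warning; non-converged or root-inadmissible
    fits are returned flagged so the arbitration layer can exclude them.
    """
    y = np.asarray(y, dtype=float)
    if d is None:
        d = choose_differencing(np.log(y))
    out: list[LogArimaResults] = []
    for p, q in candidates:
        try:
            out.append(LogArima(y, (p, d, q)).fit())
        except Exception as e:  # singular/unstable candidate
            warnings.warn(f"ARIMA({p},{d},{q}) failed to fit: {e}", stacklevel=2)
    if not out:
        raise RuntimeError("no ARIMA candidate could be fitted")
    return out
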