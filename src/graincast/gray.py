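"""GM(1,1) gray-system prediction from short windows.

The first-order, one-variable gray model fits an exponential law to the
accumulated (cumulative-sum) sequence x1 of a short positive series x0.
Parameters are estimated by least squares on the whitening equation
x0(k) = -a z1(k) + b, where z1(k) is the background value — the mean of
consecutive accumulated values, z1(k) = 1/2 (x1(k) + x1(k-1)).  The time
response

    x1_hat(k+1) = (x0(1) - b/a) e^(-a k) + b/a

is restored to the original scale by first-order inverse accumulation.
``a`` is the developmental gray number, ``b`` the endogenous-control gray
number.  Rolling one-step prediction from the most recent 5 observations is
the package's near-term cross-check of the hybrid trend/ARIMA projections.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import percent_change
from .series import YieldSeries

#: background-value weight; 1/2 is the classical choice
BACKGROUND_WEIGHT = 0.5

#: below this |a| the exponential response degenerates to the linear limit
A_ZERO_TOL = 1e-12

__all__ = ["GM11", "GM11Results", "fit_gm11", "rolling_predict", "cross_validate"]


@dataclass(frozen=True)
class GM11Results:
    """A GM(1,1) fit on one window."""

    a: float                      # developmental gray number
    b: float                      # endogenous control gray number
    x0: tuple[float, ...]         # original window
    window_years: tuple[int, ...] | None = None

    @property
    def n(self) -> int:
        return len(self.x0)

    def accumulated_response(self, k) -> np.ndarray:
        """Time response x1_hat(k+1) for integer k >= 0 (k=0 returns x0(1))."""
        k = np.asarray(k, dtype=float)
        if abs(self.a) < A_ZERO_TOL:
            # a -> 0 limit: accumulated sequence grows linearly by b per step
            return self.x0[0] + self.b * k
        return (self.x0[0] - self.b / self.a) * np.exp(-self.a * k) + self.b / self.a

    def restored(self, k) -> np.ndarray:
        """Restored (inverse-accumulated) value x0_hat(k+1) for k >= 1."""
        k = np.asarray(k, dtype=float)
        if np.any(k < 1):
            raise ValueError("restored values are defined for k >= 1")
        return self.accumulated_response(k) - self.accumulated_response(k - 1)

    def predict(self, steps: int = 1) -> np.ndarray:
        """One- to multi-step ahead predictions beyond the window, original scale."""
        if steps < 1:
            raise ValueError("steps must be >= 1")
        k = np.arange(self.n, self.n + steps)
        return self.restored(k)

    def fitted(self) -> np.ndarray:
        """In-window restored values x0_hat(2..n); x0_hat(1) = x0(1) exactly."""
        return self.restored(np.arange(1, self.n))

    def summary(self) -> str:
        yrs = f" years {self.window_years[0]}-{self.window_years[-1]}" if self.window_years else ""
        return (f"GM(1,1){yrs}  a={self.a:.6f}  b={self.b:.4f}  "
                f"next-step prediction={float(self.predict(1)[0]):.2f}")


class GM11:
    """GM(1,1) gray model on a short window of positive values.

    Parameters
    ----------
    window : positive values in time order (classically 5 of them)
    years : optional parallel calendar years
    background_weight : weight of the newer value in the background mean
    """

    def __init__(self, window, years=None, background_weight: float = BACKGROUND_WEIGHT):
        self.x0 = np.asarray(window, dtype=float)
        if self.x0.size < 4:
            raise ValueError("GM(1,1) needs at least 4 values")
        if np.any(self.x0 <= 0):
            raise ValueError("GM(1,1) requires positive values")
        if not 0.0 < background_weight < 1.0:
            raise ValueError("background weight must lie in (0, 1)")
        self.years = tuple(int(y) for y in years) if years is not None else None
        self.background_weight = background_weight

    def fit(self) -> GM11Results:
        x1 = np.cumsum(self.x0)
        w = self.background_weight
        z1 = w * x1[1:] + (1.0 - w) * x1[:-1]
        B = np.column_stack([-z1, np.ones_like(z1)])
        Y = self.x0[1:]
        (a, b), *_ = np.linalg.lstsq(B, Y, rcond=None)
        fit = GM11Results(a=float(a), b=float(b), x0=tuple(self.x0),
                          window_years=self.years)
        if abs(fit.a) >= 2.0:
            raise ValueError(
                f"GM(1,1) inadmissible: |a| = {abs(fit.a):.3f} >= 2; the window "
                "changes too fast for a first-order gray model"
            )
        return fit


def fit_gm11(window, years=None, background_weight: float = BACKGROUND_WEIGHT) -> GM11Results:
    """Fit GM(1,1) on one window (classically the 5 most recent years)."""
    return GM11(window, years=years, background_weight=background_weight).fit()


def rolling_predict(series, target_years, window_length: int = 5) -> dict[int, float]:
    """One-step GM(1,1) predictions for each target year from the immediately
    preceding ``window_length`` values.

    Actual observations are preferred for the window; where a predecessor has
    not been observed (e.g. predicting two years past the end of the series),
    the prediction already made for it is rolled in instead.
    """
    if isinstance(series, YieldSeries):
        known = dict(series.values)
    else:
        known = {int(y): float(v) for y, v in dict(series).items()}
    predictions: dict[int, float] = {}
    for t in sorted(int(y) for y in target_years):
        window_years = list(range(t - window_length, t))
        vals = []
        for y in window_years:
            if y in known:
                vals.append(known[y])
            elif y in predictions:
                vals.append(predictions[y])
            else:
                raise ValueError(
                    f"cannot predict {t}: no observation or prior prediction for {y}"
                )
        fit = GM11(vals, years=window_years).fit()
        predictions[t] = float(fit.predict(1)[0])
    return predictions


def cross_validate(gs_predictions: dict[int, float],
                   hybrid_projections: dict[int, float],
                   actuals: dict[int, float],
                   threshold: float = 5.0) -> pd.DataFrame:
    """Tabulate GS-vs-actual and GS-vs-hybrid signed percent differences.

    Rows are the years common to all three inputs; the ``consistent`` column
    flags whether both absolute differences are below ``threshold`` percent.
    """
    years = sorted(set(gs_predictions) & set(hybrid_projections) & set(actuals))
    if not years:
        raise ValueError("no common years to compare")
    rows = []
    for y in years:
        gs, hy, ac = gs_predictions[y], hybrid_projections[y], actuals[y]
        d_actual = percent_change(ac, gs)
        d_hybrid = percent_change(hy, gs)
        rows.append({
            "year": y, "gs": gs, "hybrid": hy, "actual": ac,
            "gs_vs_actual_pct": d_actual, "gs_vs_hybrid_pct": d_hybrid,
            "consistent": abs(d_actual) < threshold and abs(d_hybrid) < threshold,
        })
    return pd.DataFrame(rows).set_index("year")
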