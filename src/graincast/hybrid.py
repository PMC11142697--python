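"""The hybrid trend/ARIMA yield projector.

For one crop and series kind, the best trend-regression family (by
R-squared) and the best of the five ARIMA candidates (by original-scale
in-sample RMSE, after excluding non-converged or root-inadmissible fits)
compete; whichever has the smaller RMSE supplies the 2020-2030 projection.
A tie goes to the trend form, the simpler deterministic extrapolator.
Held-out actual years (2020-2021) quantify projection reliability as signed
percent differences, with a 5% consistency flag.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._util import percent_change, percent_difference, round_half_up
from .arima import CANDIDATE_PQ, LogArimaResults, choose_differencing, fit_candidates
from .series import ProjectionReport, YieldSeries
from .trend import TrendResults, select_trend

logger = logging.getLogger(__name__)

__all__ = ["HybridYieldModel", "HybridResults", "arima_tr_project",
           "holdout_validate", "percent_change"]


@dataclass(frozen=True)
class HybridResults:
    """Arbitrated projection for one (crop, kind) series."""

    crop: str
    kind: str
    winner: str                          # "trend" | "arima"
    trend_results: TrendResults
    arima_results: LogArimaResults | None
    candidates: tuple[LogArimaResults, ...]
    projections: dict[int, float]        # calendar year -> kg/ha
    differencing: int
    holdout_differences: dict[int, float] = field(default_factory=dict)
    within_5pct: dict[int, bool] = field(default_factory=dict)
    holdout_actuals: dict[int, float] = field(default_factory=dict)

    @property
    def winner_results(self):
        return self.trend_results if self.winner == "trend" else self.arima_results

    @property
    def winner_rmse(self) -> float:
        return self.winner_results.rmse

    @property
    def all_within_5pct(self) -> bool:
        return bool(self.within_5pct) and all(self.within_5pct.values())

    def percent_change(self, year_from: int, year_to: int) -> float:
        """Signed percent change of the projection between two horizon years,
        rounded to 0.1 for reporting."""
        for y in (year_from, year_to):
            if y not in self.projections:
                raise KeyError(f"year {y} not in the projection horizon")
        return percent_change(self.projections[year_from], self.projections[year_to])

    def equation(self) -> str:
        if self.winner == "trend":
            return self.trend_results.equation()
        return self.arima_results.summary().split("  RMSE")[0]

    def model_id(self) -> str:
        return (f"{self.trend_results.form} TR" if self.winner == "trend"
                else self.arima_results.label)

    def to_report(self, ratio_table=None) -> ProjectionReport:
        holdout = {
            y: (self.holdout_actuals[y],
                self.projections[y],
                self.holdout_differences[y])
            for y in sorted(self.holdout_differences)
        }
        return ProjectionReport(
            crop=self.crop, kind=self.kind, model_id=self.model_id(),
            equation=self.equation(), projections=dict(self.projections),
            holdout=holdout, ratio_table=ratio_table,
        )

    def summary(self) -> str:
        lines = [
            f"Hybrid trend/ARIMA projection: {self.crop} ({self.kind} yield)",
            f"  winner: {self.model_id()}  RMSE = {self.winner_rmse:.4f} kg/ha",
            f"  trend candidate: {self.trend_results.form}  "
            f"R^2 = {self.trend_results.rsquared:.4f}  RMSE = {self.trend_results.rmse:.4f}",
        ]
        if self.arima_results is not None:
            lines.append(f"  ARIMA candidate: {self.arima_results.label} (d={self.differencing})"
                         f"  RMSE = {self.arima_results.rmse:.4f}")
        years = sorted(self.projections)
        lines.append(f"  projection {years[0]}-{years[-1]}: "
                     f"{round_half_up(self.projections[years[0]], 1)} -> "
                     f"{round_half_up(self.projections[years[-1]], 1)} kg/ha "
                     f"({self.percent_change(years[0], years[-1]):+.1f}%)")
        for y in sorted(self.holdout_differences):
            ok = "within" if self.within_5pct[y] else "OUTSIDE"
            lines.append(f"  holdout {y}: projected vs actual "
                         f"{self.holdout_differences[y]:+.1f}% ({ok} 5%)")
        return "\n".join(lines)

    def plot(self, series: YieldSeries | None = None, ax=None):
        """Plot the projection (and optionally the observed series)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if series is not None:
            ys = series.years
            ax.plot(ys, [series.values[y] for y in ys], "k.", ms=3, label="observed")
        ph = sorted(self.projections)
        ax.plot(ph, [self.projections[y] for y in ph], "r-", label=self.model_id())
        ax.set_xlabel("year")
        ax.set_ylabel("yield (kg/ha)")
        ax.set_title(f"{self.crop} {self.kind} yield")
        ax.legend()
        return ax


class HybridYieldModel:
    """Fit and arbitrate the trend and ARIMA projectors for one series.

    Parameters
    ----------
    series : YieldSeries covering at least the fit window
    fit_end : last calendar year used for fitting (holdout years come after)
    horizon_end : last projected calendar year
    """

    def __init__(self, series: YieldSeries, fit_end: int = 2019,
                 horizon_end: int = 2030, candidate_pq=CANDIDATE_PQ,
                 adf_alpha: float = 0.05):
        if series.last_year < fit_end:
            raise ValueError(
                f"series ends {series.last_year}, before fit_end {fit_end}")
        self.series = series
        self.fit_end = int(fit_end)
        self.horizon_end = int(horizon_end)
        if self.horizon_end <= self.fit_end:
            raise ValueError("horizon must extend past the fit window")
        self.candidate_pq = candidate_pq
        self.adf_alpha = adf_alpha

    def fit(self) -> HybridResults:
        window = self.series.window(self.series.first_year, self.fit_end)
        years = window.years
        y = np.array([window.values[yy] for yy in years])

        trend = select_trend(window)
        d = choose_differencing(np.log(y), alpha=self.adf_alpha)
        candidates = tuple(fit_candidates(y, d=d, candidates=self.candidate_pq))
        usable = [c for c in candidates if c.converged and c.admissible]
        for c in candidates:
            logger.info("%s/%s candidate %s", self.series.crop, self.series.kind,
                        c.summary())
        best_arima = min(usable, key=lambda c: c.rmse) if usable else None

        # arbitration: strictly smaller RMSE wins; tie -> trend
        if best_arima is None or trend.rmse <= best_arima.rmse:
            winner = "trend"
        else:
            winner = "arima"
        horizon = list(range(self.fit_end + 1, self.horizon_end + 1))
        if winner == "trend":
            projections = trend.predict(horizon)
        else:
            projections = best_arima.forecast_years(horizon)
        logger.info("%s/%s winner: %s (RMSE %.4f)", self.series.crop,
                    self.series.kind, winner,
                    trend.rmse if winner == "trend" else best_arima.rmse)
        return HybridResults(
            crop=self.series.crop, kind=self.series.kind, winner=winner,
            trend_results=trend, arima_results=best_arima,
            candidates=candidates, projections=projections, differencing=d,
        )


def arima_tr_project(series: YieldSeries, fit_end: int = 2019,
                     horizon_end: int = 2030) -> HybridResults:
    """One-call form of :class:`HybridYieldModel`."""
    return HybridYieldModel(series, fit_end=fit_end, horizon_end=horizon_end).fit()


def holdout_validate(projection: HybridResults,
                     actuals: dict[int, float],
                     threshold: float = 5.0) -> HybridResults:
    """Fill in holdout percent differences (projected vs actual) and the
    per-year within-threshold flags; returns an updated copy."""
    diffs, within = {}, {}
    for year, actual in sorted(actuals.items()):
        if year not in projection.projections:
            raise KeyError(f"holdout year {year} outside the projection horizon")
        d = percent_difference(projection.projections[year], actual)
        diffs[year] = d
        within[year] = abs(d) < threshold
    return replace(projection, holdout_differences=diffs, within_5pct=within,
                   holdout_actuals={int(y): float(v) for y, v in actuals.items()})
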