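"""Yield-gap analysis: average/top ratios, potential limits, S-curve stage
classification and top-country distribution tallies.

The top national yield of a crop is treated as the attainable potential
limit of its world average; the ratio 100 x average/top is the gap metric.
A rising ratio means the gap is narrowing.  On the logistic (S-shaped)
view of yield progress, a crop whose 2030 ratio is below 30% is at the low
stage (input priority: high-yield countries), above 70% at the high stage
(priority: low-yield countries), and in between at the mid stage (priority:
both).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from ._util import round_half_up
from .series import YieldSeries

STAGE_LOW_BELOW = 30.0   # ratio % below which average yield is at the low stage
STAGE_HIGH_ABOVE = 70.0  # ratio % above which it is at the high stage

#: ratio changes (percentage points) smaller than this are called stable
STABLE_TOL = 0.05

_PRIORITY = {"low": "high-yield countries", "mid": "both",
             "high": "low-yield countries"}

__all__ = ["GapReport", "TopCountryTally", "ratio_series", "classify_gap",
           "stage_and_priority", "tally_top_countries", "build_gap_report"]


def ratio_series(avg_projection: dict[int, float],
                 top_projection: dict[int, float],
                 ndigits: int | None = 1) -> dict[int, float]:
    """Per-year ratio 100 x average/top over the common years, one-decimal
    reporting by default.  Scale-invariant by construction."""
    years = sorted(set(avg_projection) & set(top_projection))
    if not years:
        raise ValueError("no common years between the two projections")
    out = {}
    for y in years:
        top = top_projection[y]
        if top <= 0:
            raise ValueError(f"non-positive top projection in {y}")
        r = avg_projection[y] / top * 100.0
        out[y] = round_half_up(r, ndigits) if ndigits is not None else r
    return out


def classify_gap(ratio_by_year: dict[int, float]) -> tuple[str, float]:
    """Label the gap trajectory from the first-to-last ratio change.

    Returns ``(label, change)`` where change is in percentage points (one
    decimal): a rising ratio means the gap narrows, a falling one that it
    widens; changes below ``STABLE_TOL`` points are 'stable'.
    """
    if len(ratio_by_year) < 2:
        raise ValueError("need at least two years to classify a trajectory")
    years = sorted(ratio_by_year)
    change = ratio_by_year[years[-1]] - ratio_by_year[years[0]]
    if abs(change) < STABLE_TOL:
        label = "stable"
    elif change > 0:
        label = "narrowing"
    else:
        label = "widening"
    return label, round_half_up(change, 1)


def stage_and_priority(ratio_2030: float) -> tuple[str, str]:
    """S-curve stage of the average yield relative to its potential limit,
    and where input priority should go.  Boundary ratios (30%, 70%) fall in
    the mid band."""
    if not 0 < ratio_2030 <= 100:
        raise ValueError(f"ratio {ratio_2030} outside (0, 100]")
    if ratio_2030 < STAGE_LOW_BELOW:
        stage = "low"
    elif ratio_2030 > STAGE_HIGH_ABOVE:
        stage = "high"
    else:
        stage = "mid"
    return stage, _PRIORITY[stage]


@dataclass(frozen=True)
class TopCountryTally:
    """Distribution intensity of top-yield countries for one crop: how many
    years each country held the world-top yield, and the share of the span."""

    crop: str
    counts: dict[str, int]
    percentages: dict[str, float]
    n_years: int

    def summary(self) -> str:
        lines = [f"Top-yield country distribution, {self.crop} "
                 f"({self.n_years} years):"]
        for c, n in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0])):
            lines.append(f"  {c}: {n} years ({self.percentages[c]:.1f}%)")
        return "\n".join(lines)


def tally_top_countries(series: YieldSeries) -> TopCountryTally:
    """Count, per country, the years it held the world-top yield.

    Every observed year must carry a label; percentages are over the whole
    observed span, half-up to one decimal.
    """
    if series.kind != "top" or not series.top_country:
        raise ValueError("tally needs a top series with top_country labels")
    missing = sorted(set(series.values) - set(series.top_country))
    if missing:
        raise ValueError(f"{series.crop}: missing top-country labels for {missing}")
    n = len(series.values)
    counts = Counter(series.top_country[y] for y in series.years)
    pct = {c: round_half_up(k / n * 100.0, 1) for c, k in counts.items()}
    return TopCountryTally(crop=series.crop, counts=dict(counts),
                           percentages=pct, n_years=n)


@dataclass(frozen=True)
class GapReport:
    """Gap trajectory and S-curve classification for one crop."""

    crop: str
    ratio_by_year: dict[int, float]
    trend_label: str
    ratio_change: float              # percentage points, first -> last year
    potential_limit_2030: float      # kg/ha (top projection at the horizon end)
    stage: str
    priority: str

    def summary(self) -> str:
        years = sorted(self.ratio_by_year)
        return (
            f"Yield gap, {self.crop}: average/top ratio "
            f"{self.ratio_by_year[years[0]]:.1f}% ({years[0]}) -> "
            f"{self.ratio_by_year[years[-1]]:.1f}% ({years[-1]}), "
            f"{self.trend_label} ({self.ratio_change:+.1f} points)\n"
            f"  potential limit at {years[-1]}: "
            f"{round_half_up(self.potential_limit_2030)} kg/ha; "
            f"stage: {self.stage}; input priority: {self.priority}"
        )


def build_gap_report(crop: str, avg_projection: dict[int, float],
                     top_projection: dict[int, float]) -> GapReport:
    """Assemble the per-crop gap report from average and top projections."""
    ratios = ratio_series(avg_projection, top_projection)
    label, change = classify_gap(ratios)
    last = max(ratios)
    stage, priority = stage_and_priority(ratios[last])
    return GapReport(crop=crop, ratio_by_year=ratios, trend_label=label,
                     ratio_change=change,
                     potential_limit_2030=float(top_projection[last]),
                     stage=stage, priority=priority)
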