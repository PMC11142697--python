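"""Seeded generators of yield and climate series with the statistical
structure the analysis assumes.

World average yields are emulated as a smooth quadratic trend in ordinal
year plus small AR(1) noise (autocorrelated, so the ARMA candidates are
distinguishable); top national yields as a multiplicative premium on the
average plus inflated noise, clipped to stay at or above the average, with a
top-country label that persists between random switch events.  Global mean
temperature follows a gently accelerating quadratic (about 13.9 deg C in
1961 rising to about 15.0 deg C by 2021); land precipitation fluctuates
around a constant mean (about 850-950 mm) with no trend.  Everything is
deterministic given the seed.

The per-crop trend presets are the published 1961-2019 world-average fits,
and the noise scales match the published trend-fit RMSEs, so synthetic
series are realistic in level, curvature and roughness.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import top_country_map
from .series import ClimateSeries, YieldSeries

__all__ = ["YieldGenSpec", "ClimateGenSpec", "CROP_PRESETS", "default_spec",
           "generate_yields", "generate_climate", "make_reference_fixture"]

_DEFAULT_POOL = ("Australia", "Egypt", "Netherlands", "New Zealand", "Italy")


@dataclass(frozen=True)
class YieldGenSpec:
    """Generator settings for one crop's (average, top) pair.

    trend: (c0, c1, c2) of the average-yield quadratic c0 + c1 x + c2 x^2 on
    ordinal year x (x = 1 at the span start).  AR(1) noise: innovation sd
    ``noise_sd`` kg/ha, autoregression ``ar_rho``.  The top series is
    ``top_premium`` x average plus noise inflated by ``top_noise_inflation``.
    """

    crop: str = "rice"
    trend: tuple[float, float, float] = (1740.0, 60.072, -0.1531)
    ar_rho: float = 0.3
    noise_sd: float = 80.0
    top_premium: float = 2.2
    top_noise_inflation: float = 3.0
    country_pool: tuple[str, ...] = _DEFAULT_POOL
    switch_prob: float = 0.2
    span: tuple[int, int] = (1961, 2021)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.ar_rho < 1.0:
            raise ValueError("ar_rho must lie in [0, 1)")
        if self.noise_sd < 0 or self.top_noise_inflation < 0:
            raise ValueError("noise scales must be non-negative")
        if self.top_premium <= 1.0:
            raise ValueError("top_premium must exceed 1")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must lie in [0, 1]")
        if self.span[1] < self.span[0]:
            raise ValueError("empty span")


@dataclass(frozen=True)
class ClimateGenSpec:
    """Generator settings for the climate table.

    Temperature follows the quadratic t0 + t1 x + t2 x^2 (deg C, increasing
    over the span) plus white noise; precipitation is white noise around a
    constant mean (mm), i.e. trendless by construction.
    """

    temp_trend: tuple[float, float, float] = (13.88, 0.002, 0.00028)
    temp_sd: float = 0.08
    precip_mean: float = 900.0
    precip_sd: float = 22.0
    span: tuple[int, int] = (1961, 2021)
    seed: int = 0

    def __post_init__(self):
        t0, t1, t2 = self.temp_trend
        n = self.span[1] - self.span[0] + 1
        slopes = [t1 + 2 * t2 * x for x in (1, n)]
        if min(slopes) <= 0:
            raise ValueError("temperature trend must be increasing over the span")
        if self.precip_mean <= 0:
            raise ValueError("precipitation mean must be positive")


#: realistic per-crop presets: trend = published world-average fit, noise_sd
#: of the order of that fit's residual RMSE, premium ~ top/average level.
CROP_PRESETS: dict[str, YieldGenSpec] = {
    "rice": YieldGenSpec(crop="rice", trend=(1740.0, 60.072, -0.1531),
                         noise_sd=80.0, top_premium=2.2),
    "wheat": YieldGenSpec(crop="wheat", trend=(1055.0, 46.042, -0.0941),
                          noise_sd=85.0, top_premium=2.7,
                          top_noise_inflation=5.0),
    "maize": YieldGenSpec(crop="maize", trend=(1919.3, 54.812, 0.2025),
                          noise_sd=170.0, top_premium=4.5,
                          top_noise_inflation=8.0),
    "soybean": YieldGenSpec(crop="soybean", trend=(1163.0, 24.648, 0.0372),
                            noise_sd=90.0, top_premium=1.5,
                            top_noise_inflation=4.0),
}


def default_spec(crop: str, seed: int = 0,
                 span: tuple[int, int] = (1961, 2021)) -> YieldGenSpec:
    """The realistic preset for one crop, reseeded/respanned."""
    from dataclasses import replace
    return replace(CROP_PRESETS[crop], seed=seed, span=span)


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd / np.sqrt(1.0 - rho ** 2) if rho > 0 else sd)
    innov = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + innov[t - 1]
    return e


def generate_yields(spec: YieldGenSpec) -> tuple[YieldSeries, YieldSeries]:
    """Generate one (average, top) pair of yield series.

    Deterministic given ``spec.seed``; the top series carries country labels
    drawn from ``spec.country_pool`` with persistence.
    """
    rng = np.random.default_rng(spec.seed)
    first, last = spec.span
    years = np.arange(first, last + 1)
    x = years - first + 1.0
    c0, c1, c2 = spec.trend
    trend = c0 + c1 * x + c2 * x * x
    if np.any(trend <= 0):
        raise ValueError("average trend dips non-positive over the span")

    avg = trend + _ar1(rng, years.size, spec.ar_rho, spec.noise_sd)
    avg = np.maximum(avg, 1.0)  # guard positivity for extreme draws
    top_noise = _ar1(rng, years.size, spec.ar_rho,
                     spec.noise_sd * spec.top_noise_inflation)
    top = np.maximum(spec.top_premium * avg + top_noise, avg)  # clip: top >= average

    labels: dict[int, str] = {}
    pool = list(spec.country_pool)
    current = pool[int(rng.integers(len(pool)))]
    for y in years:
        if labels and len(pool) > 1 and rng.random() < spec.switch_prob:
            others = [c for c in pool if c != current]
            current = others[int(rng.integers(len(others)))]
        labels[int(y)] = current

    avg_series = YieldSeries(crop=spec.crop, kind="average",
                             values=dict(zip(years.tolist(), avg.tolist())))
    top_series = YieldSeries(crop=spec.crop, kind="top",
                             values=dict(zip(years.tolist(), top.tolist())),
                             top_country=labels)
    return avg_series, top_series


def generate_climate(spec: ClimateGenSpec) -> ClimateSeries:
    """Generate the climate table: warming quadratic + noise temperatures,
    trendless precipitation."""
    rng = np.random.default_rng(spec.seed)
    first, last = spec.span
    years = np.arange(first, last + 1)
    x = years - first + 1.0
    t0, t1, t2 = spec.temp_trend
    temp = t0 + t1 * x + t2 * x * x + rng.normal(0.0, spec.temp_sd, years.size)
    precip = rng.normal(spec.precip_mean, spec.precip_sd, years.size)
    precip = np.maximum(precip, 1.0)
    return ClimateSeries(
        temperature=dict(zip(years.tolist(), temp.tolist())),
        precipitation=dict(zip(years.tolist(), precip.tolist())),
    )


def make_reference_fixture(seed: int = 0) -> dict[tuple[str, str], YieldSeries]:
    """Four-crop fixture whose top series carry the documented 1961-2021
    top-country labels (see :mod:`graincast.reference`); yield values are
    synthetic, from the per-crop presets.

    Enables the distribution-intensity tallies without any data download.
    """
    out: dict[tuple[str, str], YieldSeries] = {}
    for crop in CROP_PRESETS:
        avg, top = generate_yields(default_spec(crop, seed=seed))
        labels = top_country_map(crop)
        top = YieldSeries(crop=crop, kind="top", values=top.values,
                          top_country={y: labels[y] for y in top.years})
        out[(crop, "average")] = avg
        out[(crop, "top")] = top
    return out
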