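"""Synthetic-data generators: determinism, structure, recovery."""
from dataclasses import replace

import numpy as np
import pytest
import statsmodels.api as sm

import graincast as gc


def test_same_seed_reproduces_bit_for_bit():
    a1, t1 = gc.generate_yields(gc.default_spec("wheat", seed=7))
    a2, t2 = gc.generate_yields(gc.default_spec("wheat", seed=7))
    assert a1.values == a2.values
    assert t1.values == t2.values
    assert t1.top_country == t2.top_country
    a3, _ = gc.generate_yields(gc.default_spec("wheat", seed=8))
    assert a3.values != a1.values


def test_zero_noise_reproduces_the_trend_exactly():
    spec = replace(gc.default_spec("maize", seed=0), noise_sd=0.0, ar_rho=0.0)
    avg, top = gc.generate_yields(spec)
    c0, c1, c2 = spec.trend
    for y in avg.years:
        x = y - spec.span[0] + 1
        assert avg.values[y] == pytest.approx(c0 + c1 * x + c2 * x * x, rel=1e-12)
        assert top.values[y] == pytest.approx(spec.top_premium * avg.values[y],
                                              rel=1e-12)
    czero = gc.ClimateGenSpec(temp_sd=0.0, precip_sd=0.0)
    climate = gc.generate_climate(czero)
    t0, t1, t2 = czero.temp_trend
    assert climate.temperature[1961] == pytest.approx(t0 + t1 + t2, rel=1e-12)
    assert all(p == pytest.approx(czero.precip_mean)
               for p in climate.precipitation.values())


@pytest.mark.parametrize("seed", range(5))
def test_top_never_falls_below_average(seed):
    avg, top = gc.generate_yields(gc.default_spec("soybean", seed=seed))
    assert all(top.values[y] >= avg.values[y] for y in avg.years)


def test_generated_temperature_warms_and_precipitation_stays_in_band():
    climate = gc.generate_climate(gc.ClimateGenSpec(seed=1))
    t = [climate.temperature[y] for y in climate.years]
    assert 13.6 < t[0] < 14.2 and 14.7 < t[-1] < 15.3
    p = np.array([climate.precipitation[y] for y in climate.years])
    assert 800 < p.mean() < 1000


def test_precipitation_has_no_significant_trend():
    """The precipitation slope on year is insignificant at 5% in nearly all
    seeded realizations (it is white noise by construction)."""
    hits = 0
    for seed in range(100):
        climate = gc.generate_climate(gc.ClimateGenSpec(seed=seed))
        years = np.array(climate.years, dtype=float)
        p = np.array([climate.precipitation[y] for y in climate.years])
        res = sm.OLS(p, sm.add_constant(years - years[0] + 1)).fit()
        hits += res.pvalues[1] >= 0.05
    assert hits >= 90


@pytest.mark.parametrize("seed", range(10))
def test_temperature_trend_recovery(seed):
    """predict_temperature_trend at 2030 lands within 0.2 deg C of the
    generating quadratic."""
    spec = gc.ClimateGenSpec(seed=seed)
    climate = gc.generate_climate(spec)
    t0, t1, t2 = spec.temp_trend
    x = 2030 - spec.span[0] + 1
    truth = t0 + t1 * x + t2 * x * x
    pred = gc.predict_temperature_trend(climate, 2030).prediction
    assert pred == pytest.approx(truth, abs=0.2)


def test_country_labels_persist_and_come_from_the_pool():
    spec = replace(gc.default_spec("rice", seed=3), switch_prob=0.1)
    _, top = gc.generate_yields(spec)
    labels = [top.top_country[y] for y in top.years]
    assert set(labels) <= set(spec.country_pool)
    runs = sum(a != b for a, b in zip(labels, labels[1:]))
    assert runs < len(labels) / 2  # persistence: far fewer switches than years


def test_reference_fixture_has_labels_and_valid_pairs(reference_fixture):
    assert len(reference_fixture) == 8
    rice_top = reference_fixture[("rice", "top")]
    assert rice_top.top_country[1992] == "Dominica"
    wheat_top = reference_fixture[("wheat", "top")]
    assert wheat_top.top_country[2008] == "Zambia"
    for crop in ("rice", "wheat", "maize", "soybean"):
        avg = reference_fixture[(crop, "average")]
        top = reference_fixture[(crop, "top")]
        assert all(top.values[y] >= avg.values[y] for y in avg.years)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        gc.YieldGenSpec(ar_rho=1.0)
    with pytest.raises(ValueError):
        gc.YieldGenSpec(top_premium=0.9)
    with pytest.raises(ValueError):
        gc.ClimateGenSpec(temp_trend=(15.0, -0.05, 0.0))
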