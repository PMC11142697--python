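"""Eleven-form curve estimation, ranking, temperature trend and the
warming-retardation arithmetic."""
import numpy as np
import pytest

import graincast as gc
from graincast.climate import CURVE_FORMS, fit_curve, scan_curves

RNG = np.random.default_rng(12)
X_WIDE = np.sort(RNG.uniform(10.0, 18.0, 61))

# generating coefficients for the noiseless-recovery check (u = 6000 for logistic)
_GEN = {
    "linear": (200.0, 150.0),
    "logarithmic": (100.0, 500.0),
    "inverse": (5000.0, -9000.0),
    "quadratic": (5000.0, -400.0, 20.0),
    "cubic": (1000.0, 50.0, 2.0, 0.5),
    "compound": (800.0, 1.08),
    "power": (20.0, 2.1),
    "s": (12.436, -61.573),
    "growth": (5.0, 0.15),
    "exponential": (800.0, 0.12),
    "logistic": (2.0, 0.7),
}
_EQUIVALENT = {"compound": {"compound", "growth", "exponential"},
               "growth": {"compound", "growth", "exponential"},
               "exponential": {"compound", "growth", "exponential"}}


@pytest.mark.parametrize("form", CURVE_FORMS)
def test_noiseless_recovery_and_selection(form):
    """Each form attains R^2 = 1 on its own noiseless data, recovers its
    coefficients, and the scan's winner reproduces those data (the winner is
    the form itself, or an exactly equivalent reparameterization in the
    compound/growth/exponential trio)."""
    params = _GEN[form]
    upper = 6000.0 if form == "logistic" else None
    probe = gc.CurveResults(form=form, params=params, rsquared=1.0, fvalue=0.0,
                            f_pvalue=0.0, nobs=0, upper=upper)
    y = probe.predict(X_WIDE)
    assert np.all(y > 0)
    fit = fit_curve(X_WIDE, y, form, logistic_upper=upper)
    assert fit.rsquared == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(fit.params, params, rtol=1e-6)
    ranked, _ = scan_curves(X_WIDE, y, logistic_upper=upper)
    winner = ranked[0]
    assert winner.rsquared == pytest.approx(1.0, abs=1e-9)
    assert winner.form in _EQUIVALENT.get(form, {form}) or \
        np.allclose(winner.predict(X_WIDE), y, rtol=1e-6)


def test_s_form_evaluation_at_a_reference_point():
    """The S fit for soybean top yields on temperature, evaluated at 14.5 deg
    C, gives about 3.6 t/ha."""
    fit = gc.CurveResults(form="s", params=(12.436, -61.573), rsquared=0.442,
                          fvalue=46.7, f_pvalue=1e-4, nobs=61)
    val = float(fit.predict(14.5))
    assert val == pytest.approx(np.exp(12.436 - 61.573 / 14.5), rel=1e-12)
    assert val == pytest.approx(3603.0, abs=5.0)


def test_logarithmic_evaluation_at_a_reference_point():
    fit = gc.CurveResults(form="logarithmic", params=(-45337.722, 17928.46),
                          rsquared=0.818, fvalue=234.196, f_pvalue=1e-4, nobs=61)
    val = float(fit.predict(14.5))
    assert val == pytest.approx(-45337.722 + 17928.46 * np.log(14.5), rel=1e-12)
    assert val == pytest.approx(2605.0, abs=5.0)


def test_polynomial_nesting_of_rsquared():
    rng = np.random.default_rng(3)
    x = rng.uniform(10, 18, 61)
    y = 100 + 5 * x + rng.normal(0, 10, 61)
    r2 = {f: fit_curve(x, y, f).rsquared for f in ("linear", "quadratic", "cubic")}
    assert r2["cubic"] >= r2["quadratic"] - 1e-12
    assert r2["quadratic"] >= r2["linear"] - 1e-12


def test_quadratic_beats_cubic_by_parsimony_on_quadratic_data():
    x = X_WIDE
    y = 5000.0 - 400.0 * x + 20.0 * x ** 2
    ranked, _ = scan_curves(x, y)
    forms = [f.form for f in ranked]
    assert forms.index("quadratic") < forms.index("cubic")
    assert ranked[0].form == "quadratic"


def test_log_forms_equal_an_ols_oracle():
    """Each log-scale form's estimate equals explicit normal equations on the
    transformed data to 1e-10."""
    rng = np.random.default_rng(9)
    x = np.sort(rng.uniform(10, 18, 40))
    y = np.exp(2.0 + 0.1 * x) * np.exp(rng.normal(0, 0.05, 40))
    t = np.log(y)
    for form, reg in [("exponential", x), ("s", 1.0 / x), ("power", np.log(x))]:
        X = np.column_stack([np.ones_like(reg), reg])
        beta = np.linalg.solve(X.T @ X, X.T @ t)
        fit = fit_curve(x, y, form)
        if form in ("exponential",):
            assert fit.params[0] == pytest.approx(np.exp(beta[0]), rel=1e-10)
            assert fit.params[1] == pytest.approx(beta[1], rel=1e-10)
        elif form == "power":
            assert fit.params[1] == pytest.approx(beta[1], rel=1e-10)
        else:
            assert fit.params == pytest.approx(tuple(beta), rel=1e-10)


def test_constant_response_still_ranks():
    y = np.full_like(X_WIDE, 500.0)
    ranked, _ = scan_curves(X_WIDE, y)
    assert len(ranked) == len(CURVE_FORMS)
    assert all(f.rsquared == pytest.approx(0.0, abs=1e-9) for f in ranked)


def test_s_form_wins_its_own_monte_carlo():
    """Data from the S form with 1% multiplicative noise: the scan ranks S
    first in nearly all seeded replicates when the predictor spans enough of
    the 1/x curvature."""
    wins = 0
    for s in range(30):
        rng = np.random.default_rng(2000 + s)
        x = rng.uniform(10.0, 18.0, 61)
        y = np.exp(12.436 - 61.573 / x) * np.exp(rng.normal(0, 0.01, 61))
        ranked, _ = scan_curves(x, y)
        wins += ranked[0].form == "s"
    assert wins >= 27  # >= 90%


def test_infeasible_forms_are_skipped_with_reasons():
    x = np.linspace(-5, 5, 30)  # non-positive x
    y = np.linspace(1, 30, 30)
    ranked, skipped = scan_curves(x, y)
    assert {"logarithmic", "inverse", "power", "s"} <= set(skipped)
    assert ranked  # the rest still fit


def test_temperature_trend_prediction():
    # exactly linear warming is reproduced with zero residual
    years = range(1961, 2022)
    lin = gc.ClimateSeries(
        temperature={y: 13.0 + 0.02 * (y - 1960) for y in years},
        precipitation={y: 900.0 for y in years})
    t = gc.predict_temperature_trend(lin, 2030)
    assert t.prediction == pytest.approx(13.0 + 0.02 * 70, abs=1e-8)
    assert t.rsquared_by_form["polynomial2"] == pytest.approx(1.0, abs=1e-9)
    # constant series predicts the constant
    const = gc.ClimateSeries(
        temperature={y: 14.2 for y in years},
        precipitation={y: 900.0 for y in years})
    assert gc.predict_temperature_trend(const, 2030).prediction == \
        pytest.approx(14.2, abs=1e-8)


def test_carbon_peak_arithmetic():
    params = gc.CarbonPeakParams(t_predicted_2030=15.7)
    assert gc.carbon_peak_retardation(params) == 2.5
    assert gc.ceiling_temperature(params) == 15.8
    boundary = gc.CarbonPeakParams(t_predicted_2030=13.8 + 1.5)
    assert gc.carbon_peak_retardation(boundary) == 0.0
    with pytest.raises(ValueError):
        gc.CarbonPeakParams(t_predicted_2030=13.0)
    with pytest.raises(ValueError):
        gc.CarbonPeakParams(t_predicted_2030=15.7, warming_floor=2.5)
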