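# Methods

This note documents the models implemented in `graincast`, the conventions
and defaults that matter for reproducing numbers, and what the synthetic
data generators do and do not emulate.  Nothing here asserts an empirical
result the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

Yield observations are annual, in kg/ha, for four crops (rice, wheat, maize,
soybean) and two series kinds: the *average* (world-mean) yield and the *top*
yield, the highest national yield of that crop anywhere in that year.  The
top yield is interpreted as the attainable potential limit of the average.
Series must cover a contiguous span of calendar years with strictly positive
yields, and a top series can never dip below its average on a shared year —
readers enforce all three invariants and name the offending year on
violation.  Climate series carry global mean temperature (plausibility band
10–20 °C) and annual land precipitation (positive mm).

I/O is tidy comma-delimited text (one row per observation).  Spreadsheet-style
wide tables (years down, one column per crop × kind) are not parsed directly:
melt them into the long layout first, e.g.
`df.melt(id_vars="year", var_name="series", value_name="yield")` plus a split
of the series name into the `crop` and `kind` columns.  Values are kept
at full float precision internally; report CSVs round yields to 0.1 kg/ha and
percentages to one decimal.  All externally reported rounding is half-up
(ties away from zero), because the published tallies this package reproduces
follow that convention (e.g. 22/61 → 36.1%), not banker's rounding.

## Trend regression

Five trendline families on the ordinal year x = year − origin + 1, origin
being the first fitted year (1961 for the reference window, so 2030 ↔ x = 70):

| form | model | estimation scale | parameters |
|---|---|---|---|
| linear | y = b0 + b1 x | original | 2 |
| logarithmic | y = b0 + b1 ln x | original | 2 |
| polynomial2 | y = b0 + b1 x + b2 x² | original | 3 |
| exponential | y = b0 e^(b1 x) | log y | 2 |
| power | y = b0 x^b1 | log y | 2 |

The exponential and power families are fitted by least squares in their
log-linearized form (the spreadsheet-trendline convention that matches the
published equation style), not by nonlinear iteration; this choice is
isolated in `TrendModel.fit` and could be swapped.  R² is reported on the
estimation scale and drives selection; this makes the R² of multiplicative
forms not strictly comparable with the additive ones, a known caveat of the
convention.  Whether the original analysis computed those R² values on the
original or the linearized scale is not stated anywhere we can check; the
linearized scale is this package's documented choice.  RMSE is always
computed on the original kg/ha scale over the fitting window so it is
directly comparable with the ARIMA candidates'.  Selection takes the maximal
R²; exact ties break toward fewer parameters (so noiseless linear data
select the linear form, not the quadratic that interpolates it equally).

"Polynomial" means degree 2 throughout: every published polynomial projection
equation is quadratic.

## ARIMA candidates

Yields are modelled on the log scale to remove the heteroscedasticity of
growing series.  The differencing order d is the smallest in {0, 1, 2} for
which the d-times differenced log series passes an augmented Dickey–Fuller
test at the 5% level (constant included, no deterministic trend, lag order by
AIC — conventional defaults; if even d = 2 fails, d = 2 is used with a
warning).  Five ARMA structures with a drift constant are then fitted to the
differenced logs by maximum likelihood (statsmodels state-space SARIMAX):
(p,q) ∈ {(1,2), (1,1), (1,0), (0,2), (0,1)}.

The published candidate labels are internally inconsistent — a structure
labelled ARIMA(0,0,1) for soybean carries a constant ≈ 0.0156 on log yields
that is only plausible as a drift on *differenced* logs.  This package
resolves d by the stationarity test and always interprets the constant as a
drift on the differenced scale; the label inconsistency is noted, not
resolved.

In-sample RMSE uses one-step-ahead fitted values over the full fitting window
(the first d observations, consumed by differencing, are excluded — whether
the original computation included them is unstated), back-transformed to
kg/ha by plain exponentiation.  No smearing (variance) correction is applied
to the back-transform, for fidelity to equation-based arithmetic; forecasts
are therefore conditional medians rather than means of the implied lognormal.
Candidates that fail to converge or whose AR/MA roots are not outside the
unit circle are flagged and excluded from arbitration: forecasts from such
fits are unreliable.

Because the five candidates are partially nested, the generating structure
cannot be expected to attain the strictly lowest in-sample RMSE — a larger
nested model can only match or undercut it.  The property verified is
"statistically tied-lowest": the true structure's RMSE within 2% of the best
candidate's in the bulk of seeded replications.

## Hybrid arbitration

The best trend form and the best ARIMA candidate compete on original-scale
RMSE; the smaller wins and supplies the 2020–2030 projection.  A tie goes to
the trend form — the simpler, deterministic extrapolator (ties do not occur
in the reference inputs).  Holdout years (2020–2021) are excluded from all
fitting; reliability is reported as the signed percent difference
(projected − actual)/actual × 100 with a 5% band.

## GM(1,1)

Standard first-order, one-variable gray model.  The accumulated sequence
x⁽¹⁾ = cumsum(x⁽⁰⁾) gives background values z⁽¹⁾(k) = ½(x⁽¹⁾(k) + x⁽¹⁾(k−1))
— the ½ is the textbook background weight, exposed as a knob; a and b solve
the least-squares problem x⁽⁰⁾(k) = −a z⁽¹⁾(k) + b.  The time response
x̂⁽¹⁾(k+1) = (x⁽⁰⁾(1) − b/a)e^(−ak) + b/a is restored by first-order inverse
accumulation; the k = 0 anchor equals x⁽⁰⁾(1) exactly.  |a| < 1e-12 switches
to the linear limit (accumulation grows by b per step), which makes constant
windows exact.  |a| ≥ 2 raises an admissibility error; note that for positive
windows under the symmetric background weight, a is structurally confined to
(−2, 2), so this guard only binds for skewed background weights.

Rolling prediction refits on the 5 observations immediately preceding each
target year.  Actual observations are rolled in as they become available
(2021 is predicted from 2016–2020 including actual 2020, consistent with
distinct per-target-year (a, b) pairs in the source analysis); where a
predecessor was never observed, the prediction already made for it is used
instead, enabling short chained forecasts.  This rolling-with-actuals reading
is an assumption: the exact windows behind the published per-year parameters
cannot be confirmed from available material.

## Climate-response scan

Eleven classical curve-estimation parameterizations (see README for the
formulas).  The intrinsically multiplicative forms (compound, power, S,
growth, exponential) are estimated on ln y; the logistic on
ln(1/y − 1/u) with a finite upper bound u, defaulting to 1.1 × max(y) — no
published result depends on the logistic form, so the default only needs to
make the form well-posed.  R², F and the p-value are reported on the
estimation scale.  Note the compound, growth and exponential forms are
reparameterizations of one and the same model and always fit identically;
a scan winner among them is decided by the tie rules below.

Ranking is by R² first; fits within 1e-6 of each other are treated as tied
and ordered by parameter count (parsimony — so noiseless quadratic data rank
the quadratic above the cubic that also interpolates them) and then by F.
The source analysis says selection used "both R² and F" without an ordering;
this ordering is the package's recorded choice.  Significance annotations
use the 0.001/0.01/0.05 thresholds.

One caveat established by simulation in the test suite: data generated from
the S form with 1% noise are reliably recognized (S ranked first in ≥90% of
seeded replicates) only when the predictor spans enough of the 1/x
curvature (e.g. x in 10–18).  Over a narrow band such as 13.9–15.1 °C the
raw-scale cubic, with two extra parameters, frequently edges out the true
form — a structural limit of R²-based selection across estimation scales,
not an implementation artifact.

The temperature trend for 2030 is a quadratic on ordinal year (reported
alongside the R² of all five trend families); the 'Carbon Peak' arithmetic
uses the pre-industrial mean 13.8 °C and the 1.5/2.0 °C Paris band:
retardation = (T₂₀₃₀ − 13.8 − 1.5)/T₂₀₃₀ × 100, ceiling = 13.8 + 2.0.

## Yield gap

Ratios are 100 × average/top per year.  The trajectory label comes from the
sign of the first-to-last change (rising = narrowing, falling = widening;
below 0.05 points = stable); the magnitude is reported raw, in percentage
points, rather than re-binned into verbal tiers.  Stage thresholds are 30%
and 70% of the potential limit, with boundary values assigned to the mid
band.  Top-country tallies count, per country, the years it held the top
yield; percentages are over the observed span (61 years for 1961–2021),
half-up to one decimal.  Year lists expressed as "X to Y" ranges in the
documented record are inclusive — the only reading that reproduces the
published counts.

## Reference inputs

`graincast.reference` freezes the published projection equations (with their
RMSEs and the competing ARIMA candidates' RMSEs) and the 1961–2021
top-country record.  These are inputs, not fitted outputs: the original
FAOSTAT/NOAA source series are not redistributed here, so the package's own
estimators are exercised on synthetic data while the closed-form decade
arithmetic (percent increases, potential limits, ratios) runs off the frozen
equations.  One inconsistency in the record — soybean 1989 claimed by both
Ethiopia PDR and Italy — is resolved in favour of Ethiopia PDR, the only
assignment consistent with the published per-country totals.

## Synthetic data

The generators emulate the structure the analysis assumes, with per-crop
presets whose trend coefficients are the published world-average fits and
whose noise scales match the published trend RMSEs (e.g. rice: quadratic
(1740, 60.072, −0.1531), innovation sd 80 kg/ha):

- average yield = quadratic trend + AR(1) noise (ρ = 0.3) — autocorrelated
  so the ARMA candidates are distinguishable;
- top yield = premium × average + inflated AR(1) noise, clipped from below
  at the average so the top ≥ average invariant holds structurally
  (premiums 1.5–4.5 and inflations 3–8 by crop, set to the rough level and
  roughness of the observed top series);
- top-country labels persist between switch events (probability 0.2/year);
- temperature: increasing quadratic ≈13.9 → ≈15.0 °C over 1961–2021, white
  noise sd 0.08 °C; precipitation: white noise around 900 mm (sd 22 mm),
  trendless by construction.

What the generators do *not* emulate: structural breaks (green-revolution
phases), heteroscedastic or regime-switching top-country dynamics, any
coupling between the climate and yield series, and the exact spectra of the
real series.  Passing tests therefore demonstrate correctness of the
estimators and the pipeline under the assumed structure — not forecasting
skill on the real FAOSTAT series, whose published RMSE/GS cross-checks
require the original data and are outside the test gate.

## Problem sizes and numerics

Test and acceptance computations run at desk scale by design: 61-point
series, 100-replicate trend-recovery and 60-replicate AR-recovery Monte
Carlos, 30-replicate scan/RMSE rate checks.  The AR(1) structure (φ = 0.5,
n = 400) anchors the ARIMA recovery check because its MLE is effectively
unbiased at that length, making "mean within 3 Monte-Carlo standard errors"
a sharp test; MA coefficients carry a small finite-sample bias and are
checked per-fit with a ±0.1 band instead.  Degenerate inputs are handled
explicitly: constant responses get R² = 0 (not NaN), constant GM(1,1)
windows hit the a → 0 limit form, and singular designs raise fitting errors
rather than silently pseudo-inverting.

## Known limitations

- The trend/ARIMA comparison mixes R²-selected and RMSE-selected candidates
  exactly as the source procedure does; it is a projection heuristic, not a
  forecast-combination method with optimality claims.
- Long-horizon GM(1,1) forecasting is deliberately unsupported (the gray
  model is a near-term cross-check only), as are seasonal ARIMA, exogenous
  regressors, multivariate climate regressions and prediction intervals for
  trend extrapolations.
- The S-curve stage classification applies fixed 30/70 thresholds to a
  schematic growth story; no functional S-curve is fitted to the ratio
  trajectory.
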