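# elaforecast

Decomposition-ensemble forecasting of weekly epidemic case counts and
the emergency medicine reserve demand derived from them.

Public-health agencies size their emergency medicine stockpiles from a
forecast of the number of cases an epidemic will produce over the next
season. Weekly surveillance counts mix several components — annual
seasonality, slow drifts from changes in detection technology and
care-seeking behaviour, one-off surges, and noise — and no single
forecaster handles all of them well. `elaforecast` implements the ELA
(EMD–Elman–ARIMA) hybrid:

1. **Decompose** the training series by Empirical Mode Decomposition
   (EMD) into intrinsic mode functions IMF1…IMFm plus a residual, and
   regroup them as `x = x1 + x2`, with `x1 = IMF1 + … + IMF_k` (the
   high-frequency content) and `x2` the remaining modes plus residual
   (seasonality and trend).
2. **Forecast the components** with matched models: an Elman recurrent
   network for `x1`

       x_c(k) = ∂·x_c(k−1) + x(k−1),
       x(k)   = f(w¹u(k) + w²x_c(k)),
       y(k)   = g(w³x(k)),    0 < ∂ < 1,

   and an AIC-selected ARIMA(p,d,q)

       x(t) = c + ∅₁x_{t−1} + … + ∅_p x_{t−p} + ε_t + θ₁ε_{t−1} + … + θ_q ε_{t−q}

   for `x2`.
3. **Ensemble and project**: the ELA point forecast is the elementwise
   sum of the component forecasts, evaluated by MAPE
   `= (1/n)·Σ|x̂_t − x_t|/|x_t|`, and the reserve demand is
   `S = p·α` with `p` the predicted case total and `α` the per-case
   medicine demand coefficient (α = 1 for ordinary treatment courses).

The package also ships the surrounding workflow: ADF stationarity
testing, differencing, Hodrick–Prescott trend/cycle splitting, a
trend-augmented ARIMA baseline, a four-model comparison harness, and a
seeded generator of influenza-like weekly series used as the test
corpus.

## Library example

```python
from elaforecast import ELAModel, RunConfig, SyntheticSpec, generate, train_test_split

series = generate(SyntheticSpec(seed=4))          # 221 weekly case counts
train, test = train_test_split(series, 21)        # 200 train / 21 validate

results = ELAModel(train, RunConfig(seed=4)).fit()
print(results.summary())
forecast = results.forecast(21)                   # cases/week, 21 weeks
```

`results.summary()` prints:

```
ELA decomposition-ensemble forecast model
=============================================
training observations : 200
IMFs extracted        : 3 (+ residual)
grouping split_k      : 3 (x1 = IMF1..3, x2 = rest + residual)
x1 forecaster         : Elman(4 lags, 8 hidden, gain 0.5)
x2 forecaster         : ARIMA(3,1,2) (AIC -1767.31)
demand coefficient    : alpha = 1.0
seed                  : 4
```

## Command line

```bash
elaforecast simulate --out series.csv --seed 4
elaforecast forecast series.csv --out forecast.csv --seed 4
elaforecast compare series.csv --out compare.csv --seed 4 --markdown
```

The `forecast` run above ends with

```
horizon=21  MAPE=27.39%  reserve demand (alpha=1.0) = 36,469
```

meaning: over the 21 held-out weeks the summed component forecast was
off by 27.4% per week on average, and at α = 1 the forecast season
total of ≈36,469 cases is the reserve demand in treatment courses. The
`compare` run tabulates all four forecasters on the identical split:

```
| model          |   mape_pct |   demand |
|:---------------|-----------:|---------:|
| ARIMA-original |    15.647  |  43685.4 |
| ARIMA-dummy    |    20.0145 |  41105   |
| ELMAN          |    38.7865 |  29990.6 |
| ELA            |    27.3927 |  36469.2 |
actual cases over horizon: 53,154
```

(`ARIMA-dummy` is the variant with the Hodrick–Prescott trend as an
exogenous regressor.) Which model wins depends on the noise
realization; see `docs/methods.md` for what the synthetic corpus can
and cannot show.

Further subcommands: `decompose` (one CSV per mode plus a summary),
`stationarity` (ADF report for the raw and differenced series),
`arima-fit` (AIC grid and whiteness check), `scan-k` (validation scan
of the grouping boundary).

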