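# soilvar

Data-driven analysis of soil moisture–temperature coupling in a
winter-wheat soil profile.

Hourly soil temperature (°C) and volumetric moisture (%) measured at
several depths are tightly coupled through evaporation, root water
uptake and heat conduction, but mechanistic soil–plant–atmosphere models
need many hard-to-measure parameters. `soilvar` implements the
alternative: a purely stochastic, time-series description of the
coupling that needs nothing but the sensor records, aimed at
agro-hydrologists and biostatisticians who want to quantify *how
strongly*, *in which direction* and *with what delay* the two variables
drive each other at each depth.

## The model

For each depth the pipeline is:

1. **Seasonal differencing.** The diurnal cycle is removed with a
   period-24 difference, `y_t = (1 − B²⁴) x_t = x_t − x_{t−24}`.
2. **Stationarity gate.** Each differenced series must pass an augmented
   Dickey–Fuller test (variants with no constant, a constant, or
   constant + trend; MacKinnon response-surface critical values;
   augmentation lags chosen so a Ljung–Box test accepts white residuals).
3. **VAR fit.** The (moisture, temperature) pair is modelled as a
   bivariate VAR(p),

   `y_t = c + Φ₁ y_{t−1} + … + Φ_p y_{t−p} + ε_t,  ε_t ~ N(0, Σ)`,

   estimated by conditional Gaussian maximum likelihood, with p chosen
   by AIC = 2k − 2 ln L̂ and BIC = k ln n − 2 ln L̂ (k = m(mp+1)) on a
   common sample, taking the more parsimonious order when they disagree.
4. **Stability.** All eigenvalues of the companion matrix F must lie
   inside the unit circle.
5. **Impulse responses.** Unit-shock responses φ_jk(i) (generalized,
   order-invariant, by default), summarised per direction by an
   **intensity** (gap between the largest positive and largest negative
   response, zero-clamped) and a **time lag** (first horizon after which
   |φ| stays below 5% of the intensity), with residual-bootstrap 90%
   bands.
6. **Granger causality.** Both directions are tested with
   `F = ((RSS₁ − RSS₀)/p) / (RSS₀/(T − 2p − 1))` at the 1/5/10% levels.

A seeded synthetic-data generator produces whole station-seasons
(diurnal harmonics, seasonal trend, coupled VAR noise with known ground
truth, irrigation pulses) so that every stage is testable without field
data.

## Worked example

```python
import numpy as np
from soilvar import SyntheticConfig, generate_dataset, seasonal_difference, VAR

ds = generate_dataset(SyntheticConfig(seed=7))          # 160-day season
mc = seasonal_difference(ds.series[("moisture", 30)])   # MC30SD
st = seasonal_difference(ds.series[("temperature", 30)])

model = VAR.from_pair(mc, st)
table = model.select_order(8)
res = model.fit(table.chosen_p)
print(table.rule)
print(f"max companion root: {res.stability().max_modulus:.4f}")

irf = res.irf(horizon=120, scheme="generalized")
print(f"T<-M intensity: {irf.intensity('ST30SD', 'MC30SD'):.4f} degC")
print(f"T<-M time lag:  {irf.time_lag('ST30SD', 'MC30SD')} h")
g = res.granger("ST30SD")
print(f"moisture -> temperature: F = {g.f_stat:.2f}, "
      f"causes at 5%: {g.causes(0.05)}")
```

prints

```
AIC and BIC agree at p=8
max companion root: 0.9768
T<-M intensity: 0.2772 degC
T<-M time lag:  121 h
moisture -> temperature: F = 6.82, causes at 5%: True
```

i.e. at 30 cm the fitted system is stable but highly persistent, a 1%
moisture shock moves temperature by up to ~0.28 °C, the response has not
settled within the 120-hour window (the lag is reported as horizon + 1),
and past moisture significantly improves temperature prediction.

The same analysis runs from the shell:

```bash
soilvar simulate --output-dir scratch --seed 7
soilvar run --input scratch/synthetic_seed7.csv --depths 10,30 \
            --output-dir scratch/report --boot 1000 --seed 7
```

which writes per-depth `adf.csv`, `lag_selection.csv`, `var_model.json`,
`stability.csv`, `irf.csv` (+bands), `granger.csv`, a consolidated
`report.json` and a run log.

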