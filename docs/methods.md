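# Methods

This note records the statistical model the package implements, the
numerical and design choices that were genuinely open, and what the
synthetic-data generator does and does not emulate.

## Model and pipeline

Each depth contributes one bivariate system: volumetric soil moisture
(%) and soil temperature (°C) on a strict hourly grid. The analysis
chain is deliberately sequential, and later stages assume the earlier
gates passed:

1. **Seasonal differencing** at period S = 24 h removes the diurnal
   cycle: `y_t = x_t − x_{t−24}`. The differenced series is the
   modelling substrate throughout; its first S parent values are
   retained so the transform is exactly invertible.
2. **Stationarity** is tested with the augmented Dickey–Fuller
   regression `Δy_t = ρ y_{t−1} + Σ β_i Δy_{t−i} [+ c [+ δ t]] + ε_t`,
   in three variants (`AR` no deterministic terms, `ARD` constant, `TS`
   constant + trend). The pipeline default is `AR`: a seasonally
   differenced series is near-zero-mean by construction, and the
   no-constant critical values are the ones consistent with the
   reference unit-root table. The augmentation order q is the smallest
   one whose regression residuals pass a Ljung–Box test at 24 lags
   (α = 0.05, degrees of freedom reduced by q); if none of q ≤ q_max
   passes, the BIC-minimising q is used with a warning. A series judged
   non-stationary at the 10% level stops the pipeline — a VAR on a
   unit-root series would invalidate the impulse-response and Granger
   stages — unless an explicit override is set.
3. **VAR estimation** is conditional Gaussian maximum likelihood, which
   for a common regressor set equals equation-wise OLS. The residual
   covariance uses the ML divisor n (not n − k; configurable
   consumers can rescale), and
   `ln L̂ = −(n/2)(m ln 2π + ln det Σ̂ + m)`.
4. **Lag order** is chosen by AIC = 2k − 2 ln L̂ and
   BIC = k ln(n) − 2 ln L̂ with k = m(mp + 1) mean parameters
   (intercept plus lag matrices; covariance parameters excluded — the
   convention uniquely consistent with the reference fit table). All
   candidate orders p = 1..p_max are fitted on a common sample (first
   p_max observations reserved) so the criteria are comparable. When
   AIC and BIC disagree the smaller minimiser wins: fewer parameters,
   smaller estimation error. The intercept is always estimated, even
   when a calibration is quoted without one.
5. **Stability** is the unit-circle condition on the companion matrix
   F (top block-row Φ₁..Φ_p, identity subdiagonal): stable iff
   max |eig(F)| < 1.
6. **Impulse responses** come from the MA representation
   Ψ₀ = I, Ψ_i = Σ_{s≤min(i,p)} Φ_s Ψ_{i−s}. Three unit-shock
   conventions are implemented; the default is the **generalized**
   scheme, column k of φ(i) = Ψ_i Σ e_k / σ_kk, because it is
   order-invariant and is the only convention that allows *both*
   contemporaneous cross-responses to be nonzero, which is what the
   reference response table shows. Cholesky (scaled to unit own
   contemporaneous response) and reduced-form unit shocks are one flag
   away.
7. **Coupling summaries.** The *intensity* of a response curve is
   `max(0, max φ) − min(0, min φ)` — the zero-clamped gap between the
   largest positive and largest negative excursion, in units of the
   responding variable per unit shock. The *time lag* is the first
   horizon after which |φ| stays within `epsilon_frac` (default 5%) of
   the intensity through the end of the window; "approximately zero"
   needs an explicit threshold, and 5% of the curve's own scale is the
   package's definition. A curve that has not settled by the horizon H
   (default 120 h) reports H + 1, surfaced as "> H".
8. **Confidence bands** are nonparametric residual-bootstrap percentile
   intervals (default B = 1,000, level 0.90): resample centred fitted
   residuals with replacement, rebuild the series from the fitted
   coefficients and the actual presample, refit, recompute the IRF.
   Explosive refits are discarded and logged; if more than 20% of
   draws are discarded a "fragile" warning is raised. Deterministic
   given the seed.
9. **Granger causality** uses the textbook restricted/unrestricted OLS
   pair with an intercept and
   `F = ((RSS₁ − RSS₀)/p) / (RSS₀/(T − 2p − 1))`, T being the
   regression sample (all rows with p lags of both variables).
   Critical values at 1/5/10% come from the F(p, T − 2p − 1)
   distribution. The lag order defaults to the VAR's chosen order, with
   a per-direction override: whitening the two equations can need
   different history lengths, and reproducing reference decision tables
   requires direction-specific lags.

## Dickey–Fuller critical values and p-values

The 1/5/10% critical values are MacKinnon-style response surfaces
`cv(level, n) = b₀ + b₁/n + b₂/n² + b₃/n³` for the one-variable case.
Continuous p-values are interpolated on a frozen quantile grid of the
null distribution generated by the package's own vectorised Monte Carlo
(`simulate_df_distribution`): 200,000 driftless random walks of length
1,000 per variant, seeds recorded in `soilvar/_dfquant.py`. The grid is
asymptotic; finite-sample dependence is carried by the response-surface
critical values, and the two agree at the tabulated levels to within
Monte-Carlo resolution (~0.01). Interpolated p-values below 0.001 are
printed as "< 0.001" — below the grid's resolving floor. A seeded
Monte-Carlo fallback for critical values at arbitrary n exists for
independence from the response-surface constants.

## Synthetic station-seasons

The generator emulates one winter growing season (default 160 days,
start 19 December) at three depths with the phenomenology a profile of
soil sensors shows: a 24-hour harmonic whose amplitude decays and whose
phase drifts later with depth; a piecewise-linear seasonal trend
(cooling into winter, warming into spring) whose seasonal difference is
a known constant per segment; a stationary bivariate VAR "weather"
process; and drip-irrigation pulses (jump + exponential decay,
half-life 96 h) confined to the wetted depths.

The stochastic component is built by *period-24 integration* of the
centred VAR process, so that seasonal differencing of the generated
levels returns the VAR sample exactly — every downstream stage can be
tested against known truth without approximation. Two consequences are
documented rather than hidden:

* The VAR's stationary mean is absorbed into the deterministic trend (a
  constant mean in differences is a linear trend in levels).
* The integrated component is a 24-phase random walk whose excursion
  over a season is roughly 40–130× the innovation scale for the
  near-unit-root default truths. Keeping levels inside the instrument
  ranges (−20..60 °C, 0..100%) therefore caps the innovation scale; the
  defaults are solved from each truth's innovation-to-channel variance
  gain matrix (the topsoil system amplifies moisture innovations into
  the temperature channel ~1500-fold in variance). All fitted
  statistics — coefficients, F statistics, unit-shock IRFs, time lags —
  are invariant to this overall scale, but the generated *fluctuation
  magnitudes* are smaller than field data, and irrigation jumps are
  scaled to ~15σ of the topsoil deseasonalized moisture noise (0.25%,
  0.15%) to keep a field-like event-to-noise contrast rather than a
  field-like absolute magnitude.

The default truths are the three field-calibrated reference coefficient
sets (topsoil p = 5, subsoil p = 8, substratum p = 7; variable order
moisture, temperature). The substratum set has a maximum companion root
of 0.997: series generated from it are close enough to integrated that
the ADF gate legitimately fails to reject on some seeds — matching how
borderline the deep-soil series are in the field — so end-to-end tests
exercise the 10 and 30 cm depths and treat the 90 cm gate behaviour as a
feature, not a bug.

What passing the synthetic tests does **not** show: robustness to
sensor dropouts and calibration drift (the reader rejects or
interpolates ≤ 2 h gaps, nothing more), to non-Gaussian innovations
(the generator is Gaussian by design, matching the ML framing), to
trend misspecification beyond piecewise-linear, or to level-dependent
noise. Conclusions about real stations rest on the stationarity gate
and the residual diagnostics, not on the generator.

## Numerical choices and degenerate inputs

* OLS solves use `lstsq`/`solve` on explicitly rank-checked
  cross-products; rank deficiency raises a "collinear" error rather
  than silently pseudo-inverting.
* The ADF lag search compares Ljung–Box p-values on each q's own
  regression; BIC fallback values are computed per regression.
* Eigenvalues of the companion matrix are computed directly
  (`numpy.linalg.eigvals`); stability is a strict < 1 comparison with
  no tolerance — a root of exactly 1 is unstable.
* `sigma` must be symmetric PSD at construction; Cholesky-based shock
  schemes additionally require strict positive definiteness and raise
  "degenerate" otherwise.
* Zero-intensity (identically zero) response curves define time lag 0.
* Bootstrap replicates that fail to refit or are explosive are
  discarded, not imputed; determinism is per-seed.
* Information criteria in lag selection use the common trimmed-sample
  n; single fits use their own fitted n. For comparisons against the
  reference fit table the package's arithmetic is exact given ln L̂, k
  and n (see the acceptance tests for the effective-n subtlety).

## Problem sizes used in the checks

The packaged checks run at deliberately modest sizes chosen to make the
statistical assertions sharp: ADF size/power at T = 500 over 1,000
replicates; Granger size at T = 1,000 over 1,000 replicates and power
at T = 500 over 200; VAR recovery averaged over 20 fixed-seed samples
of T = 4,000 (individual near-unit-root lag estimates carry ~0.03
sampling sd, so the replicate-averaged estimate is the meaningful
recovery statistic); IRF-vs-simulation agreement over 10⁴ paths;
bootstrap behaviour at T = 300 with B up to 1,000. Full station-seasons
(3,840 hourly values per series) are generated where the pipeline is
exercised end to end.

## Known limitations

* Strictly bivariate analyses per depth; no conditioning on other
  depths or covariates, no cointegration/VECM treatment of the
  borderline-integrated deep-soil series.
* Granger causality is temporal predictability, not mechanism; the
  package reports decisions at three fixed levels and leaves
  multiple-depth multiplicity to the analyst.
* The time-lag statistic depends on the 5% settling threshold; curves
  that plateau at a nonzero level report the horizon bound rather than
  a lag.
* p-values for the ADF test are asymptotic-grid interpolations;
  exact finite-sample p-values would need a per-n simulation.
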