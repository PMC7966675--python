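# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that make results reproducible.

## Heatwave definition and exposure

A heatwave day at a grid cell is a day inside a maximal run of at least
`min_run = 3` consecutive days whose daily maximum temperature is *strictly
greater than* the cell threshold. The threshold is the 92.5th percentile of
the cell's pooled baseline summer daily maxima. Conventions that the
definition leaves open, fixed here:

- **Percentile interpolation**: linear interpolation between order
  statistics (numpy's default), so thresholds are bit-reproducible. The
  worked check: the 92.5th percentile of 1..100 is 92.575.
- **Summer**: months {6, 7, 8} by default (northern hemisphere),
  configurable. The synthetic calendar uses twelve 30-day months on a
  365-day year; month 12 absorbs the remainder.
- **Pooling**: all baseline summer days per cell are pooled into one
  distribution (rather than per-day-of-year percentiles). This is the
  simpler convention and the one the 3-day-run definition composes with
  naturally.
- **Strict inequality**: days exactly at the threshold do not count.
- **Missing data**: cells with fewer than `min_valid_days = 30` valid
  baseline summer days get a NaN threshold and drop out of aggregates; a
  cell-year with more than 10% missing days is likewise excluded.

Exposure person-days for year *y* are Σ over cells of
(heatwave days in *y* − baseline-mean heatwave days) × stratum population,
i.e. the *excess* relative to a 1986–2005-style baseline; per-capita excess
divides by the stratum total. Excess can be negative in cool years.
Absolute (non-excess) person-days are reported alongside.

## Attributable mortality and prevention

The attributable fraction is AF = (RR − 1)/RR, floored at zero for
protective RRs (out of scope). Attributable deaths on heatwave days are
AF × baseline deaths summed over heatwave days; the default heatwave-day
relative risk is 1.104, the elderly excess-risk level, used as a single
global RR unless location-specific values are supplied. Whether that value
acts as the mortality-model RR or only as a vulnerability statistic is left
to configuration — both roles are supported (`ExposureResponse.rr` vs
`by_location`).

Air-conditioning prevention uses the simplest multiplicative model:
prevented fraction PF = prevalence × efficacy, residual deaths =
deaths × (1 − PF). Efficacy is configuration, not an estimate.

PM2.5 burden applies the same AF identity to a user-supplied
concentration→RR curve; concentrations at or below the curve's reference
give AF = 0. The atmospheric chemistry/transport modelling that produces
concentrations is explicitly an input, not part of this package.

## WBGT labour loss

Vapour pressure uses the Magnus-type form
e = (RH/100)·6.105·exp(17.27·Ta/(237.7 + Ta)) (hPa), and the simplified
outdoor WBGT = 0.567·Ta + 0.393·e + 3.94 — the radiation- and wind-free
approximation appropriate when only temperature and humidity are available.
Work capacity is the Hothaps-style logistic
capacity = 0.1 + 0.9/(1 + (WBGT/α₁)^α₂), clamped to 1 for WBGT ≤ 0; the 0.1
floor represents residual output under extreme heat. Industry defaults
follow the heavy/moderate/light convention: primary (α₁ = 30.94,
α₂ = 16.64), secondary (32.93, 17.81), tertiary (34.64, 22.72, flagged
indoor). All are overridable — they are configuration, not ground truth.
The working day is 8 h (so 36 lost hours = 4.5 working days) and the
working year defaults to 250 days. The indoor adjustment for tertiary
industries is a toggle, default off: with no shade-temperature input the
indoor form coincides with the outdoor one.

## Vectorial capacity

VC(T) = m·a(T)²·b_m(T)·b_h(T)·exp(−μ(T)·n(T))/μ(T): biting rate a,
human-infection probability per bite b_h, mosquito-infection probability
b_m, daily mosquito mortality μ, extrinsic incubation period n, and
vector-to-human ratio m. Each parameter may be a constant or a function of
temperature; a registry keyed by species supplies defaults. The
*Ae. aegypti* preset transcribes the established Liu-Helmersson-type fits
(linear biting rate, piecewise-linear b_m, Briere-type b_h, quartic μ with
a 0.01/day floor, exponential-decay EIP). No comparable printed fit was
available for *Ae. albopictus*, so its preset is a labelled synthetic
variant: the same functional family shifted 2 °C cooler with halved biting
rate, reflecting shade preference and lower competence. It should be
replaced with species-specific fits for real analyses. μ ≤ 0 at any
evaluated temperature raises an error naming the day (the
exposure-lifetime term would diverge).

Percent change between eras is 100·(B − A)/A on period-mean VC, which is
pure arithmetic here: reproducing the published 37% (aegypti) / 14%
(albopictus) rises would require the real 1961–2018 climate record.

## Event analysis

Wildfire exposure overlays per-cell event-days with population, zeroing
cells flagged urban (by the synthetic mask or a population-density
threshold — the exclusion rule is stated qualitatively in the source
indicator, so the threshold is configuration). Period change is the
difference of window means with a {increase, decrease, no change} sign.

Cyclone trends per intensity grade compare a baseline window with an
analysis window. The default test is the conditional exact comparison of
two Poisson rates: conditioning on the total event count N, the
analysis-period count is Binomial(N, p₀) under the null with p₀ the
analysis share of exposure years; the two-sided p-value is the
minimum-likelihood method (scipy's `binomtest`), which equals the doubled
tail for the equal-exposure symmetric case. Mann–Kendall (tie-corrected
normal approximation, with continuity correction) is the declared
alternative for monotone trends over the full series. Both are offered
because the source's own exact test is unnamed; α = 0.05, two-sided.
Grades with zero events in both periods are reported missing rather than
given a rate ratio.

## Input–output economics

The economy is the standard Leontief system x = A·x + f with technical
coefficients A (spectral radius < 1), gross output x, final demand f, and
value-added coefficients v = VA/x ∈ (0, 1]. Direct sectoral losses
(labour-share × output, raw output, or deaths converted through per-worker
value added) are propagated as demand-equivalent withdrawals:
Δx_total = (I − A)^{-1}·Δx_direct; indirect = total − direct. This
demand-side convention is declared rather than inferred; a supply-side
(Ghosh) alternative is available via `method="ghosh"`. Losses are reported
in value-added terms so totals read as GDP shares; the currency basis is
2015 USD. Mortality is monetised at VSL = $3.2 million (2015 USD) by
default. On synthetic economies with interdependence 0.6–0.8 the indirect
share of value-added losses exceeds half — qualitatively matching the
observation that most heat-related economic costs are higher-order — and
this is tested as a property, not a number.

## Composite indices and scaling

Composite scores min–max-normalise each component within declared bounds,
invert higher-is-worse components, and take the weighted sum × 100.
Weights are configuration (the published weighting scheme is not printed);
values outside bounds clip with a warning; degenerate bounds are an error.
Indicator series scale to [0, 1] with 1 = worst observed case in the
window for impact series and 1 = declared best-possible value for response
series (e.g. 100% phase-out). Constant impact series raise rather than
return an arbitrary scaling.

## Synthetic data: what it does and does not emulate

The climate generator is cell baseline mean (+ Gaussian spatial offsets) +
sinusoidal seasonality + linear warming trend + i.i.d. Gaussian daily
noise. Defaults: 18–24 °C baseline mean, 8–10 °C seasonal amplitude,
0.5 °C/decade trend (a realistic recent-decades magnitude), 2 °C daily
noise. It supports percentile thresholds and trend recovery but has **no**
autocorrelated weather, no blocking-driven persistent heat events, no
humidity–temperature coupling, and no spatial correlation of daily noise —
so a green trend-recovery test establishes the accounting and detection
logic, not realism of heatwave duration statistics. Population is
log-normal-weighted (σ = concentration) with a constant elderly fraction
and the densest cells flagged urban. Event counts are Poisson
(independence across years — no ENSO-like clustering). Economies draw a
random nonnegative coefficient matrix rescaled to the target spectral
radius (shrunk further only if intermediate demand would exceed a sector's
output, keeping final demand nonnegative); value-added shares are an
independent parameter, so the column-sum payments identity is not imposed
— only the row identity x = A·x + f is.

All generators are pure functions of their spec including the seed;
identical specs give bit-identical output.

## Numerical conventions and limitations

- Percentiles: linear interpolation; detection: strict inequality;
  calendar: 365-day, twelve 30-day months.
- Exact-test p-values: minimum-likelihood two-sided convention.
- Leontief inversion by dense `linalg.solve`; fine for the ≤ 100-sector
  tables this targets.
- The headline published magnitudes (billions of person-days, 26 800
  deaths, $126 billion losses) are **not** reproducible from synthetic
  data and are not targets of any test; the pipeline reproduces the
  methods and their arithmetic, verified against oracles and worked
  examples.
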