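# Methods

## Climatology and anomalies

The reference climatology ("climate values") for daily Tmax and Tmin is
built in a fixed order: (1) a centered rolling mean of width
`window_days` (default 31, i.e. 15 days each side) over the continuous
daily series, then (2) the average of the rolled values for each day of
the year across the reference years (default 1971–2000). The order
matters: rolling-then-averaging attenuates the annual harmonic by the
moving-average gain $\sin(n\pi/T)/(n\sin(\pi/T)) \approx 0.988$ for
$n=31$, $T=365$, so for a perfectly periodic series the per-day mean
anomaly over the reference period is not identically zero but carries a
residual of $(1-\text{gain})\times$ amplitude (≈0.1 °C for an 8 °C
amplitude). Only at `window_days = 1` — where the profile is the plain
day-of-year mean — is the zero-mean property exact, and the tests pin
both facts. Anomalies always subtract the profile from the *raw* daily
values; smoothing enters only through the profile.

Windows at the reference-period boundaries extend into adjacent years
when the series provides them; otherwise partial windows are accepted
when at least two-thirds of the window days are present. The same
two-thirds rule governs missing data inside a window (missing days are
excluded from the mean; a window with more than one-third missing is
invalid). A day of year with no valid contribution at all is a hard
error rather than a silently interpolated value.

Leap days: 29 February contributes to rolling windows like any other
day, but the profile is indexed on the 365 days of a common calendar;
when anomalies are computed, 29 February borrows the 28 February
profile value. The calendar throughout is the proleptic Gregorian
calendar with real leap years; gaps in input files become explicit
missing rows, and rows with Tmin > Tmax are masked on both variables
and counted in the log.

## Event detection

A day qualifies when both the Tmax and Tmin anomaly are strictly below
`anomaly_threshold` (default −4 °C; a day at exactly −4 does not
qualify) and the date's month is in `allowed_months` (default
January–March). Events are maximal runs of at least `min_duration`
(default 4) consecutive qualifying days. Policy choices, all
configurable:

- the month filter applies day-wise, so a run crossing out of the
  allowed season is truncated before the length test;
- missing anomaly days never qualify, so a gap breaks a run
  (conservative under-detection, visible in the log);
- year boundaries get no special treatment — a December–January spell
  can only qualify on its January days under the default month set.

Rates divide the event count by the inclusive year count of the period
and scale to a decade; rounding to one decimal happens only at
presentation time. Scenario comparison builds the climatology from the
model's own historical run over the profile period and applies it to
every scenario series, evaluating the historical run over the profile
period and each scenario over the evaluation period (defaults 1971–2000
and 2071–2100, both inclusive 30-year windows; the bounds are
parameters).

## Synthetic climate generator

Daily temperature is a seasonal harmonic plus optional linear trend
plus AR(1) weather noise:

- harmonic: `tmax_mean − tmax_amplitude · cos(2π(doy − coldest_doy)/365.25)`,
  defaults 10.5 ± 4.5 °C with the coldest day in mid-January and
  `tmin = tmax − 3 °C`, mimicking a hyper-oceanic site with winter
  means of roughly 3–6 °C and summer means of 12–15 °C;
- AR(1) noise with lag-1 coefficient 0.7 and marginal standard
  deviation `noise_std` (default 1 °C), *shared* between Tmax and Tmin,
  plus independent white components of 0.3 × `noise_std` per variable —
  shared noise makes joint-variable exceedance behave like real cold
  spells, where both extremes drop together;
- an optional linear trend in °C per decade.

Cold spells of known start, depth and duration are injected as a
temperature **ceiling** on both variables: on spell days the value is
`min(ambient, seasonal + trend − depth)`. Physically this treats a
spell as an advected cold air mass that caps the local temperature —
ambient weather can deepen a spell but never lift it. The ceiling is
what makes the generator's ground truth exact: with a purely additive
injection, Gaussian noise of std 1.5 °C would erase a spell day's
threshold margin (depth 6 − |−4| = 2 °C) about 9% of the time, and no
detector could recover injected start dates reliably. Under the ceiling
the measured exact-start recovery is 100% at noise std 1.0–1.5 (300
spells each); days where noise would push Tmin above Tmax are clamped
and logged.

With zero noise the full chain (simulate → profile → anomalies →
detect) returns exactly the injected spell list whenever depth exceeds
the threshold magnitude plus the small attenuation residual, the
duration meets the minimum and the spell lies in allowed months.
`poisson_spell_config` places spells as a Poisson process (rate per
decade) uniformly inside January–March windows, kept disjoint, for
rate-recovery experiments.

What the generator does **not** emulate: skewed or heavy-tailed daily
temperature distributions, seasonally varying variance,
autocorrelation beyond lag-1 structure, precipitation or snow cover,
and spatial fields. Passing tests therefore demonstrate the detection
logic and arithmetic, not the meteorological realism of any particular
station record; the real-data event counts are checked by the
integration tests that accept external station and model files.

## Synthetic plot generator

Each field × year yields one invaded and one uninvaded record. Invaded
plots carry logistic canopy curves in day of year,
`asymptote / (1 + exp(−rate (doy − midpoint)))`, sampled biweekly, for
both leaf area (normal-year asymptote 2.9 m² per plant) and light
interception (asymptote 0.98); defaults: midpoint day 120, rate 0.08
d⁻¹, 4 fields, years 2016–2019, event year 2018. In the event year the
leaf-area asymptote is multiplied by 1/11, biomass by 0.5, the
interception plateau drops to 0.55 and the canopy midpoint is delayed
90 days; resident richness (baseline mean 3 species under the invader
vs 9 in open grassland, Poisson-drawn) is multiplied by 4 in the event
year and stays released afterwards, while the canopy recovers to 95% of
normal. Uninvaded plots never respond to the event. Continuous metrics
carry multiplicative lognormal noise with a 5% coefficient of
variation, mean-one so ratios are unbiased. Effect magnitudes follow
the observed field responses (11-fold leaf-area collapse, 55% peak
interception, 90-day delay, 4-fold richness release); they are the
generator's fixed study conditions, not tuning knobs.

`summarize_plots` exports a tidy long table (field, treatment, year,
metric, value) with richness, shoot and total biomass, per-year maxima
of the canopy curves and the day of year of the first interception
crossing of a configurable level (default 50%). Mixed-model inference
on that table is deliberately left to external statistical tools.

## Numerical and design choices

- **First crossing** of an interception level, by linear interpolation
  between sampled points, defines the crossing date (the phenological
  reading of a delayed canopy closure); a series that never reaches the
  level returns none rather than extrapolating. If the first sample is
  already at or above the level, the first sample's time is returned.
- **Fold changes** are plain ratios; orientation (n-fold smaller vs
  larger) is the caller's choice, since published phrasing mixes both.
- **Strict inequality** at the anomaly threshold, and inclusive day
  counts for durations (start and end days both count).
- **Plant density is a free input** to the seed-loss estimator, never
  hard-coded: reported per-plot and per-m² densities in the source
  system are not perfectly consistent, so the arithmetic takes whatever
  density the user supplies.
- Series validation masks non-physical rows (Tmin > Tmax) on both
  variables rather than trusting either value.
- A series shorter than a full year is accepted with a logged warning
  (toy inputs are legitimate for the ecological estimators); operations
  that genuinely need coverage, like profile building, enforce it as a
  hard error.

## Problem sizes in the checked examples

The test suite and acceptance script run entirely on synthetic data:
detector-vs-brute-force equivalence on random anomaly series of up to
10,000 days (1,000 series in the test suite, 300 in the acceptance
script), spell recovery over 100 seeds × 3 spells on 10-year series,
fold-change recovery over 50 seeds of the 4-field plot design, and
Poisson rate recovery over 60 replicates of 30-year series. These sizes
give stable estimates (binomial standard error below 0.6% on the
recovery rate) while keeping a full run in seconds to minutes.

## Known limitations

- The 31-day-window attenuation residual (~1% of seasonal amplitude)
  is inherent to the pinned order of operations; analyses comparing
  anomalies across series with very different seasonal amplitudes
  should keep it in mind.
- Missing-day handling (break runs) can only under-count events;
  records with frequent winter gaps will bias rates low.
- The netCDF reader picks the single nearest land grid point and does
  no regridding or bias correction; model-vs-observation comparisons
  rely on anomalies, not absolute values, to absorb mean bias.
- Event detection treats the two variables symmetrically; criteria
  based on a single variable are available via the criterion flag but
  untested against any published count.
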