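# coldsnap

Detection of multi-day cold extreme-weather events (EWEs) in daily
temperature records, with the ecological estimators needed to quantify
what such an event does to an invasive plant stand and the resident
community it suppresses.

The motivating system is an Atlantic hyper-oceanic grassland invaded by
*Gunnera tinctoria* (giant rhubarb), where a severe late-winter cold
spell (Storm Emma, late February–early March 2018 in Ireland) collapsed
the invader's canopy for a season: leaf area fell ~11-fold, light
interception peaked at 55% instead of ~100% and crossed the 50% level
~90 days late, and resident species richness in invaded plots rose
~4-fold while uninvaded grassland was unaffected. `coldsnap` packages
both halves of that analysis — the climatological event detection and
the plot-level impact arithmetic — plus synthetic generators with known
ground truth so every stage is testable without downloading station or
climate-model data.

## Method

**Climatology.** For daily maximum and minimum temperature $T_x, T_n$,
the reference climatology is built in two steps over a reference period
(default 1971–2000): a centered 31-day rolling mean of the continuous
daily series, then the average of the rolled values for each day of the
year:

$$\bar T_v(d) = \frac{1}{|Y|}\sum_{y \in Y} \frac{1}{31}\sum_{k=-15}^{15} T_v(y, d+k), \qquad v \in \{x, n\},\ d \in 1..365.$$

Daily anomalies subtract the profile value for each calendar day from
the *raw* series, $T'_v(t) = T_v(t) - \bar T_v(\mathrm{doy}(t))$; 29
February borrows the 28 February profile value.

**Event criterion.** A day qualifies when **both** anomalies lie
strictly below a threshold (default −4 °C) and the month is January,
February or March; a cold EWE is a maximal run of at least 4 consecutive
qualifying days. Missing days never qualify, so data gaps break runs
conservatively. Event counts over an inclusive year range are reported
per decade, $10\,n_{\text{events}}/n_{\text{years}}$: 13 events over
1957–2023 gives 1.9 per decade, 5 over 1971–2000 gives 1.7. For climate
model runs (e.g. EURO-CORDEX historical vs RCP2.6/RCP8.5 2071–2100) the
profile is always built from the model's own historical run, never from
observations.

**Impact estimators.** Seed-production loss
($\text{lost} = \text{seeds/plant} \times \text{plants/ha} \times (1 - f_{\text{viable}})$),
biomass-per-area scaling (individual dry mass × plant count / plot
area), species richness (presence/absence counts), fold changes between
years, the first interpolated crossing of a light-interception level,
and the arcsine-square-root transform for proportion data.

## Worked example

Simulate 35 years of synthetic daily weather with three injected cold
spells and run the full pipeline:

```sh
$ coldsnap demo --out demo-out --seed 4
demo: 3 event(s) detected (0.86/decade); outputs in demo-out
$ cat demo-out/events.csv
site,start,end,duration_days,min_tmax_anom,min_tmin_anom
synthetic,1982-02-10,1982-02-15,6,-7.0294712857242825,-7.018681328627375
synthetic,1995-01-20,1995-01-24,5,-6.403435105815286,-6.3916786214962045
synthetic,2003-03-01,2003-03-07,7,-8.248483209597572,-8.23078354699074
```

The detector recovers exactly the three injected spells (starts
1982-02-10, 1995-01-20, 2003-03-01; durations 6, 5 and 7 days), each
with peak anomalies near the injected depths (7, 6.5 and 8 °C below
the seasonal norm). The rate table shows 3 events over 35 years = 0.86
per decade. `demo-out/` also contains the day-of-year climatology, the
full anomaly series and a manifest recording every parameter and seed;
rerunning the same config is byte-identical.

The seed-loss arithmetic at the reported field magnitudes (200,000
seeds per plant, 1.1 plants/m², 10% of plants with viable
inflorescences after the event):

```sh
$ coldsnap seed-loss --seeds-per-plant 200000 --density 1.1 --viable-after 0.10
potential_seeds_per_ha: 2.2e+09
seeds_lost_per_ha:      1.98e+09
```

i.e. a potential 2.2 billion seeds per hectare, of which 1.98 billion
are lost to the event.

Other subcommands: `detect`, `rates`, `compare` (historical vs scenario
runs), `simulate-climate`, `simulate-plots`, `summarize-plots`.

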