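# migdivide

Analysis toolkit for **migratory divides** — contact zones where bird
populations with different inherited migration directions meet.  Written
for movement ecologists working with light-level geolocator tracks and
ringing recoveries of songbirds (the motivating system is the Eurasian
blackcap divide in central Europe, where southwest- and southeast-bound
populations meet near 14° E), it covers the downstream steps between
"table of positions" and "numbers in the results section":

* **Phenotyping** — autumn migration direction as the rhumb-line bearing
  between breeding and wintering sites; classification into SW / S
  (intermediate) / SE / NW (British-wintering) phenotypes from the
  wintering location; Brown–Forsythe spread comparisons with FDR
  correction; ANOVA repeatability of repeated tracks.
* **Cline fitting** — maximum-likelihood fit of the sigmoid cline
  μ(x) = μ_L + (μ_R − μ_L)(1 + tanh(2(x − c)/w))/2 to grouped direction
  data along an east–west transect, with two-log-likelihood profile
  support intervals for the centre c and width w, and conversion of w
  from degrees of longitude to km.
* **Timing** — migration progress against perpendicular threshold lines
  at 30/50/70% of the great-circle route, with a longitude-weighted
  crossing estimator, equinox exclusion rules, duration/speed, and OLS
  phenotype contrasts (SW−SE, S−mean(SW,SE), NW−SW) with backward
  elimination of nuisance covariates at p > 0.10.
* **Mating simulation** — multinomial cohorts, per-phenotype arrival-date
  models, and arrival-window mate choice, quantifying how much earlier
  arrival of intermediate birds raises like-with-like pairing.
* **Recovery filtering** — reduction of EURING-style ringing recoveries
  to directed southward movements from the breeding region.
* **Synthetic data** — seeded generators for cohorts, geolocator-like
  tracks (with equinox-inflated latitude noise), arrivals and recoveries,
  with ground truth attached, so the whole pipeline is testable end to
  end without field data.

See `docs/methods.md` for the models, defaults and design choices.

## Worked example

Run the whole pipeline on synthetic data:

```sh
migdivide all --outdir out --seed 42
```

which logs, among other artifacts,

```
simulated 160 birds -> out
cline centre 14.039 E, width 20.2 km
mean both-S pairing fraction 0.407
retained 5 of 26 recoveries
```

`out/cline_fit.json` then holds the fitted cline — for this seed a centre
of 14.04° E with a 2LL support interval of [14.00, 14.08] and a width of
20 km (2LL [13, 30] km): one 160-bird draw from a divide generated at
centre 14.0° E / width 27 km, so the point estimate sits inside its own
support interval and the truth inside the estimate's.
`out/timing_contrasts.csv` holds the phenotype timing contrasts; at this
seed the intermediate-vs-SW/SE arrival contrast is −7.9 days
(t₁₅₀ = −7.1), recovering the generating −8.9-day shift within its
standard error, while the SW-vs-SE contrast is 0.5 ± 1.3 days (truth 0).
The mating summary shows timing-dependent pairing raising the both-S
fraction to 0.41 against the analytic timing-independent null of
0.537² ≈ 0.29.

The same machinery is available as a library:

```python
from migdivide import (SimConfig, generate_divide_cohort, make_groups,
                       fit_cline, lon_width_to_km)

cohort = generate_divide_cohort(SimConfig(rng_seed=1))
groups = make_groups(cohort.breed_lon, cohort.direction_deg, cohort.zone,
                     min_size=4)
fit = fit_cline(groups, seed=1)
print(fit.params.center, lon_width_to_km(fit.params.width, 47.6))
```

## Input formats

CSV throughout: bird summaries (`bird_id, year, sex, region, breed_lat,
breed_lon, winter_lat, winter_lon, ...`), long-format daily tracks
(`bird_id, season, date, lat, lon, spread_km`), and minimal
EURING-2000-style recoveries (`ring_id, date1, lat1, lon1, date2, lat2,
lon2` — ring number plus date/position of the ringing and re-encounter
events; no dependence on the full EURING exchange-code dictionary).

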