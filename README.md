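# airtrace

Activity-based assessment of exposure to traffic-related air pollution
(NOx), for exposure scientists, environmental epidemiologists, and
environmental-justice researchers who want to quantify how daily travel and
activity patterns — not just home address — shape who breathes what.

Conventional large-sample studies assign each person the pollutant
concentration at their residence. `airtrace` instead routes each person's
24-hour travel diary over a road network (shortest free-flow-time paths,
discretized every 100 m of path length), matches every element of the
resulting space–time trace to a diurnally varying 1-km gridded concentration
field, and compares the two exposure measures person-day by person-day.

## The quantities computed

Both exposure measures are time-weighted means *C* = (1/*T*)∫*c dt* over a
person-day (*T* = 24 h):

- **Activity-based** *C_A* = (Σ *c_σ* Δ*t_σ*)/*T* over every discretized
  space–time location *σ* visited during the day;
- **Residence-based** *C_R* = (Σ *c_τ* Δ*t_τ*)/*T* over the 24 hourly
  concentrations *c_τ* at the residence cell (Δ*t_τ* = 1 h);
- **Exposure error** 100·(*C_A* − *C_R*)/*C_A*, positive when the
  address-only estimate understates true exposure;
- **Bias factor**: the OLS slope of *C_A* on *C_R* across the sample —
  below 1 means relative-risk estimates using the residence-based surrogate
  are attenuated toward the null;
- **Disparity statistics**: group means with 95 % CIs, one-way ANOVA with
  Games–Howell post hoc pairwise tests, and a hierarchical stepwise OLS
  *C_A* = β₀ + Σβᵢ*X_cᵢ* + γ·hours-away + ε with sociodemographic, income,
  urbanicity, and activity-time blocks entered in that order (backward
  elimination at p < 0.05 within each block).

Because survey microdata and dispersion-model output are rarely
redistributable, the package includes a first-class synthetic-city generator
(`airtrace.synthetic_city`): a planar grid network with arterial roads,
urban/suburban/second-city/rural zones, a diurnal concentration field with
commute peaks and roadway enhancement, and a diary population whose
sociodemographics are residentially sorted by urbanicity, so configured
exposure disparities are recoverable end to end.

## Worked example

```bash
airtrace generate --seed 1 --output-dir demo   # network, field, diaries
airtrace run --seed 1 --output-dir demo        # exposures, stats, report
cat demo/report.txt
```

which prints (this exact output, seed 1, default 500-household city):

```
airtrace run report
===================
person-days analyzed: 749 (140 with no travel; 0 excluded, 0 rejected rows)
mean activity-based exposure C_A: 17.12 ug/m3 (range 8.50-40.57)
mean residence-based exposure C_R: 16.41 ug/m3
mean exposure error: 5.76 % (range -64.9 to 64.9; 60 % positive)
bias factor (all / traveling): 0.833 / 0.795
mean contribution to daily exposure (%): at_residence 78.0, nonresidential 17.6, in_travel 4.4
regression: R2 0.348, adj R2 0.344, n 749
  retained: black, urban, suburban, second_city, hours_away
  dropped: age_5_18, hispanic, age_46_65, age_19_45, male, asian, middle_income, below_poverty
```

Reading the numbers: the mean activity-based exposure (17.12 μg/m³ NOx)
exceeds the residence-based mean (16.41), a mean error of 5.8 % — ignoring
where people actually go understates population exposure here.  The bias
factor 0.833 says a health study regressing outcomes on the residence-based
surrogate would attenuate relative risks by ~17 %.  Urbanicity dominates the
regression (urban residents ~8 μg/m³ above rural at equal covariates), and
because the black group is residentially concentrated in the urban core, it
carries a higher group mean — the configured disparity, recovered from the
diaries alone.

The output directory also contains `exposure.csv` (one row per person-day),
`group_stats.csv` (group distribution statistics for exposure and error),
`regression.csv` (coefficients, t, p), `pairwise_tests.csv`
(ANOVA + Games–Howell), and `summary.json`.

Every stage is also available as a library call (`airtrace.pipeline`,
`airtrace.routing.shortest_time_path`, `airtrace.exposure.activity_exposure`,
…) and as individual subcommands (`generate`, `filter`, `route`, `expose`,
`stats`, `report`).

## Diary CSV schema

One `person` row per person-day followed by its `trip` rows:

- person columns: `person_id, household_id, age_group` (5-18 / 19-45 /
  46-65 / >65), race/ethnicity flags `black, hispanic, white, asian`
  (non-exclusive, 0/1), `income_category` (below_poverty / middle / higher),
  `gender`, `urbanicity` (urban / suburban / second_city / rural),
  `res_x, res_y` (meters, planar);
- trip columns: `origin_x, origin_y, dest_x, dest_y, start_min, travel_min,
  dwell_min, purpose` (home / work / meals / travel / other).

Purposes map to activity categories as home → at-residence, travel →
in-travel, everything else → nonresidential.

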