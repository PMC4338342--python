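# Methods

This note documents the models and procedures implemented in `airtrace`, the
assumptions behind them, the defaults of the synthetic-city generator, and
the numerical choices that affect results.

## Exposure model

The unit of analysis is the *person-day*: one individual's sociodemographic
attributes, residence location, and ordered out-of-home trips over a 24-hour
survey day.  Exposure is the time-weighted mean ambient concentration
*C* = (1/*T*)∫*c dt* with *T* = 24 h, evaluated two ways:

- **Residence-based** *C_R*: the mean of the 24 hourly concentrations at the
  residence grid cell.  This is the conventional address-only estimate.
- **Activity-based** *C_A*: the person-day is expanded into a gapless
  space–time trace — dwell episodes as fixed points, travel episodes as
  points sampled every 100 m along the routed path — and each trace element
  contributes *c*(x, y, t)·Δt.

The **exposure error** is 100·(*C_A* − *C_R*)/*C_A*; positive values mean
the residence-based approach underestimates.  The **bias factor** is the OLS
slope of *C_A* on *C_R* across the sample, the standard surrogate-exposure
attenuation slope for simple linear health models: a slope *b* < 1 implies
relative risks estimated against the surrogate are attenuated by ≈(1 − *b*).
It requires variation in *C_R* and at least three pairs.

Subperiod exposures *E* = Σ*c*Δt (in (μg/m³)·h) are accumulated separately
for the three activity-location categories (at-residence, nonresidential,
in-travel, mapped from trip purposes: home → at-residence, travel →
in-travel, work/meals/other → nonresidential), and per-category percentage
contributions are reported.  By construction Σ_kind *E* = 24·*C_A*.

## Diaries: validation, filtering, timelines

Time is minutes from midnight on half-open intervals [start, start+dur), so
hour-boundary splitting and the 24-h partition are unambiguous.  Records are
cleaned in three total, idempotent steps:

1. **Parse-time rejection** (row level): malformed numerics, unknown
   categories, non-positive travel, negative dwell, and persons under 5
   years (outside the survey's coverage) are rejected with line numbers.
2. **Filtering** (record level) with machine-readable reasons:
   `missing` (incomplete attributes), `inconsistent` (overlapping or
   out-of-order trips, a trip chain whose origins deviate more than 1 m from
   the previous destination, first trip not starting at the residence), and
   `out_of_domain` (any endpoint outside the concentration grid — the
   analogue of excluding travel beyond the study-area boundary).  The
   consistency rules are our operationalization; survey practice does not
   enumerate them.
3. **Paring to [0, 1440)**: trips outside the day are dropped; a dwell
   crossing midnight is truncated; travel in progress at midnight keeps only
   the in-day portion of its travel time (the trace is clipped
   proportionally in time).  A record whose trips all fall outside the day
   is an error, since the person's in-day whereabouts are unknown.

A kept record partitions the day exactly into episodes; a zero-trip record
is one 1440-minute at-residence episode.  Durations are generated in whole
minutes; any float residue from fractional inputs is absorbed into the final
episode so the partition sums to exactly 1440.

## Routing and discretization

Trips are routed on an undirected network weighted by free-flow link time
(length/speed).  Undirected traversal is appropriate because free-flow times
are symmetric and the synthetic networks carry no one-way attributes; there
is no congestion, time-of-day weighting, or turn penalty, and the computed
route is acknowledged to be an estimate of the actual path.  Trip endpoints
snap to the nearest node (ties to the smaller id); sub-link precision is
immaterial at 1-km concentration cells.

Dijkstra's algorithm is implemented with a fully deterministic tie-break:
among equal-time paths, fewer links first, then the lexicographically
smallest node sequence.  The label (time, hops, node-sequence) is
lexicographically consistent under path extension, so the first settlement
of a node is optimal.

Each routed path is sampled at arc lengths 0, 100, 200, … m plus the
terminal endpoint (duplicate suppressed).  Link times are rescaled by the
ratio of the diary's reported travel time to the free-flow estimate, and
each sample receives the scaled traversal time of the arc span running from
the midpoint toward the previous sample to the midpoint toward the next
(end samples extend to the path ends).  Midpoint-span weighting is chosen
over an equal split because it makes Σdt exact and weights samples by local
scaled speed; sampling conventions do not dictate the weight assignment, and
this is one defensible reading.  The final span absorbs float residue so
per-trip time is conserved exactly (< 1e-9 min in tests).

## Concentration field

A `ConcentrationField` is 24 hourly layers on a regular planar grid (default
1-km cells), the average diurnal cycle of a pollutant.  Multi-day hourly
stacks are reduced by averaging each hour-of-day across days.  Lookups are
piecewise constant in space (half-open cell assignment; boundary points
belong to the higher-index cell) and in time (hour = ⌊minute/60⌋): no
interpolation, mirroring polygon-intersect receptor assignment.
Interpolation between receptors would change results and is deliberately not
offered.  Out-of-domain lookups raise by default; a clamp-to-edge flag
exists for robustness experiments but is off by default, consistent with
excluding out-of-domain travel at the filtering stage.

## Disparity statistics

Group summaries report n, mean, a t-based 95 % CI (correct for small
groups), min/max, and percentiles (5/25/50/75/95, linear interpolation).
Significance testing uses one-way ANOVA followed by Games–Howell post hoc
pairwise comparisons, which do not assume equal variances or group sizes:
for groups *i*, *j*, se = √(s²ᵢ/nᵢ + s²ⱼ/nⱼ), q* = |mᵢ − mⱼ|·√2/se,
Welch–Satterthwaite df (used unrounded), p from the upper tail of the
studentized range distribution with k groups.  With k = 2 this reduces to
the Welch t test, and under homoscedastic equal-n designs it approaches
Tukey's HSD — both identities are exercised in the test suite, along with a
cross-check against an independent implementation.  Paired t tests compare
*C_A* with *C_R*; zero-variance differences are handled explicitly (all-zero
→ p = 1; constant nonzero → reported as an exact shift).

The exposure regression is a hierarchical stepwise OLS.  Binary 0/1
predictors are entered in blocks — (1) gender, age group, race/ethnicity;
(2) income categories; (3) urbanicity categories; (4) continuous hours away
from the residence — so that sociodemographic effects are controlled before
urban-form and activity effects enter.  Within each block the least
significant candidate with p ≥ 0.05 is dropped and the model refit, one at a
time; predictors retained in earlier blocks are never re-dropped (the
alternative — allowing earlier predictors to fall out when later blocks
enter — is defensible but makes the hierarchy moot; dropped predictors are
reported explicitly instead).  The reference profile is nonblack,
non-Hispanic, non-Asian, female, over 65, higher income, rural residence, no
time away.  Rank-deficient designs raise a collinearity error naming suspect
columns.  Interaction terms are elementwise products appended as `a×b`
columns.

## Risk scaling and gas conversion

Literature concentration–response slopes are taken as given constants
(percent excess risk per unit NO2).  An NOx group-mean difference is
converted to the slope's unit — multiplied by the NO2 mass fraction
(default 0.8, typical of a traffic-dominated airshed) and, for ppbv slopes,
converted with the ideal-gas molar volume V_m = 22.414·(T/273.15)/P L/mol
(24.47 at the 25 °C, 1 atm defaults) and MW(NO2) = 46.01 g/mol — then scaled
linearly.  The fraction is applied in all risk conversions, including the
mass-unit mortality slope; conversion constants can be overridden per call.

## Synthetic city: what it emulates, and what it does not

The generator stands in for three study inputs that are typically
proprietary: a navigation-grade road network, survey travel diaries, and
dispersion-model concentration fields.

- **Network**: an n×n planar grid (default 15×15, 1-km spacing) with every
  5th row/column an arterial (22.4 m/s vs 13.4 m/s local, ≈50/30 mph).
  Coordinates are planar meters from the southwest corner; no geographic
  projection is used since all inputs are synthetic (readers accept lon/lat
  only via an affine pre-transform declared by the caller).
- **Urbanicity**: an urban core (r < 3 km from the center), discrete
  second-city disks (default two pockets of r = 1.5 km beyond the suburban
  ring), a suburban ring (r < 6.5 km), rural elsewhere.  Half-open
  convention: a point exactly on an inner boundary belongs to the outer
  zone.
- **Field**: background 8 μg/m³ + a 12 μg/m³ Gaussian urban bump (scale =
  urban radius) + 6 μg/m³ Gaussian kernels around each arterial link
  (scale 300 m — the simplest field that concentrates mass along major
  roadways), all multiplied by a 24-value diurnal profile with a sharp
  morning commute peak (06–08, max 1.8 at 07) and a broader, slightly lower
  evening peak (17–21).  Values are positive everywhere; the urban core
  exceeds the rural corners at every hour.
- **Population** (default 500 households, 1–2 persons each): households pick
  a residence node with zone-dependent density weights (urban and
  second-city denser), then draw race/ethnicity and income from
  zone-conditional probabilities — residential sorting strong enough that
  group exposure disparities are recoverable downstream.  About 19.5 % of
  person-days have no travel, matching the share of zero-travel records in
  county-scale travel surveys.  The rest make one home-anchored tour of 1–4
  stops: destinations drawn with exponential distance decay (4-km scale) and
  a 3× attraction premium for urban-core nodes (employment concentrates
  downtown — this is also what sends travelers into higher-concentration
  cells); start times from a commute-peaked mixture (60 % N(08:00, 1 h),
  else N(11:00, 2 h)); first stops of working-age adults are work dwells
  (N(470, 60) min) with 55 % probability, other dwells lognormal (median
  ≈55 min); reported travel times are Manhattan-distance estimates inflated
  by Uniform(1.1, 1.5), so they differ from free-flow routing times and
  exercise the link-time rescaling.  Schedules that cannot close at the
  residence by minute 1440 are redrawn (bounded retries).  Trip-rate and
  dwell distributions are free parameters chosen once as plausible for a
  sprawling mid-size county, not calibrated claims.

Randomness derives from a single seed through per-household and per-person
counter substreams, so populations are reproducible independently of
generation order, and identical configurations yield byte-identical output
files.

What the generator does **not** emulate: emissions, meteorology, or
chemistry (the field is a parametric pattern, not a dispersion model);
survey weighting, geocoding error, multi-day records, congestion, route
choice heterogeneity, or indoor/microenvironment concentrations.  Passing
tests therefore demonstrate the correctness and internal consistency of the
estimation machinery and the recoverability of configured disparities — not
the realism of any particular city's exposure distribution.

## Numerical choices and problem sizes

- Exact conservation: trace time per day (1440 min) and per trip (reported
  time) are enforced by absorbing float residue into the final span.
- The residence-based and activity-based accumulations use the same
  operation sequence, so zero-travel days give *C_A* = *C_R* and error 0
  machine-exactly.
- Integration correctness is checked against a 1-second Riemann oracle on
  traces with integer-second boundaries (where the oracle is exact),
  rel. tol. 1e-6; routing against exhaustive path enumeration on graphs of
  ≤ 8 nodes.
- Defaults for demonstration and testing: a 15×15-node city with 500
  households (≈750 person-days) runs the full pipeline in ~1 s; the test
  suite uses 80–150-household cities for end-to-end checks and 2000
  households where an estimator's sampling error must sit well inside a
  ±0.05 Monte-Carlo tolerance.
- Stepwise significance is fixed at two-sided p < 0.05.  Welch df are used
  unrounded.  Ties in backward elimination are broken by dropping the
  largest p first, one predictor per refit.

## Known limitations

Single pollutant; ambient concentrations only (no inhalation/dose modeling
or infiltration); shortest-time routes may not coincide with actual paths;
no household-cluster random effects in the regression (person-days from the
same household are treated as independent, as in the reference analysis
design); the synthetic field's spatial covariance is far smoother than real
dispersion output, which likely narrows the exposure-error distribution
relative to a real study area.
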