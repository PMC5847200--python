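# Methods

This note documents the models and procedures implemented in
`swiftascent`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate about real tag
data.

## Sensor model

A tag records light and an activity score every 5 minutes and pressure
and temperature every 30 minutes, all timestamped in UTC. Activity is the
cumulative absolute change of vertical acceleration over a 3.2-s burst
sampled at 10 Hz (32 samples); pitch is the burst mean. Deployed tags
store only these summaries, so the pipeline consumes activity scores and
the burst conversions exist mainly for the generator. Dropouts are kept
as NaN on the sampling grid and never interpolated at this layer; each
downstream statistic declares its own coverage requirement. Pitch is
carried through I/O but enters no analysis.

## Twilight detection and the unnatural-event rule

Dawn is the last upward crossing of the light threshold each morning and
dusk the first downward crossing each evening. Concretely, daylight
blocks are maximal runs strictly above the threshold; dips shorter than
30 min and flickers shorter than 3 h are absorbed, which implements
exactly the last-up/first-down convention in the presence of sensor
noise. Crossing times are linearly interpolated between the bracketing
5-min samples; a sample exactly at the threshold counts as night, so a
crossing beginning there is assigned to the interval starting at that
sample.

An event is **unnatural** when any single 5-min light step within ±30 min
reaches 80% of the sensor's dynamic range (boundary inclusive). Cavity
steps are usually screened by eye; the fractional-step rule makes that
judgement quantitative and reproducible, and the fraction is
configuration. Unnatural events are excluded from positioning, their
positions are interpolated (colony-pinned outside the span of natural
events), and their timestamps are replaced by the astronomical sun-event
time at that position: a cavity exit records when the bird moved, not
when the sun crossed the threshold, and using the raw step time would
systematically misplace the twilight-altitude window (we measured
spurious positive "ascents" at breeding dawns before this substitution).

## Solar geometry

Standard low-precision almanac series (Julian-century polynomials for the
solar longitude, anomaly, obliquity and the equation of time) give
geometric solar elevation; no refraction term is applied, and the twilight
threshold elevation absorbs any constant offset. Declination agrees with
published solstice values to < 0.05° and the equation of time with its
published extremes to < 0.3 min. `twilight_time` finds the crossing of a
configured elevation (0° sun events by default; −6°/−12° civil and
nautical bounds available) by Brent root-finding to < 1 s; the gridded
closed-form solution (hour-angle equation) agrees with it to < 1.5 min
and is used where thousands of cells are evaluated per event.

## Grid hidden Markov positioning

A deliberately simple stand-in for template-fit geolocation with the same
output contract: a probability map per sun event.

* **State space**: 1° cells (centres), default −5…60° N, −25…42° E.
* **Emission**: Gaussian in the observed-minus-predicted twilight time,
  sd 8 min by default; the prediction uses the sun elevation the light
  threshold corresponds to (−3.5° for the generator's light curve — the
  calibration a template fit would estimate). Cells where the sun never
  crosses that elevation get zero likelihood; a uniform mixture floor of
  1e-6 guards against outlier twilights and numerical underflow.
* **Transition**: an isotropic Gaussian blur, sd 1°/event (0.5° and a
  2-min emission sd for noise-free checks), renormalised on the bounded
  grid.
* **Smoothing**: scaled forward–backward; verified against brute-force
  path enumeration on a 4-cell toy to 1e-9.

Median positions are weighted medians of the marginal lat/lon masses.
Around the equinoxes latitude is weakly identified — the posterior's
latitude spread exceeds its longitude spread, and the dominant positional
error of a simulated cohort is equinox-season latitude, exactly the
ambiguity the bootstrap machinery exists to propagate. Track bootstrap:
one cell drawn independently per event from its posterior; unnatural
events are interpolated along the drawn track.

## Altimetry and the ascent statistic

Altitude ASL from the international barometric formula with T₀ =
288.15 K, lapse 0.0065 K/m, κ = 1.235 (exponent 0.235/1.235); p₀ comes
from the weather grid at the interpolated median position. Altitudes are
strictly ASL — coarse light-level positions rule out terrain-referenced
heights.

The twilight altitude is the mean of the two samples nearest the event
(±90-min search window, ties to the earlier sample); the baseline is the
mean over 6 h each side of the event excluding ±30 min around it, i.e. a
12-h reference window with the twilight hour removed (such windows are
sometimes counted as 11 "clean" hours, sometimes as 12; the 6+6-h
arithmetic is what is implemented, and the half-width is configuration).
Baselines require ≥ 50% of the expected 30-min samples.
The ascent flag is inclusive at its threshold (300 m default; 100 m
supported as a robustness alternative). Sight-line utilities: horizon
distance √(2Rh) (R = 6371 km) and sunrise advance arccos(R/(R+h)) /
0.25° min⁻¹.

## Behaviour classification

Flapping when activity ≥ 30 (the generator's flapping regime 5th
percentile); resting when activity < 0.8 (resting 95th percentile) *and*
the rolling 3-h pressure variance is < 3 hPa²; gliding otherwise. The
variance window may sit centred on, trailing, or leading each sample and
the smallest of the three is kept: a purely centred window straddles the
roost entry/exit flight and mislabelled about a third of genuine resting
samples in early experiments, whereas judging a just-landed bird by the
flat part of its trace restores per-class accuracy ≥ 0.93 on the default
year. The numeric thresholds are calibrated on the generator and stored
in configuration; they are a stand-in for device-specific calibrations,
not field constants.

## Phases

Breeding < 200 km from the colony; otherwise migration at or north of
15° N (both boundaries inclusive on the migration side) and non-breeding
south of it. The distance rule is evaluated first. Probabilistic
assignment sums posterior mass over the three regions; hard labels over
sampled tracks converge to these probabilities (checked by χ² at 10,000
tracks).

## Weather annotation and the regression

Each twilight takes the 6-h forecast window containing it (boundary
events belong to the window starting there) at the nearest 2.5° cell —
bilinear interpolation would suggest precision the positions do not have.
Covariates: MSLP, 2-m temperature, relative humidity and wind speed at
1000 mbar; change factors are absolute differences to the same window
24 h earlier and later for MSLP, temperature and humidity (signs
disregarded; wind changes excluded by design). All continuous factors are
z-transformed (n−1 sd) on the dataset actually fitted; zero-variance
factors are dropped with a warning.

The ascent model is a binomial-logit GEE: AR(1) working correlation over
each individual's twilight sequence (sequence index, not clock time,
defines lag 1, so dawn→dusk and dusk→dawn are both adjacent), population
as a fixed adjustment, individuals as clusters. This is a
quasi-likelihood rendering of a penalized-quasi-likelihood mixed model
with nested random intercepts; coefficient signs, ordering and the
relevance decisions are the contract, not numeric equality with any
particular mixed-model implementation. CIs are estimate ± 2·SE. Dummy
levels whose responses are constant (quasi-separation) are dropped with a
warning rather than allowed to diverge.

**Ensemble**: the model is refitted on records re-derived from
independently resampled tracks (new phase labels and weather annotations
per draw; altitudes keep the median-position p₀, whose track-to-track
variation is second order against a 2.5° weather grid). A factor is
relevant only when it survives in, and excludes zero from, every
converged run; runs that fail to converge are excluded, and more than 20%
failures abort the ensemble. This all-intervals rule is monotone: more
runs can only remove relevance.

Supporting statistics: the one-sided Wilcoxon signed-rank test on
per-individual median ascent heights (exact for n ≤ 25 with untied ranks,
zeros dropped), and the standardised slope of 30-min altitude change on
mean activity, fitted separately for twilight-containing intervals and
all others with an individual random intercept.

## The synthetic generator

The generator defines the study conditions; its defaults are fixed once:

* **Calendar/geography**: a Swiss colony (47.47° N, 8.31° E, 385 m),
  breeding until 6 Oct, a 14-day autumn migration (~3500 km) to a West
  African site (9.5° N, 10° W), non-breeding residence until 8 Apr, a
  14-day spring migration, then breeding again. The migration legs sit a
  few weeks off the equinoxes; the equinoxes themselves fall inside the
  stationary phases, where the latitude ambiguity does least damage to
  phase labels.
* **Ascents**: per-twilight Bernoulli draws — dawn probabilities 0.5
  (non-breeding), 0.25 (migration), 0.05 (breeding), dusk odds half the
  dawn odds (so the twilight-type log-odds effect is exactly log 2).
  Drawn heights are N(266, 150²) m truncated at 30 m, putting the median
  drawn height near 266 m with roughly half of ascents above the 300-m
  threshold; accuracy checks use N(600, 60²) so truth flags are
  unambiguous. An ascent adds a rectangular bump covering exactly ±30 min
  around the event: both pressure samples nearest the twilight sit on the
  plateau while every baseline sample sits off it, making the ascent
  statistic exact on noise-free data (< 5 m; verified).
* **Altitude**: non-breeding 900 m and breeding-day 900 m bases plus a
  slow Ornstein–Uhlenbeck wobble (sd 150 m, τ 36 h); migration uses a
  per-travel-day cruising level N(1800, 450²) m switching at midday so
  twilight baseline windows stay on one level (occasionally reaching the
  2000–3000 m band); breeding nights on the ground at colony elevation.
* **Light**: a sigmoid of solar elevation (midpoint −3.5°, width 1.5°,
  full scale 64) plus Gaussian noise (sd 1). On 90% of breeding evenings
  the bird is "in the cavity" from 45 min before dusk to 30 min after
  dawn — light clamps to zero, producing the abrupt unnatural steps.
* **Activity**: flapping N(40, 6²) during migration bouts (dawn+1 h to
  dawn+9 h) and ascent windows; gliding N(3, 1.2²); resting |N(0, 0.4²)|.
* **Pressure**: the inverse barometric formula against the local
  synthetic MSLP, plus sensor noise sd 1 hPa (tags of this class agree
  with nearby stations to about 1 hPa).
* **Weather**: 2.5°, 6-hourly fields. MSLP is base 1013 hPa plus
  eastward-travelling Gaussian lows (amplitude ~12 hPa, width 8°,
  12°/day, one per ~5 days, mid-latitude storm track 28–55° N) — and
  nothing else, so zero front amplitude gives an exactly constant
  pressure field. Temperature, humidity and wind couple to the fronts
  *and* carry independent smooth wave noise, so the covariates are
  correlated but never collinear.

What the generator does **not** emulate: gradual ascent/descent ramps
(the rectangular bump decouples within-interval altitude change from
twilight intervals, so the activity–climb slope on synthetic data is
positive but much weaker than a real climbing bird would show), weather
responses of the birds (ascent draws are independent of weather — the
change factors are true nulls), terrain, wind drift, template-fit light
calibration, and tag failure modes. Passing tests therefore demonstrate
the correctness and statistical behaviour of the pipeline under known
truth, not field performance.

A documented consequence of the breeding regime: birds sit at colony
elevation through twilight but fly by day, so breeding twilight "ascent
heights" are structurally depressed (often negative) — the same pattern
colonial cavity roosters show in real data. The type-I (null-generator)
check therefore runs on the airborne season, where uniform ascent
probabilities really do make every model factor null. A related residual
effect: phase-label noise from positional uncertainty lets weather
*levels* (tropical temperature, pressure) partially proxy for the
non-breeding phase in effect runs; the ±24-h *change* factors are immune.

## Numerical and testing choices

Problem sizes were chosen to keep the whole suite in a few minutes: the
ensemble recovery check runs 6 replicate years of 6 birds (6 model runs
each) and requires the phase and twilight effects, with generated signs,
in ≥ 5 of 6 replicates; the null check runs 12 airborne-season replicates
of 4 birds and bounds each factor's flag count by a one-sided binomial
test of the 10% rate (≤ 3 of 12). Exactness oracles: a 50-digit
evaluation of the barometric formula (< 1e-6 m over pressure ratios
0.3–1), exhaustive sign-assignment enumeration for the signed-rank test
(100 random sets, n ≤ 10), and brute-force path enumeration for the HMM.
All simulations are bit-reproducible from a single seed via spawned
generator streams keyed by individual id.

## Known limitations

* The positioning likelihood ignores light-curve shape (template fit),
  land/sea masks and twilight-error asymmetry; its error model is
  calibrated to the generator, not to any tag model.
* AR(1) over the twilight sequence treats unequal gaps (including
  dropout gaps) as single lags.
* The ensemble varies tracks only; it does not propagate altimetry or
  detection uncertainty.
* Real-data mode (tag CSV + manifest + NetCDF weather) shares the grid
  contract but has only been exercised on generator-written files.
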