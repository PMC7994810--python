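# Methods

This note records the models, conventions and numerical choices behind
`plumelag`, and what the synthetic-data generators do and do not
emulate.

## Timeseries pipeline

**Weekly reduction.** Wind is averaged over non-overlapping 7-day
blocks (mean over non-missing days; a block is missing only if all
seven days are). SST and call density are subsampled — one daily value
per week, at a configurable phase 0–6 within the block — because a
block mean would smooth the very SST drops the analysis targets. Both
reductions index results by block start date on a common weekly grid,
so differently phased subsamples and weekly means stay aligned. The
grid is anchored at the first date of the record; records are expected
to begin at a natural boundary (1 January or 1 October). A continuous
7-day grid cannot align with 1 October every year (365 and 366 are not
multiples of 7), so season membership of a week is decided by its start
date.

**Decomposition.** Classical additive decomposition with period 52
weeks: trend is the centred moving average (the standard 2×52 weighted
window for the even period), seasonal is the per-phase mean of the
detrended series re-centred to sum to zero, residual is the remainder.
The trend — hence the residual — is undefined for half a period at each
edge, which is what structurally drops the first and last calendar
years of a multi-year record from the analysis. The moving average is
NaN-strict: a gap in the weekly series (e.g. a hydrophone refurbishment
break) propagates to the trend rather than being imputed. On gap-free
input the implementation agrees with
`statsmodels.tsa.seasonal.seasonal_decompose` to machine precision
(verified in the tests); a calendar year is 52.18 weeks, so the
seasonal phase drifts by about a week per decade, which is immaterial
at the 8-week lag horizon. A series spanning less than one full cycle
(a single season of call density) cannot be decomposed; it is passed
through as observed values (`weekly_residual(..., detrend=False)`).

**Cross-correlation.** For driver x and response y on a common weekly
grid, the value at lag k is the Pearson correlation of (x_t, y_{t+k})
pairs within one spring–summer season, k = 0..8 weeks. The sign
convention is fixed throughout: the driver is the first argument and
positive lags mean the response trails the driver. Missing pairs are
pairwise-deleted per lag; a lag with fewer than 3 valid pairs or zero
variance in either window is missing. Negative lags are not searched —
the physical pathway is one-directional — and the peak is chosen in the
expected direction (negative for wind→SST and SST→calls, positive for
SST→SST and wind→calls), with ties broken toward the smallest lag (the
physically proximate explanation). If no value of the expected sign
exists the least-contradictory lag is returned carrying a degenerate
flag rather than an error, so batch analyses keep running. Per-lag
means and standard errors are taken across seasons, with
marine-heatwave seasons excluded a priori from the mean and reported
separately.

**PACF and the circular–linear test.** The partial autocorrelation
diagnostic uses the Durbin–Levinson recursion on sample
autocorrelations (via statsmodels) with ±1.96/√n bounds. The
wind-speed/direction association uses the Mardia linear–circular R²
(correlations of the linear variable with cos θ and sin θ), with n·R²
referred to χ²(2); the implementation is cross-checked against
`pingouin.circ_corrcl` in the tests.

## Event-based analysis

Wind events are maximal runs of ≥ `wind_event_min_days` (default 2)
consecutive days with speed strictly above the threshold (default
5.5 m s⁻¹, the regional spring–summer mean); equality does not exceed,
and gaps in the daily record break runs. Aggregations are connected
components (single linkage) of the graph linking sightings within 7
days and 50 km of one another, kept when member whale counts sum to
≥ 5; the phrase "of one another" is ambiguous between chained and
all-pairs proximity, so the stricter clique reading is available as a
config toggle (`aggregation_mode="clique"`, greedy in date order —
exact maximal-clique partitioning is not tractable and the chain
reading is the default). The lag is start-to-start, from the most
recent event with start ≤ aggregation start within a 60-day lookback
(unbounded attribution in a sparse season would be meaningless; the
lookback and the possibility that the attributed event is still
ongoing are both surfaced in the output). Prior wind input is the count
of windy days in the 30 calendar days strictly before the aggregation
start: day −30 is included, day 0 is not, and days missing from the
record count as calm. Lag summaries are reported in weeks as days/7,
unrounded. The Poisson GLM (log link, IRLS via statsmodels) reports
coefficients, standard errors, residual deviance and the
likelihood-ratio χ²₁ against the intercept-only model. Note that the
number of *events* is not monotone in the threshold — lowering the
threshold can merge two events into one — although the set of
exceedance days is; the sensitivity table should be read with that in
mind.

## Acoustics

Spectrograms use a 2048-sample Hann window with 50% overlap at 2 kHz
(frequency step ≈ 0.98 Hz, hop 0.512 s); zero power is floored at
−120 dB so correlations stay defined on silent audio.

**Detector.** The template-correlation score is the Pearson correlation
between a template and the equally shaped spectrogram window at each
time offset, restricted to the template's frequency band, computed on
*linear spectral amplitude smoothed over 5 adjacent frequency bins*.
Two design points deserve explanation. Raw dB-domain correlation
saturates near r ≈ 0.7 for a genuine call at a 10 dB band SNR: the
per-bin power of noise fluctuates with a ~5.6 dB standard deviation
(chi-square with 2 df in the dB domain), which is comparable to the
call's own contrast, capping the attainable correlation below the 0.8
operating threshold regardless of how good the template is. Smoothing
across a few frequency bins averages that fluctuation down while
preserving the broad time–frequency ridge of a fast downsweep, and the
amplitude (rather than power or dB) domain keeps the call/background
contrast without letting the loudest bins dominate. Second, a call can
start anywhere within the 0.512 s hop, so the default template bank
(13 templates) cycles sub-hop onset phases as well as call durations;
a phase-mismatched template loses enough correlation to matter, and a
phase-matched one must exist for the score to peak. Templates are
noiseless example downsweeps clipped to a 25 dB dynamic range —
mimicking what an example call cut from a real recording looks like —
padded with one window of context either side; the call span inside
the template is carried as metadata so detections are reported at call
bounds. Candidates above threshold are merged over overlapping time
spans, keeping the best-scoring candidate's template, band, start and
duration.

**Evaluation.** Matching is greedy one-to-one in descending score; a
pair matches at ≥ 50% intersection-over-union in time *and* in
frequency. IoU was chosen because the reference criterion ("overlapped
by at least 50%") does not name a denominator; IoU is symmetric and the
strictest of the candidates (detection span or annotation span would
both be more permissive). Precision is 1 by convention when nothing was
detected. Greedy matching equals exhaustive optimal matching on all
small instances tested.

**Detection range, area, density.** The propagation model is a passive
sonar equation — transmission loss k·log₁₀(r_m) + α·r_km with
spreading coefficient k (default 15, between cylindrical and spherical,
appropriate for shallow water) and absorption α (default 0, negligible
below 100 Hz) — solved for the largest range satisfying
SL − TL ≥ NL + DT by bisection (tolerance 1e-9 km). It replaces a
full range-dependent parabolic-equation propagation model: it has no
bathymetry, sound-speed profile or bearing dependence, so the eight
radials share one range and the detection area is the regular-octagon
polygon Σ ½ r_i r_{i+1} sin 45°. What the substitute preserves is the
pipeline's contract — hourly band noise in, hourly range and area out,
strictly decreasing in noise — which is what the density
standardization needs. The detection threshold DT has no established
reference value and defaults to 10 dB, a conventional operating value
for template detectors. Ambient noise is summarized per hour as the
95th percentile of in-band (20–100 Hz) per-frame integrated power, and
daily density is calls/day over the day's mean hourly area; a day with
zero or undefined mean area yields a flagged, missing density.

## Synthetic data

The generators are pure functions of (params, seed) and exist so that
every stage has recoverable ground truth.

* **Wind** (default 11 years from 1 Jan 2009): a seasonal background
  (base 4 m s⁻¹ + 1.2 m s⁻¹ seasonal cycle peaking in late spring,
  Gaussian noise sd 0.8) plus pulsed events from a seasonally modulated
  Poisson process (18 per spring–summer season, half that rate
  off-season), each lasting a truncated-geometric 2–8 days (mean ≈ 3.2)
  with at least one calm day between events. Event days sit strictly
  above the 5.5 m s⁻¹ reference threshold and background days are
  capped just below it, which makes the injected events *exactly*
  recoverable by run detection — the property the event-rate and
  recovery tests rely on. Real wind has no such cap; tests built on
  this generator validate the detection logic, not the ambiguity of
  real near-threshold wind. The resulting spring–summer mean speed is
  ≈ 5.5 m s⁻¹, event durations average ≈ 3 days (range 2–8) and
  inter-event gaps ≈ 8 days. Direction mixes a uniform component with a
  von Mises component at 270°, the westerly weight growing with speed
  (1 − e^(−c·speed), c = 0.15; c = 0 gives an exactly null coupling for
  calibration tests).
* **SST** per box: seasonal cycle (15 °C mean, 2.5 °C amplitude peaking
  mid-February) + warming trend (0.03 °C yr⁻¹) + Gaussian noise
  (0.3 °C) + optional per-season heatwave offsets + the wind response:
  gain (−0.35 °C per m s⁻¹) times the 3-day centred moving average of
  the wind anomaly, delayed by the box's lag (default 1, 2, 2, 2 weeks
  along the plume order; smoothing reflects that upwelling integrates
  wind over an event, and keeps weekly subsampling from aliasing
  single-day pulses). The gain and noise levels are chosen for
  testability — no quantitative wind→SST gain is established for the
  emulated system — and give cross-season peak correlations around
  −0.4.
* **Sightings**: a random 30% of wind events seed one aggregation with
  lag_days ~ Poisson(exp(2.5 − 0.05 · windy days in the prior 30 d)),
  5–12 whales scattered within 15 km of a centre placed with a minimum
  separation from temporally overlapping aggregations (so clusters
  cannot merge), plus uniform background singletons (0.02 day⁻¹). The
  Poisson lag matches the analysis GLM's family, making parameter
  recovery a direct test of the fitting stage. Note the analysis
  attributes each aggregation to the most recent previous event, not
  necessarily the generating one, which attenuates but never reverses
  the negative slope — the end-to-end test asserts direction and
  significance, not magnitude.
* **Audio**: linear 100→20 Hz downsweeps (Tukey envelope, default
  1.8 s) added to pink or white noise, scaled so call RMS is `snr_db`
  above the noise RMS within the call band; annotations carry the true
  spans and an overlap flag. **Hourly noise**: baseline 108 dB re 1 µPa²
  (20–100 Hz band — the level at which the sonar-equation range is a
  few km, consistent with observed shallow-water detection distances)
  with a 2 dB diurnal cycle, 1 dB jitter and episodic 25 dB spikes.

What the generators do not emulate: spatial SST fields (box series are
generated directly), hydrodynamics of the plume, whale movement or
sighting effort, bearing-dependent propagation, and real ocean noise
spectra. Passing tests therefore demonstrate that the analysis
recovers structure of the assumed form at realistic noise levels — not
that real data meet those assumptions.

## Problem sizes and seeds

The validation suite uses the study-scale defaults where they are
cheap (11-year daily records, 1 h of audio at 2 kHz) and scales counts
to what a property needs: 50 seeded runs for lag recovery, 100/1000
seeds for GLM recovery and test size, 25-year wind records where the
end-to-end GLM check needs ≈ 200 aggregations, 20 noise-only clips of
2 min for the false-alarm check. All randomness flows through
`numpy.random.default_rng` seeds; `scripts/acceptance.py` derives every
stage's seed from its `--seed` argument.

## Known limitations

Aggregation clustering is O(n²) in sightings (fine for the thousands
typical of opportunistic archives). The clique mode is greedy, not
optimal. The weekly grid anchors at the record start rather than at
each season's 1 October (impossible on a continuous grid). The sonar
model's isotropy makes all radial ranges equal, so the octagon area is
effectively 2√2·r²; the polygon machinery is kept because per-bearing
ranges are the natural extension point for a bathymetry-aware model.
The subsampling-phase invariance of the peak lag holds for the
synthetic plume's week-aligned response; real responses at non-integer
lags could shift by one week between phases.
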