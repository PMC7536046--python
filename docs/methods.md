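# Methods

## Model and assumptions

All analytic indicator formulas come from linearising a stochastic system
about a stable equilibrium under small additive white noise, and assuming
quasi-stationarity (the control parameter drifts slowly relative to the
relaxation time).  The linearisation is an Ornstein–Uhlenbeck process in
continuous time and a first-order vector autoregression in discrete time;
its stationary variance, lag-τ autocorrelation and power spectral density
are closed forms in the dominant Jacobian eigenvalue(s) — a real λ for
fold/transcritical/pitchfork (and flip, with λ → −1), a complex pair
μ ± iω₀ for Hopf and r·e^{±iθ} for Neimark–Sacker.  The three
non-oscillatory families share one formula set and are distinguished only
as metadata; nonlinear corrections near the bifurcation are outside the
model.  For the two-dimensional oscillatory families the noise is taken
isotropic with per-coordinate amplitude σ and a single coordinate is
observed; how a 2-D Hopf system is reduced to the observed scalar is not
uniquely defined, and the formulas here are for one coordinate.

Spectral densities use the angular-frequency convention: the integral of
S(ω) over the full two-sided domain (ℝ in continuous time, (−π, π] in
discrete time) equals the stationary variance.  Estimated and analytic
spectra therefore share a scale and the canonical forms can be fitted
without unit conversion.

## Spectral indicators

**S_max.**  The peak of the spectrum scales like σ²/λ² against the
variance's σ²/λ: halving the distance to the bifurcation doubles the
variance and quadruples S_max (exact for the continuous fold, and tested
as such).  For analytic spectra the peak is found by a 4096-point grid
search plus bounded scalar refinement, except where the argmax is known
(ω = 0 for non-oscillatory families, ω = π for the flip).  For estimated
spectra S_max is the maximal bin, ties broken toward low frequency, with
the zero-frequency bin excluded.

**Akaike-weight classification.**  Three canonical forms are fitted to
each estimated spectrum by bounded least squares on linear power values:
a single Lorentzian S_fold(ω; σ, λ), the symmetric two-Lorentzian
S_hopf(ω; σ, μ, ω₀) and the flat S_null(ω; σ).  The amplitude σ² enters
each form linearly and is profiled out analytically; the remaining shape
parameters are initialised from a coarse global grid augmented with the
empirical peak frequency and half-width-at-half-maximum, then polished by
one bounded trust-region least-squares run.  ω₀ is constrained to at
least twice the frequency resolution so the hopf form cannot degenerate
into the fold form.  AIC uses the Gaussian residual-likelihood
correspondence AIC = n ln(RSS/n) + 2k with k = 2 (fold), 3 (hopf),
1 (null) and an RSS floor of 1e−12 × window variance; weights are
w_i = exp(−Δᵢ/2)/Σ exp(−Δⱼ/2).  The small-sample AICc correction is not
applied (it is available as a switch via `aic_from_rss`).  Only the
continuous-time forms are fitted, to discrete-time data too: flip data
are then read as "hopf with ω₀ ≈ π", which is the intended signal — an
oscillatory transition with period 2.

## Spectrum estimation

Welch's method averages Hamming-tapered periodograms of 50%-overlapping
segments.  Two conventions matter and are deliberate:

* Only the *window's* overall mean is removed, not each segment's.  For
  strongly reddened spectra a large share of the variance lies below the
  first frequency bin; per-segment demeaning deletes it and the exact
  variance renormalisation then inflates every remaining bin by tens of
  percent.  Instead the zero-frequency bin is estimated, kept out of the
  reported grid (it is an artifact for fitting and peak-finding on
  detrended data) but inside the variance accounting as `dc_power`, and
  the whole estimate is rescaled so the two-sided integral including that
  bin equals the window's sample variance exactly.
* The one-sided scipy output is unfolded at the DC and Nyquist bins,
  which are their own negative-frequency aliases; without this the flip
  scenario's peak bin at ω = π would be halved.

The generic `welch_spectrum` default segment length is half the input
(≥ 3 segments).  The rolling-window pipeline instead uses 40-sample
segments (`EWSConfig.welch_segment_length = 40`): at the pipeline's
~170–200-point windows this trades frequency resolution for roughly
7–9 periodogram averages, which stabilises the peak location (the
late-window flip peak then sits within one bin of π in ~9 of 10 runs)
and the form fits.  Both choices are configurable.

## Rolling-window pipeline

The analysed series is truncated at the step where the ramped parameter
crosses its deterministic bifurcation value, detrended once with a Lowess
smoother (span 0.2 of the series by default; an absolute-time span is
available for irregular use cases such as an 80-day span on daily data),
and scanned with a window of 0.4 × series length whose ends advance every
10 samples along the time grid.  Per window the pipeline reports variance
(denominator n), lag-τ autocorrelation (lagged-Pearson convention, the
`pandas.Series.autocorr` estimator, so a pure alternation gives exactly
−1), S_max and its frequency, and the three Akaike weights.  Trends are
summarised by the tie-corrected Kendall tau of each metric's point
estimate against window-end time.

Uncertainty per window comes from a stationary block bootstrap: blocks
start at uniformly random positions, lengths are geometric with a
configurable mean (default: the lag at which the window ACF falls below
1/e, clipped to [5, 40]), concatenated with circular wrap-around.  All
metrics, including the spectral fits, are recomputed on each of the 100
resamples; 95% intervals are percentile intervals.  Known limitation:
block joins bias resampled autocorrelations toward zero, so CI coverage
is near-nominal only for weakly correlated windows (~88% at lag-1 AC 0.2
in the test suite) and degrades as correlation strengthens; the intervals
are display aids, not calibrated tests.

## Study system and scenarios

The Ricker model with saturating harvest,
N_{t+1} = N_t e^{r(1−N_t/K)+σε_t} − F N_t²/(N_t²+h²), with baseline
r = 0.75, K = 10, F = 0, h = 0.75, σ = 0.04, is the synthetic test bed.
The noise multiplies the population (it enters the growth exponent), so
the effective noise amplitude falls as the population declines — exactly
the density-dependent regime where variance fails as an EWS.  Negative
populations produced by the harvest term are reset to zero (an absorbing
state of the deterministic map).  The deterministic skeleton has a
saddle-node at F ≈ 2.36 (fixed-point plus tangency conditions, solved by
bracketing the maximum of the harvest curve F(N) to 1e−10) and a
period-doubling at r = 2 (at F = 0 the fixed point is N* = K with map
derivative 1 − r; solved by bracketing to 1e−12).

Forced scenarios ramp F linearly 0 → 2.7 (fold) or r linearly 0.5 → 2.3
(flip) over 500 steps; null scenarios fix the parameter at the ramp start.
Initial populations are the stable equilibrium of the initial parameters.
Truncation steps are the ramp's bifurcation crossings, 438 (fold) and 417
(flip); nulls reuse the forced truncation so both arms have identical
window placement.  These generators emulate a single noisy observable
under a slow parameter drift; they do not emulate observation error,
irregular sampling, correlated environmental noise or multi-species
coupling, so passing tests demonstrate the method's behaviour under its
own model assumptions, not robustness to those features of field data.

## Ensemble evaluation

`run_ricker_experiment` simulates 100 forced and 100 null realisations
per scenario with seeds derived from one base seed, scores each
realisation by the Kendall tau of an indicator over its windows (the
alternative, the last-window value, is available but not the default), and
sweeps a threshold to produce the ROC; the trapezoidal AUC equals the
Mann–Whitney concordance.  Decreasing lag-1 autocorrelation is scored as
the signal in the flip scenario (the lag is half the emerging period).
The per-window bootstrap is disabled here — the scores use point
estimates — which keeps the two experiments at roughly a minute of CPU.

A forced realisation counts as "classified" when its expected form's
Akaike weight is maximal at some rolling window ending at or before
t = 300.  The count is "by t = 300" rather than at the single
window ending exactly there: a class call stands once made, and the
single-window count is markedly noisier, since one noisy spectrum can hand
a transient advantage to the hopf form mid-ramp.

The flip experiment additionally reports the fraction of forced runs
whose final-window spectral peak lies within one frequency bin of π.

## Numerical and degenerate-input choices

* Parameter recovery of the canonical fits on noiseless grids is exact to
  ≤ 1e−3 (tested); the optimiser tolerances are 1e−12.
* A constant window has undefined autocorrelation (reported as NaN) and an
  all-tied metric series has Kendall tau 0 by convention.
* Windows whose spectral fits fail carry NaN weights; bootstrap summaries
  ignore NaN resamples.
* Euler–Maruyama integrates the continuous normal forms (default
  dt = 0.01); additive noise makes the weak order sufficient for the
  spectral statistics used here.  Trajectories exceeding a configurable
  bound raise a blow-up error carrying the first crossing time.
* Seeds: every stochastic routine takes an explicit seed; ensemble child
  seeds are derived arithmetically from the base seed, and identical seeds
  reproduce trajectories bitwise.

## Problem sizes

The default experiment sizes are those of the study design: 500-step
scenarios, 100 bootstrap resamples per window for single-series analysis,
and 100 + 100 realisations per ensemble experiment.  The test suite runs
the two full ensembles once and otherwise uses 5–20-seed ensembles for
distributional checks.
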