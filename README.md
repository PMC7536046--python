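# specews — spectral early warning signals for tipping points

Many ecological, physiological and climatic systems sit near *tipping
points*: local bifurcations at which a small parameter change triggers an
abrupt shift to a contrasting regime.  Classical early warning signals
(EWS) — rising variance and autocorrelation from critical slowing down —
detect the approach of such a bifurcation but say nothing about its *type*,
and can fail outright under density-dependent noise.

`specews` implements spectral EWS that address both problems.  Linearising
the dynamics about a stable equilibrium under additive white noise gives an
Ornstein–Uhlenbeck process (continuous time) or a first-order
autoregression (discrete time) whose stationary statistics are closed
forms in the dominant Jacobian eigenvalue(s).  For the fold in continuous
time, for example,

    Var = σ²/(−2λ),   ρ(τ) = e^{λ|τ|},   S(ω) = σ²/2π · 1/(ω² + λ²),

while a Hopf pair μ ± iω₀ gives a two-Lorentzian spectrum peaked near ω₀.
Two indicators fall out of these forms:

* **S_max** — the height of the spectral peak.  It scales like σ²/λ² while
  the variance scales like σ²/λ, so halving the distance to the bifurcation
  doubles the variance but *quadruples* S_max, and works for oscillatory
  and non-oscillatory bifurcations alike.
* **Akaike weights** (w_fold, w_hopf, w_null) — a bounded least-squares fit
  of the canonical fold, hopf and flat spectral forms to each estimated
  spectrum, converted to relative support via w_i ∝ exp(−Δᵢ/2).  The
  dominant weight indicates whether the approaching transition is
  oscillatory (Hopf-like, including period-doubling read as ω₀ ≈ π) or
  non-oscillatory (fold-like spectral reddening).

The package provides, for every local codimension-1 bifurcation (fold,
transcritical, pitchfork, Hopf, flip, Neimark–Sacker):

* `bifurcations` — the closed-form variance, lag-τ autocorrelation and
  power spectrum, plus `analytic_smax`;
* `simulate` — stochastic normal-form simulators and a harvested Ricker
  population model `N_{t+1} = N_t e^{r(1−N_t/K)+σε_t} − F N_t²/(N_t²+h²)`
  with linear parameter ramps, plus numerical location of its fold
  (F ≈ 2.36) and flip (r = 2) bifurcations;
* `spectrum` — variance-normalised Welch spectra and the raw 1/n-DFT
  periodogram;
* `classify` — `SpectrumModel`/`fit_form` canonical-form fits and Akaike
  weights;
* `ews` — the `SpectralEWS` model: Lowess detrending, rolling windows,
  stationary block bootstrap, Kendall-tau trends; its `fit()` returns a
  `SpectralEWSResults` with a tidy per-window table and `summary()`;
* `evaluate` — forced-vs-null ROC/AUC experiments (`run_ricker_experiment`).

## Worked example

Simulate a harvesting-ramp (fold) scenario, compute rolling-window EWS on
the series truncated at the deterministic bifurcation crossing, and read
off the trends:

```python
import specews as s

ts, trunc = s.make_scenario("fold_forced", seed=1)      # 501 steps, F: 0 → 2.7
res = s.compute_ews(ts, s.EWSConfig(n_bootstrap=50), truncation_time=trunc)
print(res.summary())
print(res.weights_at(300.0))
```

```
Spectral EWS summary
====================
series length analysed: 439 (window 176 samples, step 10)
bootstrap: n=50, mean block length=5.0

Kendall tau trends (point estimates vs window-end time):
  ac_1       +0.508
  ac_2       +0.883
  smax       -0.126
  smax_freq  -0.141
  variance   -0.705
  w_fold     +0.803
  w_hopf     -0.778
  w_null     -0.385

{'w_fold': 0.736, 'w_hopf': 0.262, 'w_null': 0.003}
```

The signature is exactly what theory predicts for a fold under
density-dependent noise: autocorrelation rises at all lags (critical
slowing down), the variance is useless as a signal (the noise amplitude
shrinks with the declining population, here even trending down), and the
fold-form Akaike weight climbs and dominates (0.736 at t = 300) —
the spectrum is reddening, warning of a non-oscillatory transition.  In a
growth-rate-ramp (flip) scenario the same pipeline instead shows falling
lag-1/rising lag-2 autocorrelation and a dominant hopf weight with fitted
frequency near π: an oscillatory transition.

There is also a small CLI:

```sh
specews simulate --scenario flip_forced --seed 1 --out flip.csv
specews ews flip.csv --truncation-time 417 --out-prefix flip_ews
specews classify flip.csv
specews evaluate --scenario fold --n-realizations 100 --seed 1 --out-dir eval
```

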