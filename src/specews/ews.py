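"""Rolling-window early-warning-signal pipeline.

The workflow mirrors common EWS practice: truncate the series before the
transition, remove the slow trend with a Lowess smoother, slide a window
over the residuals, and within each window compute

* conventional indicators — sample variance and lag-tau autocorrelation;
* spectral indicators — the Welch spectrum's peak height S_max (and its
  frequency) and the Akaike weights of the canonical fold/hopf/null
  spectral forms.

Uncertainty per window comes from a stationary block bootstrap (blocks with
geometrically distributed lengths, preserving short-range correlation); the
trend of each indicator across windows is summarised by the Kendall tau
rank correlation against time.

The model/results interface is :class:`SpectralEWS` (construct from a
:class:`~specews.simulate.TimeSeries` plus an :class:`EWSConfig`) whose
``fit()`` returns a :class:`SpectralEWSResults` carrying the per-window
estimates, bootstrap intervals, Kendall taus and a ``summary()`` table.
:func:`compute_ews` is the functional wrapper.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .classify import FORMS, akaike_weights, fit_form
from .simulate import TimeSeries
from .spectrum import smax as spectrum_smax
from .spectrum import welch_spectrum

__all__ = [
    "EWSConfig",
    "SpectralEWS",
    "SpectralEWSResults",
    "compute_ews",
    "lowess_detrend",
    "stationary_block_bootstrap",
    "variance",
    "lag_autocorrelation",
    "kendall_tau",
    "oscillation_period",
]


def variance(segment) -> float:
    """Sample variance with denominator n."""
    return float(np.var(np.asarray(segment, dtype=float)))


def lag_autocorrelation(segment, tau: int) -> float:
    """Sample autocorrelation at lag ``tau``: the Pearson correlation between
    the segment and its ``tau``-shifted copy (the convention of pandas'
    ``Series.autocorr``).  Returns NaN for a constant segment."""
    x = np.asarray(segment, dtype=float)
    tau = int(tau)
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    if len(x) <= tau + 1:
        raise ValueError("segment too short for this lag")
    if tau == 0:
        return 1.0
    a, b = x[:-tau], x[tau:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def kendall_tau(values, times=None) -> float:
    """Tie-corrected Kendall tau-b of a metric series against time.

    An all-tied (constant) series has no defined trend and returns 0.
    """
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 3:
        return float("nan")
    t = np.arange(len(y)) if times is None else np.asarray(times, dtype=float)
    tau = stats.kendalltau(t[ok], y[ok]).statistic
    return 0.0 if np.isnan(tau) else float(tau)


def oscillation_period(omega0: float) -> float:
    """Period T = 2 pi / omega0 of the oscillation implied by a spectral
    peak (or fitted hopf frequency) at angular frequency ``omega0``."""
    if omega0 <= 0:
        raise ValueError("omega0 must be positive")
    return 2 * np.pi / omega0


def lowess_detrend(
    ts: TimeSeries,
    span: float = 0.2,
    span_time: float | None = None,
) -> tuple[TimeSeries, TimeSeries]:
    """Split a series into a Lowess trend and residuals.

    ``span`` is the smoothing fraction of the series; ``span_time`` instead
    expresses the span in absolute time units (e.g. an 80-day span for daily
    chemostat data) and overrides ``span`` when given.
    """
    if span_time is not None:
        span = span_time / (ts.times[-1] - ts.times[0])
    if not 0 < span <= 1:
        raise ValueError("lowess span must lie in (0, 1]")
    if span * len(ts) < 3:
        raise ValueError("lowess span covers fewer than 3 points per fit")
    trend = sm_lowess(ts.values, ts.times, frac=span, return_sorted=False)
    meta = dict(ts.meta)
    return (
        TimeSeries(ts.times, trend, {**meta, "component": "trend"}),
        TimeSeries(ts.times, ts.values - trend, {**meta, "component": "residuals"}),
    )


def stationary_block_bootstrap(
    segment,
    mean_block_length: float,
    n_samples: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Stationary bootstrap resamples of a segment.

    Each sample is assembled from blocks starting at uniformly random
    positions whose lengths are geometric with the given mean, concatenated
    with circular wrap-around, and trimmed to the input length.  Returns an
    array of shape ``(n_samples, len(segment))``.
    """
    x = np.asarray(segment, dtype=float)
    n = len(x)
    if mean_block_length < 1:
        raise ValueError("mean_block_length must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = min(1.0 / mean_block_length, 1.0)
    out = np.empty((n_samples, n))
    for s in range(n_samples):
        filled = 0
        while filled < n:
            start = int(rng.integers(n))
            length = min(int(rng.geometric(p)), n - filled)
            idx = (start + np.arange(length)) % n
            out[s, filled : filled + length] = x[idx]
            filled += length
    return out


def auto_block_length(segment, lo: float = 5.0, hi: float = 40.0) -> float:
    """Default bootstrap block length: the smallest lag at which the sample
    ACF drops below 1/e, clipped to [lo, hi] so that significant temporal
    correlation is retained without degenerate blocks."""
    x = np.asarray(segment, dtype=float)
    max_lag = min(len(x) - 2, int(hi) + 1)
    for tau in range(1, max_lag):
        ac = lag_autocorrelation(x, tau)
        if not np.isfinite(ac) or ac < 1.0 / np.e:
            return float(np.clip(tau, lo, hi))
    return hi


@dataclass(frozen=True)
class EWSConfig:
    """Configuration of the rolling-window EWS computation.

    window_fraction : rolling-window length as a fraction of the analysed
        (truncated) series; 0.4 by default.
    window_step : spacing of window end times, in samples.
    lowess_span / lowess_span_time : detrending span (fraction / absolute).
    ac_lags : lags (in samples) at which autocorrelation is computed.
    n_bootstrap : stationary-bootstrap samples per window (0 disables the
        bootstrap and reports point estimates only).
    mean_block_length : bootstrap mean block length; None selects it from
        the first window's ACF decay (1/e lag, clipped to [5, 40]).
    welch_segment_length : Welch segment length per window (40 samples by
        default, clamped to the window length); None uses half the window.
    spectral_weights : whether to fit the canonical forms per window.
    """

    window_fraction: float = 0.4
    window_step: int = 10
    lowess_span: float = 0.2
    lowess_span_time: float | None = None
    ac_lags: tuple[int, ...] = (1, 2)
    n_bootstrap: int = 100
    mean_block_length: float | None = None
    ci_level: float = 0.95
    welch_segment_length: int | None = 40
    welch_overlap: float = 0.5
    welch_window: str = "hamming"
    spectral_weights: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must lie in (0, 1]")
        if self.window_step < 1:
            raise ValueError("window_step must be a positive integer")
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be nonnegative")

    def replace(self, **kw) -> "EWSConfig":
        return replace(self, **kw)


_BASE_METRICS = ("variance", "smax", "smax_freq")
_WEIGHT_METRICS = ("w_fold", "w_hopf", "w_null")


class SpectralEWS:
    """Early-warning-signal model for a single univariate time series.

    Parameters
    ----------
    ts : TimeSeries
        Uniformly sampled series (e.g. one scenario realisation).
    config : EWSConfig
    truncation_time : float, optional
        Analyse only samples with time <= truncation_time (typically the
        step at which a ramped parameter crosses its bifurcation value).
    """

    def __init__(self, ts: TimeSeries, config: EWSConfig | None = None,
                 truncation_time: float | None = None):
        self.config = config or EWSConfig()
        self.truncation_time = truncation_time
        self.ts = ts.slice_time(t_end=truncation_time) if truncation_time is not None else ts
        n = len(self.ts)
        self._window_len = int(round(self.config.window_fraction * n))
        if self._window_len < 20:
            raise ValueError("window covers fewer than 20 points; series too short")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: EWSConfig | None = None,
                       truncation_time: float | None = None) -> "SpectralEWS":
        return cls(TimeSeries(df["time"].to_numpy(), df["value"].to_numpy()),
                   config, truncation_time)

    # ------------------------------------------------------------------
    def _window_metrics(self, seg: np.ndarray) -> dict[str, float]:
        cfg = self.config
        out = {"variance": variance(seg)}
        for lag in cfg.ac_lags:
            out[f"ac_{lag}"] = lag_autocorrelation(seg, lag)
        seg_len = cfg.welch_segment_length or int(np.ceil(len(seg) / 2))
        seg_len = min(seg_len, len(seg))
        try:
            est = welch_spectrum(seg, segment_length=seg_len,
                                 overlap_fraction=cfg.welch_overlap,
                                 window=cfg.welch_window, dt=self.ts.dt)
            w_peak, s_peak = spectrum_smax(est)
            out["smax"] = s_peak
            out["smax_freq"] = w_peak
            if cfg.spectral_weights:
                fits = {form: fit_form(est, form) for form in FORMS}
                wts = akaike_weights([fits[f].aic for f in FORMS])
                out["w_fold"], out["w_hopf"], out["w_null"] = wts.as_tuple()
        except (ValueError, FloatingPointError):
            for m in ("smax", "smax_freq", *(_WEIGHT_METRICS if cfg.spectral_weights else ())):
                out[m] = float("nan")
        return out

    def fit(self) -> "SpectralEWSResults":
        cfg = self.config
        trend, resid = lowess_detrend(self.ts, span=cfg.lowess_span,
                                      span_time=cfg.lowess_span_time)
        r = resid.values
        n = len(r)
        w = self._window_len
        # window ends anchored on multiples of window_step along the index
        ends = [i for i in range(n) if i % cfg.window_step == 0 and i >= w - 1]
        if not ends:
            ends = [n - 1]
        rng = np.random.default_rng(cfg.seed)

        block_len = cfg.mean_block_length
        if block_len is None and cfg.n_bootstrap > 0:
            block_len = auto_block_length(r[ends[0] - w + 1 : ends[0] + 1])

        alpha = 1 - cfg.ci_level
        records = []
        for end in ends:
            seg = r[end - w + 1 : end + 1]
            point = self._window_metrics(seg)
            boot: dict[str, list[float]] = {m: [] for m in point}
            if cfg.n_bootstrap > 0:
                samples = stationary_block_bootstrap(seg, block_len,
                                                     cfg.n_bootstrap, rng)
                for s in samples:
                    bm = self._window_metrics(s)
                    for m, v in bm.items():
                        boot[m].append(v)
            t_end = self.ts.times[end]
            for m, v in point.items():
                if cfg.n_bootstrap > 0:
                    bs = np.asarray(boot[m], dtype=float)
                    bs = bs[np.isfinite(bs)]
                    if len(bs):
                        bmean = float(np.mean(bs))
                        lo, hi = np.quantile(bs, [alpha / 2, 1 - alpha / 2])
                    else:
                        bmean, lo, hi = float("nan"), float("nan"), float("nan")
                else:
                    bmean, lo, hi = v, float("nan"), float("nan")
                records.append({"time": t_end, "metric": m, "point": v,
                                "boot_mean": bmean, "ci_lo": float(lo),
                                "ci_hi": float(hi)})
        frame = pd.DataFrame.from_records(records)
        taus = {}
        for m, grp in frame.groupby("metric"):
            taus[m] = kendall_tau(grp["point"].to_numpy(), grp["time"].to_numpy())
        return SpectralEWSResults(self, frame, pd.Series(taus, name="kendall_tau"),
                                  trend, resid, float(block_len) if block_len else None)


@dataclass
class SpectralEWSResults:
    """Per-window EWS estimates with bootstrap summaries and trend statistics.

    ``frame`` is tidy: one row per (window-end time, metric) with the point
    estimate, bootstrap mean and percentile confidence bounds.
    """

    model: SpectralEWS
    frame: pd.DataFrame
    kendall_tau: pd.Series
    trend: TimeSeries
    residuals: TimeSeries
    block_length: float | None = None

    @property
    def wide(self) -> pd.DataFrame:
        """Point estimates pivoted to one column per metric."""
        return self.frame.pivot(index="time", columns="metric", values="point")

    def metric(self, name: str) -> pd.DataFrame:
        sub = self.frame[self.frame["metric"] == name]
        if sub.empty:
            raise KeyError(f"metric {name!r} was not computed")
        return sub.set_index("time")

    def weights_at(self, time: float) -> dict[str, float] | None:
        """Akaike weights of the window ending at ``time`` (None if absent)."""
        sub = self.frame[(self.frame["time"] == time)
                         & (self.frame["metric"].isin(_WEIGHT_METRICS))]
        if sub.empty:
            return None
        return dict(zip(sub["metric"], sub["point"]))

    def summary(self) -> str:
        lines = ["Spectral EWS summary",
                 "====================",
                 f"series length analysed: {len(self.model.ts)}"
                 f" (window {self.model._window_len} samples,"
                 f" step {self.model.config.window_step})",
                 f"bootstrap: n={self.model.config.n_bootstrap},"
                 f" mean block length={self.block_length}",
                 "",
                 "Kendall tau trends (point estimates vs window-end time):"]
        for m, v in self.kendall_tau.sort_index().items():
            lines.append(f"  {m:10s} {v:+.3f}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def summary_dict(self) -> dict:
        last = self.frame["time"].max()
        out = {"kendall_tau": {m: (None if np.isnan(v) else float(v))
                               for m, v in self.kendall_tau.items()},
               "last_window_time": float(last)}
        wts = self.weights_at(last)
        if wts:
            out["final_weights"] = wts
        return out

    def to_json_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)

    def plot(self, metrics=("variance", "smax", "ac_1"), ax=None):
        """Quick-look plot of selected metrics with bootstrap bands."""
        import matplotlib.pyplot as plt

        metrics = [m for m in metrics if m in set(self.frame["metric"])]
        if ax is None:
            _, axes = plt.subplots(len(metrics), 1, sharex=True,
                                   figsize=(7, 2 * len(metrics)))
        else:
            axes = np.atleast_1d(ax)
        for a, m in zip(np.ravel(axes), metrics):
            sub = self.metric(m)
            a.plot(sub.index, sub["point"], lw=1.2, label=m)
            if np.isfinite(sub["ci_lo"]).any():
                a.fill_between(sub.index, sub["ci_lo"], sub["ci_hi"], alpha=0.3)
            a.set_ylabel(m)
            a.legend(loc="upper left", fontsize=8)
        return axes


def compute_ews(ts: TimeSeries, config: EWSConfig | None = None,
                truncation_time: float | None = None) -> SpectralEWSResults:
    """Rolling-window EWS of a series; see :class:`SpectralEWS`."""
    return SpectralEWS(ts, config, truncation_time).fit()
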