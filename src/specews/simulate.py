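"""Stochastic simulators: bifurcation normal forms and the harvested Ricker map.

Two ingredient models generate the study systems:

* the normal form of each local bifurcation driven by additive white noise,
  integrated by Euler-Maruyama in continuous time or iterated directly in
  discrete time, e.g. ``dx/dt = alpha - x^2 + sigma xi(t)`` for the fold;
* a Ricker population model with saturating (Holling type-III) harvesting,

  ``N_{t+1} = N_t exp(r (1 - N_t/K) + sigma eps_t) - F N_t^2 / (N_t^2 + h^2)``,

  which undergoes a Fold bifurcation as the maximum harvesting rate F
  increases and a Flip (period-doubling) bifurcation as the growth rate r
  increases.  Note the noise enters the exponent, so fluctuations scale with
  population size (density-dependent noise).

Forced scenarios ramp the bifurcation parameter linearly through its critical
value; null scenarios hold it fixed at the ramp's starting value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "TimeSeries",
    "ParameterSchedule",
    "RickerParams",
    "BlowUpError",
    "simulate_normal_form_continuous",
    "simulate_normal_form_discrete",
    "simulate_ricker",
    "make_scenario",
    "ricker_bifurcation_points",
    "SCENARIOS",
]

BASELINE_RICKER = dict(r=0.75, K=10.0, F=0.0, h=0.75, sigma=0.04)

#: forced-scenario ramps: parameter name, (start, end) over the 500-step run
SCENARIOS = {
    "fold_forced": ("F", (0.0, 2.7)),
    "fold_null": ("F", (0.0, 0.0)),
    "flip_forced": ("r", (0.5, 2.3)),
    "flip_null": ("r", (0.5, 0.5)),
}
SCENARIO_STEPS = 500


class BlowUpError(RuntimeError):
    """Trajectory left the configured bounds; carries the first crossing time."""

    def __init__(self, time: float, value: float):
        self.time = time
        self.value = value
        super().__init__(f"trajectory blew up (|x|={value:.3g}) at t={time:.6g}")


@dataclass
class TimeSeries:
    """Uniformly sampled univariate series with provenance metadata."""

    times: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if len(self.times) < 2:
            raise ValueError("a time series needs at least two samples")
        steps = np.diff(self.times)
        dt = steps[0]
        if dt <= 0 or not np.allclose(steps, dt, rtol=1e-9, atol=1e-12 * abs(dt)):
            raise ValueError("time stamps must be uniformly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN or infinities")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)

    def slice_time(self, t_start: float | None = None, t_end: float | None = None) -> "TimeSeries":
        """Sub-series with t_start <= t <= t_end (inclusive)."""
        mask = np.ones(len(self), dtype=bool)
        if t_start is not None:
            mask &= self.times >= t_start - 1e-12
        if t_end is not None:
            mask &= self.times <= t_end + 1e-12
        if mask.sum() < 2:
            raise ValueError("time slice leaves fewer than two samples")
        return TimeSeries(self.times[mask], self.values[mask], dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "value": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, meta: dict | None = None) -> "TimeSeries":
        df = pd.read_csv(path)
        missing = {"time", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"CSV missing column(s): {sorted(missing)}")
        return cls(df["time"].to_numpy(), df["value"].to_numpy(), meta or {})


@dataclass(frozen=True)
class ParameterSchedule:
    """Linear ramp from start_value to end_value; constant outside the ramp."""

    start_value: float
    end_value: float
    start_time: float
    end_time: float

    def __post_init__(self) -> None:
        if not self.end_time > self.start_time:
            raise ValueError("end_time must exceed start_time")

    def __call__(self, t) -> np.ndarray | float:
        frac = np.clip(
            (np.asarray(t, dtype=float) - self.start_time)
            / (self.end_time - self.start_time),
            0.0,
            1.0,
        )
        out = self.start_value + frac * (self.end_value - self.start_value)
        return out if out.shape else float(out)

    @classmethod
    def constant(cls, value: float, t_end: float = 1.0) -> "ParameterSchedule":
        return cls(value, value, 0.0, max(t_end, 1.0))


@dataclass(frozen=True)
class RickerParams:
    """Parameters of the harvested Ricker model (baseline values as defaults)."""

    r: float = 0.75
    K: float = 10.0
    F: float = 0.0
    h: float = 0.75
    sigma: float = 0.04

    def __post_init__(self) -> None:
        if self.K <= 0 or self.h <= 0:
            raise ValueError("K and h must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def _as_schedule(alpha, t_end: float) -> ParameterSchedule:
    if isinstance(alpha, ParameterSchedule):
        return alpha
    return ParameterSchedule.constant(float(alpha), t_end)


def _nf_drift_continuous(family: str, x: np.ndarray, alpha: float) -> np.ndarray:
    if family == "fold":
        return np.array([alpha - x[0] ** 2])
    if family == "transcritical":
        return np.array([alpha * x[0] - x[0] ** 2])
    if family == "pitchfork":
        return np.array([alpha * x[0] - x[0] ** 3])
    if family == "hopf":
        # supercritical Hopf with unit angular frequency at onset
        r2 = x[0] ** 2 + x[1] ** 2
        return np.array(
            [alpha * x[0] - x[1] - x[0] * r2, x[0] + alpha * x[1] - x[1] * r2]
        )
    raise ValueError(f"unknown continuous-time family {family!r}")


def simulate_normal_form_continuous(
    family: str,
    alpha,
    sigma: float,
    dt: float = 0.01,
    t_end: float = 100.0,
    x0=None,
    seed: int = 0,
    blowup_bound: float = 1e6,
) -> TimeSeries:
    """Euler-Maruyama trajectory of a continuous-time normal form.

    ``alpha`` may be a number or a :class:`ParameterSchedule`.  Gaussian
    increments have standard deviation ``sigma*sqrt(dt)``.  For the Hopf
    family the state is two-dimensional (noise on both coordinates) and the
    first coordinate is observed.  Raises :class:`BlowUpError` when |x|
    exceeds ``blowup_bound``, reporting the first crossing time.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    sched = _as_schedule(alpha, t_end)
    ndim = 2 if family == "hopf" else 1
    if x0 is None:
        x = np.zeros(ndim)
    else:
        x = np.atleast_1d(np.asarray(x0, dtype=float))
        if x.shape != (ndim,):
            raise ValueError(f"x0 must have {ndim} component(s) for {family}")
    rng = np.random.default_rng(seed)
    n = int(round(t_end / dt))
    times = np.arange(n + 1) * dt
    out = np.empty(n + 1)
    out[0] = x[0]
    sqdt = np.sqrt(dt)
    for i in range(1, n + 1):
        a = sched(times[i - 1])
        x = x + _nf_drift_continuous(family, x, a) * dt + sigma * sqdt * rng.standard_normal(ndim)
        if np.max(np.abs(x)) > blowup_bound:
            raise BlowUpError(times[i], float(np.max(np.abs(x))))
        out[i] = x[0]
    return TimeSeries(
        times,
        out,
        {"model": f"normal_form_continuous:{family}", "seed": seed, "dt": dt,
         "sigma": sigma, "alpha": (sched.start_value, sched.end_value)},
    )


def _nf_map_discrete(family: str, x: float, alpha: float) -> float:
    if family == "fold":
        return x + alpha - x**2
    if family == "transcritical":
        return x + alpha * x - x**2
    if family == "pitchfork":
        return x + alpha * x - x**3
    if family == "flip":
        # period-doubling normal form: eigenvalue -(1+alpha) at the origin
        return -(1.0 + alpha) * x + x**3
    raise ValueError(f"unknown discrete-time family {family!r}")


def simulate_normal_form_discrete(
    family: str,
    alpha,
    sigma: float,
    n_steps: int = 1000,
    x0: float = 0.0,
    seed: int = 0,
    blowup_bound: float = 1e6,
) -> TimeSeries:
    """Iterate a discrete-time normal form with additive Gaussian noise."""
    sched = _as_schedule(alpha, float(n_steps))
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n_steps)
    out = np.empty(n_steps + 1)
    out[0] = x = float(x0)
    for t in range(n_steps):
        x = _nf_map_discrete(family, x, float(sched(t))) + sigma * eps[t]
        if abs(x) > blowup_bound:
            raise BlowUpError(float(t + 1), abs(x))
        out[t + 1] = x
    return TimeSeries(
        np.arange(n_steps + 1, dtype=float),
        out,
        {"model": f"normal_form_discrete:{family}", "seed": seed, "sigma": sigma,
         "alpha": (sched.start_value, sched.end_value)},
    )


def _ricker_step(N: float, r: float, K: float, F: float, h: float, noise: float) -> float:
    nxt = N * np.exp(r * (1.0 - N / K) + noise) - F * N**2 / (N**2 + h**2)
    return max(nxt, 0.0)


def simulate_ricker(
    params: RickerParams,
    n_steps: int = SCENARIO_STEPS,
    N0: float | None = None,
    seed: int = 0,
    r_schedule: ParameterSchedule | None = None,
    F_schedule: ParameterSchedule | None = None,
) -> TimeSeries:
    """Simulate the harvested Ricker map for ``n_steps`` steps.

    Optional schedules override the constant ``r`` / ``F`` of ``params``.
    Negative populations produced by the harvesting term are reset to zero.
    ``N0`` defaults to the stable equilibrium at the initial parameter values.
    """
    if N0 is None:
        r0 = float(r_schedule(0.0)) if r_schedule else params.r
        F0 = float(F_schedule(0.0)) if F_schedule else params.F
        N0 = ricker_equilibrium(RickerParams(r0, params.K, F0, params.h, params.sigma))
    if N0 < 0:
        raise ValueError("N0 must be nonnegative")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n_steps)
    out = np.empty(n_steps + 1)
    out[0] = N = float(N0)
    for t in range(n_steps):
        r = float(r_schedule(t)) if r_schedule else params.r
        F = float(F_schedule(t)) if F_schedule else params.F
        N = _ricker_step(N, r, params.K, F, params.h, params.sigma * eps[t])
        out[t + 1] = N
    return TimeSeries(
        np.arange(n_steps + 1, dtype=float),
        out,
        {"model": "ricker", "seed": seed, "params": params.__dict__.copy()},
    )


def _ricker_map(N, r, K, F, h):
    return N * np.exp(r * (1.0 - N / K)) - F * N**2 / (N**2 + h**2)


def ricker_equilibrium(params: RickerParams) -> float:
    """Stable positive fixed point of the deterministic skeleton.

    Solved numerically by bracketing N = f(N) on the branch above the
    unstable harvesting threshold; falls back to 0 when no positive stable
    equilibrium exists (post-collapse).
    """
    r, K, F, h = params.r, params.K, params.F, params.h
    g = lambda N: _ricker_map(N, r, K, F, h) - N
    # stable branch lies between the fold point and values beyond K
    hi = 2.0 * K
    grid = np.linspace(hi, K * 1e-3, 400)
    vals = g(grid)
    for a, b, va, vb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if va == 0:
            return float(a)
        if va * vb < 0:
            return float(brentq(g, b, a, xtol=1e-12))
    return 0.0


def ricker_bifurcation_points(params: RickerParams | None = None) -> tuple[float, float]:
    """Locate the deterministic Ricker bifurcation points ``(F_fold, r_flip)``.

    F_fold: the saddle-node of the harvested model at the given growth rate,
    where the fixed-point equation N = f(N) and the tangency f'(N) = 1 hold
    simultaneously.  Along the fixed-point branch the harvesting rate can be
    written as F(N) = (N e^{r(1-N/K)} - N)(N^2+h^2)/N^2, and the saddle-node
    is its maximum, located by bracketing the root of dF/dN.

    When no saddle-node exists in the searched range (e.g. weak bistability
    at small K/h ratios) F_fold is NaN.

    r_flip: the period-doubling point of the unharvested model (F = 0),
    where the fixed point N* = K has map derivative f'(K) = 1 - r = -1,
    found by bracketing f'(N*(r)) + 1 = 0 in r.
    """
    p = params or RickerParams()
    r, K, h = p.r, p.K, p.h

    def F_of_N(N):
        return (N * np.exp(r * (1.0 - N / K)) - N) * (N**2 + h**2) / N**2

    def dF(N, eps=1e-7):
        return (F_of_N(N + eps) - F_of_N(N - eps)) / (2 * eps)

    # bracket the maximum of F(N) between the low-N divergence and N = K
    grid = np.linspace(0.05 * K, K, 256)
    d = np.array([dF(N) for N in grid])
    # the saddle-node is the interior maximum of F(N) (dF: + -> -); when the
    # fixed-point branch is monotone no fold exists and NaN is reported
    F_fold = float("nan")
    for i in np.nonzero(d[:-1] * d[1:] < 0)[0]:
        if d[i] > 0 > d[i + 1]:
            N_star = brentq(dF, grid[i], grid[i + 1], xtol=1e-10)
            F_fold = float(F_of_N(N_star))
            break

    def flip_cond(rr):
        # with F=0 the positive fixed point is N*=K and f'(K) = 1 - rr
        dfdN = (1.0 - rr) * np.exp(0.0)
        return dfdN + 1.0

    r_flip = float(brentq(flip_cond, 0.5, 4.0, xtol=1e-12))
    return F_fold, r_flip


def make_scenario(name: str, seed: int = 0, params: RickerParams | None = None,
                  n_steps: int = SCENARIO_STEPS) -> tuple[TimeSeries, int]:
    """Simulate a named Ricker scenario; returns ``(series, truncation_time)``.

    ``fold_forced`` ramps harvesting F linearly 0 -> 2.7 over the run;
    ``flip_forced`` ramps growth r linearly 0.5 -> 2.3.  The matching null
    scenarios hold the parameter at the ramp's starting value.  The
    truncation time is the step at which the ramped parameter crosses the
    deterministic bifurcation value (the same step is reported for nulls so
    forced and null analyses use identical windows); the full series is
    returned.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    p = params or RickerParams()
    param_name, (start, end) = SCENARIOS[name]
    sched = ParameterSchedule(start, end, 0.0, float(n_steps))
    kwargs = {"r_schedule": sched} if param_name == "r" else {"F_schedule": sched}
    if param_name == "r":
        base = RickerParams(p.r, p.K, 0.0, p.h, p.sigma)
    else:
        base = p
    ts = simulate_ricker(base, n_steps=n_steps, seed=seed, **kwargs)
    ts.meta["scenario"] = name
    ts.meta["ramp"] = {"parameter": param_name, "start": start, "end": end}

    F_fold, r_flip = ricker_bifurcation_points(p)
    crit = {"F": F_fold, "r": r_flip}[param_name]
    ramp_name, (f_start, f_end) = SCENARIOS[name.replace("null", "forced")]
    trunc = int(np.ceil((crit - f_start) / (f_end - f_start) * n_steps))
    trunc = min(trunc, n_steps)
    ts.meta["truncation_time"] = trunc
    return ts, trunc
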