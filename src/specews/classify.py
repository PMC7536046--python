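"""Classify an estimated power spectrum by its most parsimonious canonical form.

Three candidate spectral densities are fitted to a Welch estimate by
bounded nonlinear least squares:

* ``fold``:  S(omega) = sigma^2/(2 pi) * 1/(omega^2 + lambda^2) — the
  Lorentzian preceding non-oscillatory bifurcations (spectral reddening);
* ``hopf``:  S(omega) = sigma^2/(2 pi) * [1/((omega-omega0)^2 + mu^2)
  + 1/((omega+omega0)^2 + mu^2)] — the resonant two-Lorentzian form
  preceding oscillatory bifurcations;
* ``null``:  S(omega) = sigma^2/(2 pi) — flat white-noise spectrum.

Relative support for each form is expressed through Akaike weights
``w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)`` with
``Delta_i = AIC_i - min_j AIC_j``, where the AIC uses the Gaussian
residual-likelihood correspondence ``AIC = n ln(RSS/n) + 2k``.

Because the noise amplitude enters each form as an overall factor sigma^2,
it is profiled out analytically and the optimiser searches only over the
shape parameters (lambda, or mu and omega0).

A discrete-time flip (period-doubling) bifurcation produces a spectrum
peaked at omega = pi; fitted with these continuous-time forms it is read as
"hopf" with omega0 near pi, which correctly flags an oscillatory transition.

The statsmodels-style entry point is :class:`SpectrumModel` /
:class:`SpectrumFitResults`; :func:`fit_form`, :func:`akaike_weights` and
:func:`classify_window` are thin functional wrappers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .spectrum import PowerSpectrumEstimate, welch_spectrum

__all__ = [
    "SpectrumFit",
    "AICWeights",
    "SpectrumModel",
    "fit_form",
    "aic_of_fit",
    "akaike_weights",
    "classify_window",
    "FORMS",
    "N_PARAMS",
]

FORMS = ("fold", "hopf", "null")
N_PARAMS = {"fold": 2, "hopf": 3, "null": 1}

#: relative RSS floor, as a fraction of total power, guarding AIC -> -inf
RSS_FLOOR_FRAC = 1e-12


def spectral_form(form: str, omega: np.ndarray, sigma: float,
                  lam: float = np.nan, mu: float = np.nan,
                  omega0: float = np.nan) -> np.ndarray:
    """Evaluate a canonical spectral form on an angular-frequency grid."""
    w = np.asarray(omega, dtype=float)
    s2 = sigma**2
    if form == "fold":
        return s2 / (2 * np.pi) / (w**2 + lam**2)
    if form == "hopf":
        return s2 / (2 * np.pi) * (
            1.0 / ((w - omega0) ** 2 + mu**2) + 1.0 / ((w + omega0) ** 2 + mu**2)
        )
    if form == "null":
        return np.full_like(w, s2 / (2 * np.pi))
    raise ValueError(f"unknown spectral form {form!r}")


@dataclass
class SpectrumFit:
    """Result of fitting one canonical form to an estimated spectrum."""

    form: str
    sigma_hat: float
    rss: float
    n_points: int
    aic: float
    lam_hat: float = np.nan
    mu_hat: float = np.nan
    omega0_hat: float = np.nan
    converged: bool = True

    @property
    def n_params(self) -> int:
        return N_PARAMS[self.form]

    def predict(self, omega) -> np.ndarray:
        return spectral_form(self.form, omega, self.sigma_hat,
                             self.lam_hat, self.mu_hat, self.omega0_hat)

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "sigma_hat": self.sigma_hat,
            "lam_hat": None if math.isnan(self.lam_hat) else self.lam_hat,
            "mu_hat": None if math.isnan(self.mu_hat) else self.mu_hat,
            "omega0_hat": None if math.isnan(self.omega0_hat) else self.omega0_hat,
            "rss": self.rss,
            "n_points": self.n_points,
            "aic": self.aic,
            "converged": self.converged,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass(frozen=True)
class AICWeights:
    """Normalised Akaike weights over the three candidate forms."""

    w_fold: float
    w_hopf: float
    w_null: float

    def __post_init__(self) -> None:
        total = self.w_fold + self.w_hopf + self.w_null
        if not math.isclose(total, 1.0, abs_tol=1e-12):
            raise ValueError("weights must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w_fold, self.w_hopf, self.w_null)

    @property
    def dominant(self) -> str:
        return FORMS[int(np.argmax(self.as_tuple()))]


def _profiled_sigma2(shape_vals: np.ndarray, powers: np.ndarray) -> float:
    """Least-squares optimal sigma^2 for S = sigma^2 * g(omega)."""
    denom = float(np.dot(shape_vals, shape_vals))
    if denom == 0:
        return 0.0
    return max(float(np.dot(shape_vals, powers)) / denom, 0.0)


def _rss_floor(est: PowerSpectrumEstimate) -> float:
    return RSS_FLOOR_FRAC * max(est.total_power, 1e-300)


def aic_from_rss(rss: float, n: int, k: int, floor: float = 0.0) -> float:
    """AIC under the Gaussian residual likelihood: n ln(RSS/n) + 2k."""
    if n <= k:
        raise ValueError("need more data points than parameters")
    return n * math.log(max(rss, floor, 1e-300) / n) + 2 * k


def aic_of_fit(fit: SpectrumFit) -> float:
    return fit.aic


class SpectrumModel:
    """Canonical-form model for an estimated power spectrum.

    Parameters
    ----------
    est : PowerSpectrumEstimate
        Welch (or single-periodogram) estimate with at least 8 bins.
    form : str
        ``fold``, ``hopf`` or ``null``.

    ``fit()`` returns a :class:`SpectrumFit`.  The fold fit searches over
    lambda < 0 and the hopf fit over (mu < 0, omega0 >= 2 * grid
    resolution); the omega0 lower bound stops the hopf form degenerating
    into the fold form.  With the overall amplitude sigma^2 profiled out,
    the remaining shape parameters are initialised by a coarse global grid
    (augmented with the empirical peak frequency and spectral half-width)
    and polished by one bounded least-squares run.
    """

    def __init__(self, est: PowerSpectrumEstimate, form: str):
        if form not in FORMS:
            raise ValueError(f"unknown spectral form {form!r}")
        if len(est.omegas) < 8:
            raise ValueError("need at least 8 spectral bins to fit")
        self.est = est
        self.form = form

    # -- initialisation heuristics -------------------------------------
    def _half_width(self) -> float:
        p = self.est.powers
        w = self.est.omegas
        peak = float(np.max(p))
        above = w[p >= peak / 2]
        width = float(above.max() - above.min()) if len(above) > 1 else w[1] - w[0]
        return max(width / 2, w[1] - w[0])

    def fit(self) -> SpectrumFit:
        est = self.est
        w, p = est.omegas, est.powers
        n = len(w)
        floor = _rss_floor(est)
        k = N_PARAMS[self.form]

        if self.form == "null":
            c = float(np.mean(p))
            rss = float(np.sum((p - c) ** 2))
            return SpectrumFit("null", math.sqrt(2 * np.pi * c), rss, n,
                               aic_from_rss(rss, n, k, floor))

        dw = w[1] - w[0]
        hw = self._half_width()
        w_peak = float(w[int(np.argmax(p))])
        wmax = float(w[-1])

        if self.form == "fold":
            def shape(theta):
                (lam,) = theta
                return 1.0 / (2 * np.pi) / (w**2 + lam**2)
            bounds = ([-10 * wmax], [-1e-8])
            lam_grid = -np.geomspace(dw / 4, 10 * wmax, 24)
            grid = lam_grid[:, None]
        else:  # hopf
            def shape(theta):
                mu, w0 = theta
                return (1.0 / (2 * np.pi)) * (
                    1.0 / ((w - w0) ** 2 + mu**2) + 1.0 / ((w + w0) ** 2 + mu**2)
                )
            w0_min = 2 * dw
            bounds = ([-10 * wmax, w0_min], [-1e-8, wmax])
            mu_grid = -np.geomspace(dw / 4, 10 * wmax, 12)
            w0_grid = np.unique(np.clip(
                np.concatenate([np.linspace(w0_min, wmax, 12), [w_peak, hw]]),
                w0_min, wmax))
            mm, ww0 = np.meshgrid(mu_grid, w0_grid)
            grid = np.column_stack([mm.ravel(), ww0.ravel()])

        def residuals(theta):
            g = shape(theta)
            s2 = _profiled_sigma2(g, p)
            return s2 * g - p

        # coarse global search (sigma^2 profiled per grid point), then a
        # single bounded local polish from the best grid point
        G = np.stack([shape(theta) for theta in grid])
        s2s = np.clip((G @ p) / np.einsum("ij,ij->i", G, G), 0.0, None)
        rss_grid = np.sum((s2s[:, None] * G - p) ** 2, axis=1)
        theta0 = grid[int(np.argmin(rss_grid))]

        try:
            sol = least_squares(residuals, theta0, bounds=bounds,
                                method="trf", xtol=1e-12, ftol=1e-12)
            converged = bool(sol.success)
            rss = float(np.sum(sol.fun**2))
            theta = sol.x
        except Exception:
            converged = False
            rss, theta = np.inf, theta0
        if float(rss_grid.min()) < rss:
            rss, theta = float(rss_grid.min()), theta0
            converged = True
        g = shape(theta)
        s2 = _profiled_sigma2(g, p)
        sigma_hat = math.sqrt(s2)
        aic = aic_from_rss(rss, n, k, floor) if converged else np.inf
        if self.form == "fold":
            return SpectrumFit("fold", sigma_hat, rss, n, aic,
                               lam_hat=float(theta[0]), converged=converged)
        return SpectrumFit("hopf", sigma_hat, rss, n, aic,
                           mu_hat=float(theta[0]), omega0_hat=float(theta[1]),
                           converged=converged)


def fit_form(est: PowerSpectrumEstimate, form: str) -> SpectrumFit:
    """Bounded least-squares fit of one canonical form; see :class:`SpectrumModel`."""
    return SpectrumModel(est, form).fit()


def akaike_weights(aics) -> AICWeights:
    """Akaike weights from the (fold, hopf, null) AIC scores.

    Invariant under adding a constant to every AIC; an infinite AIC gets
    zero weight.  At least one score must be finite.
    """
    a = np.asarray(aics, dtype=float)
    if a.shape != (3,):
        raise ValueError("expected exactly three AIC scores (fold, hopf, null)")
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("at least one AIC must be finite")
    delta = a - a[finite].min()
    raw = np.exp(-delta / 2)  # exp(-inf) = 0: infinite AIC gets zero weight
    wts = raw / raw.sum()
    return AICWeights(*wts)


def classify_window(
    segment,
    segment_length: int | None = None,
    overlap_fraction: float = 0.5,
    window: str = "hamming",
    dt: float = 1.0,
) -> tuple[AICWeights, dict[str, SpectrumFit]]:
    """Welch spectrum of a (detrended) window, fitted by all three forms.

    Returns the Akaike weights and the per-form fits.
    """
    est = welch_spectrum(segment, segment_length=segment_length,
                         overlap_fraction=overlap_fraction, window=window, dt=dt)
    fits = {form: fit_form(est, form) for form in FORMS}
    weights = akaike_weights([fits[f].aic for f in FORMS])
    return weights, fits
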