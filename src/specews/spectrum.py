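"""Power-spectrum estimation: normalised periodograms and Welch averaging.

The raw periodogram uses the 1/n-normalised discrete Fourier transform,
``P(k) = |x~(k)|^2`` with ``x~(k) = (1/n) sum_j x_j exp(2 pi i (j-1)(k-1)/n)``,
so that ``sum_k P(k)`` equals the segment's mean square (Parseval).

Welch estimates average tapered periodograms over overlapping segments and
are reported as two-sided spectral densities on the angular-frequency grid
omega in (0, pi] (for unit sampling step), rescaled so that the numerical
integral of the symmetric two-sided extension equals the sample variance of
the analysed window.  This matches the normalisation of the analytic
spectra in :mod:`specews.bifurcations`, so estimated and theoretical
densities can be compared (and fitted) without unit conversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import TimeSeries

__all__ = ["PowerSpectrumEstimate", "periodogram", "welch_spectrum", "smax"]


@dataclass
class PowerSpectrumEstimate:
    """Two-sided spectral density sampled on a positive angular-frequency grid.

    ``dc_power`` keeps the zero-frequency bin's density out of the reported
    grid (detrending makes it an artifact for fitting and peak-finding) but
    inside the variance accounting, so steep low-frequency spectra are not
    inflated by renormalisation.
    """

    omegas: np.ndarray
    powers: np.ndarray
    n_segments: int
    segment_length: int
    total_power: float  # sample variance of the analysed window
    dt: float = 1.0
    dc_power: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omegas = np.asarray(self.omegas, dtype=float)
        self.powers = np.asarray(self.powers, dtype=float)
        if self.omegas.shape != self.powers.shape or self.omegas.ndim != 1:
            raise ValueError("omegas and powers must be 1-d arrays of equal length")
        if np.any(np.diff(self.omegas) <= 0):
            raise ValueError("omegas must be strictly increasing")
        if np.any(self.powers < 0):
            raise ValueError("powers must be nonnegative")

    def integral_two_sided(self) -> float:
        """Riemann sum of the symmetric two-sided extension over (-pi, pi]/dt.

        Each positive-frequency bin has a mirror image at -omega except the
        zero-frequency bin (``dc_power``) and the Nyquist bin at
        omega = pi/dt, which are their own aliases.
        """
        dw = self.omegas[1] - self.omegas[0] if len(self.omegas) > 1 else 2 * np.pi
        weights = np.full(len(self.omegas), 2.0)
        if np.isclose(self.omegas[-1], np.pi / self.dt, rtol=1e-9):
            weights[-1] = 1.0
        return float((np.sum(weights * self.powers) + self.dc_power) * dw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"omega": self.omegas, "power": self.powers})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def periodogram(segment: np.ndarray) -> np.ndarray:
    """Raw power per DFT bin, ``P(k) = |(1/n) DFT(x)|^2``.

    Requires n >= 4 samples with the mean already removed; returns all n
    bins (k = 0, ..., n-1).  Under this convention
    ``sum_k P(k) = (1/n) sum_j x_j^2``.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("segment must be 1-d with at least 4 samples")
    return np.abs(np.fft.fft(x) / len(x)) ** 2


def welch_spectrum(
    ts: TimeSeries | np.ndarray,
    segment_length: int | None = None,
    overlap_fraction: float = 0.5,
    window: str = "hamming",
    dt: float | None = None,
) -> PowerSpectrumEstimate:
    """Welch estimate of the two-sided spectral density on omega in (0, pi/dt].

    Periodograms of tapered, ``overlap_fraction``-overlapping segments are
    averaged and exactly rescaled so the two-sided integral (including the
    zero-frequency bin, kept aside as ``dc_power``) equals the window's
    sample variance.  Only the window's overall mean is removed, so slow
    within-window fluctuation is retained in the zero-frequency bin rather
    than being discarded segment by segment.  Defaults: Hamming taper, 50%
    overlap, segment length half the window (giving three segments).
    """
    if isinstance(ts, TimeSeries):
        x = ts.values
        dt = ts.dt if dt is None else dt
    else:
        x = np.asarray(ts, dtype=float)
        dt = 1.0 if dt is None else dt
    n = len(x)
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if segment_length is None:
        segment_length = int(np.ceil(n / 2))
    if segment_length > n:
        raise ValueError("segment_length exceeds series length")
    if segment_length < 4:
        raise ValueError("segment_length must be at least 4")

    noverlap = int(np.floor(overlap_fraction * segment_length))
    x = x - np.mean(x)
    freqs, pxx = signal.welch(
        x,
        fs=1.0 / dt,
        window=window,
        nperseg=segment_length,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        return_onesided=True,
    )
    # convert one-sided density per cycle-frequency to two-sided per
    # angular frequency: omega = 2 pi f, and the one-sided estimate already
    # folds negative frequencies in — except at the DC and Nyquist bins,
    # which are their own aliases and are reported unfolded
    pxx = pxx.copy()
    pxx[0] *= 2.0
    if segment_length % 2 == 0:
        pxx[-1] *= 2.0
    omegas = 2 * np.pi * freqs[1:]
    powers = pxx[1:] / (4 * np.pi)
    dc = pxx[0] / (4 * np.pi)

    var = float(np.var(x))
    step = segment_length - noverlap
    n_segments = max((n - segment_length) // step + 1, 1)
    est = PowerSpectrumEstimate(
        omegas, np.maximum(powers, 0.0), n_segments, segment_length, var, dt,
        dc_power=max(dc, 0.0),
        meta={"window": window, "overlap_fraction": overlap_fraction},
    )
    total = est.integral_two_sided()
    if total > 0 and var > 0:
        est.powers = est.powers * (var / total)
        est.dc_power = est.dc_power * (var / total)
    return est


def smax(est: PowerSpectrumEstimate) -> tuple[float, float]:
    """Peak of the estimated spectrum, ``(omega_peak, s_peak)``.

    Ties are broken toward the lowest frequency (np.argmax takes the first
    maximal bin on the increasing grid).
    """
    if len(est.powers) == 0:
        raise ValueError("empty spectrum estimate")
    i = int(np.argmax(est.powers))
    return float(est.omegas[i]), float(est.powers[i])
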