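"""Velocity autocorrelation and vibrational power spectrum.

The normalised velocity autocorrelation function is

    C(t) = < v(t0) . v(t0 + t) > / < v(t0)^2 >,

averaged over atoms and sliding time origins, so C(0) = 1 exactly.
The vibrational power spectrum is its one-sided cosine transform

    I(w) = (2/pi) * integral_0^inf C(t) cos(w t) dt,

discretised on the available lags.  The fast path evaluates the
transform as a type-I DCT (even-extension FFT); a brute-force direct
sum with identical quadrature weights is provided as an oracle and the
two agree to machine precision.  Frequencies are reported in THz
(1/ps), from 0 to the Nyquist frequency 1/(2 dt).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.fft
import scipy.signal

from .errors import DomainError

__all__ = ["VACF", "SpectrumResult", "vacf", "power_spectrum",
           "peak_frequencies", "bond_projected_velocity"]


def bond_projected_velocity(pos_a: np.ndarray, pos_b: np.ndarray,
                            vel_a: np.ndarray, vel_b: np.ndarray) -> np.ndarray:
    """Relative velocity of two atoms projected on their bond axis.

    Isolates the stretch component of a bond (e.g. C=O) from
    whole-molecule motion before computing a VACF.  Inputs are
    ``(T, 3)`` arrays; returns a ``(T,)`` scalar series.
    """
    bond = pos_b - pos_a
    unit = bond / np.linalg.norm(bond, axis=-1, keepdims=True)
    return np.einsum("tk,tk->t", vel_b - vel_a, unit)


@dataclass(frozen=True)
class VACF:
    """Normalised velocity autocorrelation on a uniform lag grid."""

    lags_ps: np.ndarray
    c: np.ndarray
    dt: float

    @property
    def n_lags(self) -> int:
        return len(self.c)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_ps": self.lags_ps, "C": self.c})


def vacf(velocities: np.ndarray, dt: float,
         max_lag_ps: Optional[float] = None) -> VACF:
    """Velocity autocorrelation function of one or many atoms.

    Parameters
    ----------
    velocities : ndarray
        Shape ``(T,)`` for a scalar series, ``(T, n)`` for many scalar
        series, or ``(T, n, 3)`` for vector series; atoms and Cartesian
        components are averaged.
    dt : float
        Sampling interval, ps.
    max_lag_ps : float, optional
        Largest lag retained.  Defaults to half the series length; must
        be smaller than the series span.

    The per-lag average uses all ``T - lag`` sliding origins, and the
    result is normalised so that ``C(0) == 1`` exactly.
    """
    v = np.asarray(velocities, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    elif v.ndim == 3:
        v = v.reshape(v.shape[0], -1)
    elif v.ndim != 2:
        raise ValueError("velocities must be 1-, 2- or 3-dimensional")
    T = v.shape[0]
    if T < 2:
        raise DomainError("need at least two velocity samples")
    if dt <= 0:
        raise DomainError("dt must be positive")
    if max_lag_ps is None:
        n_lags = T // 2 + 1
    else:
        n_lags = int(round(max_lag_ps / dt)) + 1
        if n_lags > T:
            raise DomainError("max_lag must be shorter than the series")
    # FFT-based autocorrelation, summed over columns.
    nfft = scipy.fft.next_fast_len(2 * T)
    spec = np.abs(np.fft.rfft(v, n=nfft, axis=0)) ** 2
    raw = np.fft.irfft(spec.sum(axis=1), n=nfft)[:n_lags]
    norm = raw / (T - np.arange(n_lags))       # unbiased per-lag origin count
    c0 = norm[0]
    if c0 <= 0:
        raise DomainError("zero velocity signal has no autocorrelation")
    c = norm / c0
    c[0] = 1.0
    return VACF(dt * np.arange(n_lags), c, float(dt))


@dataclass(frozen=True)
class SpectrumResult:
    """One-sided cosine-transform power spectrum of a VACF."""

    frequencies_thz: np.ndarray
    intensity: np.ndarray
    window: str
    max_lag_ps: float
    dt: float

    @property
    def nyquist_thz(self) -> float:
        return 0.5 / self.dt

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency_THz": self.frequencies_thz,
                             "intensity": self.intensity})


def _half_hann(n: int) -> np.ndarray:
    """Taper decaying from 1 at lag 0 to 0 at the last lag."""
    if n == 1:
        return np.ones(1)
    return 0.5 * (1.0 + np.cos(np.pi * np.arange(n) / (n - 1)))


def _dct1_weights(x: np.ndarray) -> np.ndarray:
    """Endpoint-halved copy of ``x`` (trapezoid weights of the DCT-I sum)."""
    w = x.copy()
    w[0] *= 0.5
    if len(w) > 1:
        w[-1] *= 0.5
    return w


def power_spectrum(acf: VACF, window: str = "hann", method: str = "fft",
                   zero_pad: int = 1) -> SpectrumResult:
    """Discrete one-sided cosine transform of a VACF.

    ``window`` is ``"hann"`` (default; half-Hann taper over the lags) or
    ``"none"``.  ``zero_pad > 1`` extends the lag axis with zeros, which
    refines the frequency grid without adding information.  ``method``
    selects the even-extension FFT path (``"fft"``) or the direct
    quadrature sum (``"direct"``); both evaluate

        I(w_k) = (2/pi) dt [ C_0/2 + sum_{n=1}^{M-2} C_n cos(w_k n dt)
                             + (-1)^k C_{M-1}/2 ]

    on frequencies ``w_k = pi k / ((M-1) dt)``.
    """
    c = acf.c.astype(float)
    if window == "hann":
        c = c * _half_hann(len(c))
    elif window != "none":
        raise ValueError(f"unknown window {window!r}")
    if zero_pad < 1:
        raise ValueError("zero_pad must be >= 1")
    M = len(c) * zero_pad
    if M < 2:
        raise DomainError("need at least two lags for a spectrum")
    padded = np.zeros(M)
    padded[:len(c)] = c

    if method == "fft":
        intensity = scipy.fft.dct(padded, type=1) * (acf.dt / np.pi)
    elif method == "direct":
        n = np.arange(M)
        k = np.arange(M)
        cosines = np.cos(np.pi * np.outer(k, n) / (M - 1))
        intensity = (2.0 * acf.dt / np.pi) * cosines @ _dct1_weights(padded)
    else:
        raise ValueError(f"unknown method {method!r}")

    freqs = np.arange(M) / (2.0 * (M - 1) * acf.dt)   # THz
    return SpectrumResult(freqs, intensity, window,
                          float(acf.lags_ps[-1]), acf.dt)


def peak_frequencies(spec: SpectrumResult, n_peaks: Optional[int] = None,
                     prominence_frac: float = 0.05) -> list[float]:
    """Local spectral maxima in THz, strongest first.

    ``prominence_frac`` sets the minimum peak prominence as a fraction
    of the spectrum's dynamic range; a flat spectrum has no peaks.
    """
    intensity = spec.intensity
    span = float(intensity.max() - intensity.min())
    if span <= 0:
        return []
    idx, _ = scipy.signal.find_peaks(intensity, prominence=prominence_frac * span)
    order = np.argsort(intensity[idx])[::-1]
    peaks = [float(spec.frequencies_thz[i]) for i in idx[order]]
    return peaks if n_peaks is None else peaks[:n_peaks]
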