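"""Narrowband signal primitives: zero-phase filtering, analytic signals,
frequency warping and the cross-frequency phase-locking value.

All other modules are built on top of these operations.  Signals are plain
NumPy arrays; multichannel data is oriented ``(n_samples, n_channels)`` to
compose with scikit-learn, and the sampling rate ``fs`` travels alongside as
a scalar argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "FrequencyRatio",
    "BandDefinition",
    "bandpass_two_pass",
    "bandstop_two_pass",
    "analytic",
    "freq_warp",
    "freq_warp_offset",
    "cf_plv",
    "edge_slice",
]


@dataclass(frozen=True)
class FrequencyRatio:
    """Coprime integer pair (p, q) defining the frequency ratio f1:f2 = p:q.

    The pair is reduced by its greatest common divisor on construction so
    that the polynomial degree of the downstream phase fit is minimal.
    """

    p: int
    q: int

    def __post_init__(self) -> None:
        p, q = int(self.p), int(self.q)
        if p < 1 or q < 1:
            raise ValueError(f"p and q must be positive integers, got {p}:{q}")
        g = math.gcd(p, q)
        object.__setattr__(self, "p", p // g)
        object.__setattr__(self, "q", q // g)

    @classmethod
    def coerce(cls, ratio) -> "FrequencyRatio":
        if isinstance(ratio, cls):
            return ratio
        p, q = ratio
        return cls(int(p), int(q))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.p}:{self.q}"


@dataclass(frozen=True)
class BandDefinition:
    """A narrow analysis band around ``center`` with the conventional
    pass/stop/flank half-widths (Hz) used for both filtering and SSD.

    Defaults follow the standard narrowband convention: signal band
    center +- 1 Hz, band-stop +- 2 Hz, flanking noise band +- 3 Hz.
    """

    center: float
    pass_halfwidth: float = 1.0
    stop_halfwidth: float = 2.0
    flank_halfwidth: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.pass_halfwidth < self.stop_halfwidth < self.flank_halfwidth < self.center):
            raise ValueError(
                "require 0 < pass < stop < flank < center, got "
                f"center={self.center}, pass={self.pass_halfwidth}, "
                f"stop={self.stop_halfwidth}, flank={self.flank_halfwidth}"
            )

    def scaled(self, factor: float) -> "BandDefinition":
        """Band for the ``factor``-th harmonic: center and half-widths scaled.

        Frequency-warping a narrowband signal by an integer multiplies both
        its instantaneous frequency and its bandwidth, so the harmonic band
        widens proportionally.
        """
        return BandDefinition(
            center=self.center * factor,
            pass_halfwidth=self.pass_halfwidth * factor,
            stop_halfwidth=self.stop_halfwidth * factor,
            flank_halfwidth=self.flank_halfwidth * factor,
        )

    @property
    def passband(self) -> tuple[float, float]:
        return (self.center - self.pass_halfwidth, self.center + self.pass_halfwidth)

    @property
    def stopband(self) -> tuple[float, float]:
        return (self.center - self.stop_halfwidth, self.center + self.stop_halfwidth)

    @property
    def flankband(self) -> tuple[float, float]:
        return (self.center - self.flank_halfwidth, self.center + self.flank_halfwidth)


def _check_band(low: float, high: float, fs: float) -> None:
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band ({low}, {high}) Hz invalid for fs={fs} Hz (Nyquist {fs / 2})")


def bandpass_two_pass(x: np.ndarray, fs: float, low: float, high: float, order: int = 2) -> np.ndarray:
    """Zero-phase band-pass: one forward and one backward pass of a
    Butterworth filter of the given order (group delay cancels exactly).

    ``x`` may be 1-D or ``(n_samples, n_channels)``; filtering runs along
    axis 0.
    """
    _check_band(low, high, fs)
    x = np.asarray(x, dtype=float)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def bandstop_two_pass(x: np.ndarray, fs: float, low: float, high: float, order: int = 2) -> np.ndarray:
    """Zero-phase band-stop (notch) companion of :func:`bandpass_two_pass`."""
    _check_band(low, high, fs)
    x = np.asarray(x, dtype=float)
    sos = sps.butter(order, [low, high], btype="bandstop", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def analytic(x: np.ndarray) -> np.ndarray:
    """Analytic signal ``x + i H(x)`` via the Hilbert transform.

    The real part of the output equals ``x`` sample-for-sample; magnitude
    and angle give the instantaneous amplitude and phase of the (narrowband)
    input.  Works along axis 0 for 2-D input.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 16:
        raise ValueError("need at least 16 samples for a meaningful analytic signal")
    return sps.hilbert(x, axis=0)


def freq_warp(z: np.ndarray, q: int) -> np.ndarray:
    """Frequency warp by ``q``: multiply the instantaneous phase by ``q``
    while preserving the amplitude envelope, ``z**q / |z|**(q-1)``.

    Zeros of ``z`` map to zero (the continuous limit), never NaN.
    """
    if q < 1:
        raise ValueError("warp factor q must be >= 1")
    z = np.asarray(z, dtype=complex)
    if q == 1:
        return z.copy()
    mag = np.abs(z)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(mag > 0, z / np.where(mag > 0, mag, 1.0), 0.0)
    return mag * unit**q


def freq_warp_offset(z: np.ndarray, q: int, k: int, K: int) -> np.ndarray:
    """Frequency warp by ``q`` followed by a constant phase offset 2*pi*k/K.

    The offset grid is used to scan for phase-locked (constant, nonzero
    phase difference) rather than strictly phase-synchronized components.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0 <= k < K:
        raise ValueError(f"phase offset index k={k} out of range [0, {K})")
    return freq_warp(z, q) * np.exp(2j * np.pi * k / K)


def cf_plv(phi1: np.ndarray, phi2: np.ndarray, ratio) -> float:
    """Cross-frequency phase-locking value at ratio p:q.

    ``PLV = |mean(exp(i (p*phi2 - q*phi1)))|`` where ``phi1`` is the phase of
    the reference signal at f1 and ``phi2`` the phase at f2, f1:f2 = p:q.
    Equals 1 iff the generalized phase difference is constant, and is
    invariant to adding constants to either phase sequence.
    """
    ratio = FrequencyRatio.coerce(ratio)
    phi1 = np.asarray(phi1, dtype=float)
    phi2 = np.asarray(phi2, dtype=float)
    if phi1.shape != phi2.shape:
        raise ValueError(f"phase sequences differ in shape: {phi1.shape} vs {phi2.shape}")
    if phi1.size == 0:
        raise ValueError("empty phase sequences")
    # work on unit phasors: immune to wrapping conventions of the inputs
    return float(np.abs(np.mean(np.exp(1j * (ratio.p * phi2 - ratio.q * phi1)))))


def edge_slice(n_samples: int, fs: float, edge_margin_s: float) -> slice:
    """Interior slice discarding ``edge_margin_s`` seconds at each end
    (Hilbert/filter transients corrupt phase estimates near the edges).

    Falls back to keeping at least the middle half when the margin would
    swallow the whole signal.
    """
    m = int(round(edge_margin_s * fs))
    if m <= 0:
        return slice(None)
    if 2 * m >= n_samples:
        m = n_samples // 4
    return slice(m, n_samples - m)
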