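"""Synthetic multichannel EEG with p:q cross-frequency coupled sources.

The generator reproduces a standard validation protocol for cross-frequency
decomposition methods: a band-limited (9-11 Hz) Gaussian "base" rhythm is
frequency-warped by p and by q, yielding a pair of perfectly p:q
phase-synchronized sources in bands around 10p and 10q Hz; a large
population of mutually independent 1/f ("pink") noise dipoles provides a
realistic broadband background; all sources are mixed linearly into the
sensor array; and the coupled sources are rescaled so that each one's mean
projected channel variance stands in a prescribed ratio (the SNR) to the
mean channel variance of the cumulative projected noise.

A realistic volume-conductor forward model is deliberately not part of this
generator: linear mixing is what the decomposition relies on, so the default
mixing columns are random spatially smooth topographies (sums of Gaussian
blobs over a synthetic circular electrode layout), and any user-supplied
leadfield can be plugged in instead.

The uncoupled control variant draws the fit-band sources from base rhythms
independent of the reference-band bases, so no true cross-frequency
coupling exists while all marginal spectra are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_core import FrequencyRatio, analytic, bandpass_two_pass, freq_warp

__all__ = [
    "SimulationSpec",
    "SimulationTruth",
    "electrode_layout",
    "gen_coupled_pair",
    "gen_pink_noise",
    "gen_patterns",
    "normalize_snr",
    "gen_dataset",
]


@dataclass
class SimulationSpec:
    """Parameters of one simulated recording.

    Defaults are the protocol's standard conditions: 5 coupled source pairs,
    100 pink-noise dipoles, 64 channels, 150 s at 200 Hz, base band 9-11 Hz.
    """

    n_pairs: int = 5
    n_noise: int = 100
    n_channels: int = 64
    duration_s: float = 150.0
    fs: float = 200.0
    base_band: tuple[float, float] = (9.0, 11.0)
    ratio: FrequencyRatio | tuple = (1, 2)
    snr: float = 1.0
    coupled: bool = True
    seed: int = 0
    leadfield: np.ndarray | None = None  # (n_channels, n_nodes, 3); None = smooth random columns

    def __post_init__(self):
        self.ratio = FrequencyRatio.coerce(self.ratio)
        if min(self.n_pairs, self.n_channels) < 1 or self.n_noise < 0:
            raise ValueError("counts must be positive (n_noise may be 0)")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")
        top = max(self.ratio.p, self.ratio.q) * self.base_band[1]
        if top >= self.fs / 2:
            raise ValueError(f"warped band reaches {top} Hz, above Nyquist {self.fs / 2} Hz")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated sensor recording.

    ``source_signals`` rows are ordered: reference-band sources (one per
    pair), then fit-band sources, then noise dipoles; ``source_patterns``
    columns match.  ``pair_phases`` holds the exact instantaneous phases of
    each pair's warped analytic signals, for which the generalized phase
    difference p*phi_fit - q*phi_ref is identically zero by construction
    (coupled variant).
    """

    source_signals: np.ndarray  # (n_sources, n_samples)
    source_patterns: np.ndarray  # (n_channels, n_sources)
    coupled_pair_index: list  # (ref row, fit row, FrequencyRatio)
    snr: float
    seed: int
    pair_phases: list = field(default_factory=list)  # (phi_ref, phi_fit) per pair

    @property
    def n_pairs(self) -> int:
        return len(self.coupled_pair_index)

    @property
    def reference_sources(self) -> np.ndarray:
        return self.source_signals[[i for i, _, _ in self.coupled_pair_index]]

    @property
    def fit_sources(self) -> np.ndarray:
        return self.source_signals[[j for _, j, _ in self.coupled_pair_index]]

    @property
    def reference_patterns(self) -> np.ndarray:
        return self.source_patterns[:, [i for i, _, _ in self.coupled_pair_index]]

    @property
    def fit_patterns(self) -> np.ndarray:
        return self.source_patterns[:, [j for _, j, _ in self.coupled_pair_index]]


def electrode_layout(n_channels: int) -> np.ndarray:
    """Deterministic 2-D sensor coordinates on the unit disk (sunflower
    spiral) standing in for a standard montage; used only to draw spatially
    smooth mixing topographies."""
    i = np.arange(n_channels) + 0.5
    r = np.sqrt(i / n_channels)
    theta = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _base_analytic(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Analytic signal of band-limited white noise in the base band."""
    white = rng.standard_normal(spec.n_samples)
    base = bandpass_two_pass(white, spec.fs, *spec.base_band)
    return analytic(base)


def gen_coupled_pair(spec: SimulationSpec, rng: np.random.Generator | None = None, return_phases: bool = False):
    """One p:q-synchronized source pair.

    Two copies of a single band-limited Gaussian base rhythm are frequency
    warped by p and by q, yielding real sources in bands around
    ``p*center`` and ``q*center`` Hz whose generalized phase difference is
    exactly constant.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    z = _base_analytic(spec, rng)
    ratio = spec.ratio
    z_ref = freq_warp(z, ratio.p)
    z_fit = freq_warp(z, ratio.q)
    if return_phases:
        return z_ref.real, z_fit.real, np.angle(z_ref), np.angle(z_fit)
    return z_ref.real, z_fit.real


def gen_pink_noise(n_sources: int, n_samples: int, fs: float, seed=None, f_min: float = 0.5) -> np.ndarray:
    """Mutually independent rows of 1/f-power-spectrum noise, unit variance.

    Spectral shaping of white Gaussian noise: each positive-frequency
    Fourier amplitude is scaled by 1/sqrt(f), giving a power spectral
    density falling off as 1/f (log-log slope -1).  Content below ``f_min``
    (Hz) is zeroed: the 1/f divergence at the lowest bins would otherwise
    concentrate almost all variance in a handful of slow trends, making
    finite realizations of different rows spuriously correlated (and real
    recordings are high-passed at ~0.5 Hz anyway).
    """
    if n_samples < 256:
        raise ValueError("need n_samples >= 256 for meaningful pink noise")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal((n_sources, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    keep = freqs >= f_min
    shaping[keep] = 1.0 / np.sqrt(freqs[keep])
    x = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def gen_patterns(
    n_sources: int,
    n_channels: int,
    seed=None,
    leadfield: np.ndarray | None = None,
) -> np.ndarray:
    """Random unit-norm mixing columns, shape ``(n_channels, n_sources)``.

    Default columns are sums of 2-4 signed Gaussian blobs evaluated at the
    synthetic electrode layout (spatially smooth, mutually distinct).  If a
    ``leadfield`` of shape (n_channels, n_nodes, 3) is given, each column is
    instead the field of a randomly placed, randomly oriented unit dipole.
    Redraws until the matrix has full rank min(n_sources, n_channels).
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = electrode_layout(n_channels)
    want_rank = min(n_sources, n_channels)
    for _ in range(100):
        if leadfield is not None:
            lf = np.asarray(leadfield, dtype=float)
            cols = []
            for _j in range(n_sources):
                node = int(rng.integers(lf.shape[1]))
                orient = rng.standard_normal(3)
                orient /= np.linalg.norm(orient)
                cols.append(lf[:, node] @ orient)
            P = np.column_stack(cols)
        else:
            P = np.zeros((n_channels, n_sources))
            for j in range(n_sources):
                n_blobs = int(rng.integers(2, 5))
                col = np.zeros(n_channels)
                for _b in range(n_blobs):
                    center = rng.uniform(-1.1, 1.1, size=2)
                    width = rng.uniform(0.25, 0.6)
                    amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5)
                    d2 = np.sum((pos - center) ** 2, axis=1)
                    col += amp * np.exp(-d2 / (2 * width**2))
                P[:, j] = col
        norms = np.linalg.norm(P, axis=0)
        if np.any(norms < 1e-12):
            continue
        P /= norms
        if np.linalg.matrix_rank(P) >= want_rank:
            return P
    raise RuntimeError("failed to draw a full-rank pattern matrix in 100 attempts")


def normalize_snr(
    signal_sources: np.ndarray,
    noise_sources: np.ndarray,
    patterns: np.ndarray,
    target_snr: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale each signal source so that the mean-over-channels variance of
    its individual sensor projection, divided by the mean-over-channels
    variance of the summed projected noise, equals ``target_snr``.

    ``patterns`` holds signal columns first, then noise columns.  Returns
    ``(sensor_data, scales)`` with sensor data of shape
    ``(n_samples, n_channels)`` and the per-signal amplitude scales applied.
    """
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    S = np.atleast_2d(np.asarray(signal_sources, dtype=float))
    N = np.atleast_2d(np.asarray(noise_sources, dtype=float))
    k, m = S.shape[0], N.shape[0]
    P = np.asarray(patterns, dtype=float)
    if P.shape[1] != k + m:
        raise ValueError(f"patterns has {P.shape[1]} columns, expected {k + m}")
    Ps, Pn = P[:, :k], P[:, k:]
    noise_sensor = (Pn @ N).T  # (T, channels)
    noise_var = float(np.mean(np.var(noise_sensor, axis=0)))
    if noise_var <= 0:
        raise ValueError("projected noise has zero variance")
    scales = np.empty(k)
    for i in range(k):
        var_i = float(np.var(S[i])) * float(np.mean(Ps[:, i] ** 2))
        if var_i <= 0:
            raise ValueError(f"signal source {i} has zero projected variance")
        scales[i] = np.sqrt(target_snr * noise_var / var_i)
    sensor = ((Ps * scales) @ S).T + noise_sensor
    return sensor, scales


def gen_dataset(spec: SimulationSpec) -> tuple[np.ndarray, SimulationTruth]:
    """Full simulated recording: sensors ``(n_samples, n_channels)`` plus
    ground truth.

    Coupled variant: each pair's two sources are warps of one shared base
    rhythm.  Uncoupled variant (``spec.coupled=False``): the fit-band
    sources are warped from independent bases, so within- and between-band
    sources are all mutually independent.
    """
    rng = np.random.default_rng(spec.seed)
    ratio = spec.ratio
    refs, fits, phases = [], [], []
    for _ in range(spec.n_pairs):
        z = _base_analytic(spec, rng)
        z_ref = freq_warp(z, ratio.p)
        if spec.coupled:
            z_fit = freq_warp(z, ratio.q)
        else:
            z_fit = freq_warp(_base_analytic(spec, rng), ratio.q)
        refs.append(z_ref.real)
        fits.append(z_fit.real)
        phases.append((np.angle(z_ref), np.angle(z_fit)))

    signal_sources = np.vstack(refs + fits)  # (2*n_pairs, T)
    patterns = gen_patterns(2 * spec.n_pairs + spec.n_noise, spec.n_channels, seed=rng, leadfield=spec.leadfield)

    if spec.n_noise > 0 and np.isfinite(spec.snr):
        noise = gen_pink_noise(spec.n_noise, spec.n_samples, spec.fs, seed=rng)
        sensor, scales = normalize_snr(signal_sources, noise, patterns, spec.snr)
        sources = np.vstack([signal_sources * scales[:, None], noise])
    else:
        sources = signal_sources
        patterns = patterns[:, : 2 * spec.n_pairs]
        sensor = (patterns @ sources).T

    truth = SimulationTruth(
        source_signals=sources,
        source_patterns=patterns,
        coupled_pair_index=[(i, spec.n_pairs + i, ratio) for i in range(spec.n_pairs)],
        snr=spec.snr,
        seed=spec.seed,
        pair_phases=phases,
    )
    return sensor, truth
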