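"""End-to-end generalized cross-frequency decomposition (GCFD).

Workflow: (a) extract the strongest narrowband components of the reference
band with spatio-spectral decomposition (SSD); (b) optionally reduce the
fit band to a small virtual-sensor space with a secondary SSD; (c) for each
reference component, run the cross-frequency phase fit (XPF) to find the
fit-band component in strongest p:q phase synchrony with it; (d) rank the
(reference, fit) pairs by their phase-locking value and attach sensor-space
spatial filters and patterns to each.

Spatial patterns are computed from filters under the uncorrelated-sources
assumption, ``pattern = M' s / (s' s)`` — equivalently the data covariance
applied to the filter — and patterns found in the virtual-sensor space are
mapped back to the channels through the secondary-SSD pattern matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .signal_core import BandDefinition, FrequencyRatio, bandpass_two_pass, edge_slice
from .ssd import SSD
from .xpf import XPF

__all__ = ["CoupledPair", "GCFD", "compute_pattern", "run_gcfd", "scan_base_frequency"]


def compute_pattern(M: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Spatial pattern of the component ``s`` extracted from data ``M``
    (n_samples, n_channels): channel-wise regression of M onto s,
    ``M' s / (s' s)``."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    s = np.asarray(s, dtype=float).ravel()
    if M.shape[0] != s.shape[0]:
        if M.shape[1] == s.shape[0]:
            M = M.T
        else:
            raise ValueError(f"length mismatch: M has {M.shape[0]} samples, s has {s.shape[0]}")
    energy = float(s @ s)
    if energy <= 0:
        raise ValueError("component has zero energy")
    return M.T @ s / energy


@dataclass
class CoupledPair:
    """A reference component and its fitted p:q-synchronous counterpart."""

    reference_component: np.ndarray
    fit_component: np.ndarray
    reference_filter: np.ndarray
    fit_filter: np.ndarray
    reference_pattern: np.ndarray
    fit_pattern: np.ndarray
    plv: float
    ratio: FrequencyRatio
    base_frequency: float
    offset_k: int = 0

    def summary(self) -> dict:
        return {
            "plv": self.plv,
            "ratio": [self.ratio.p, self.ratio.q],
            "base_frequency": self.base_frequency,
            "offset_k": self.offset_k,
        }


class GCFD(BaseEstimator):
    """Extract p:q cross-frequency phase-coupled component pairs.

    Parameters
    ----------
    fs : float
        Sampling rate (Hz).
    f1 : float
        Center of the reference band (Hz); the fit band sits at
        ``f2 = f1 * q / p``.
    ratio : (p, q)
        Frequency ratio f1:f2.
    n_reference : int
        Reference-band SSD components processed (clamped to channel count).
    n_secondary : int, 0, or "auto"
        Virtual sensors retained by the secondary fit-band SSD; 0 disables
        the reduction; "auto" enables 15 when there are more than 20
        channels.
    K : int or "auto"
        Phase offsets scanned by XPF (1 = strict synchrony).  "auto" uses 2
        when p is even and 1 otherwise: linearly extracted reference
        components carry an arbitrary sign, and for even p a sign flip of
        the reference cannot be absorbed by negating the weights, so the
        half-turn offset must be scanned explicitly.
    ref_band, fit_band : BandDefinition, optional
        Override the default +-1/+-2/+-3 Hz band conventions.
    preprocess : bool
        Apply the wide 0.5 Hz to 1.5*max(f1, f2) zero-phase band-pass
        before analysis.
    n_restarts, edge_margin_s, random_state
        Passed to :class:`~gcfd.xpf.XPF`.

    Attributes
    ----------
    pairs_ : list of CoupledPair, sorted by descending PLV.
    ssd_reference_ : fitted reference-band SSD.
    ssd_secondary_ : fitted fit-band SSD, or None if disabled.
    """

    def __init__(
        self,
        fs: float = 200.0,
        f1: float = 10.0,
        ratio=(1, 2),
        n_reference: int = 5,
        n_secondary="auto",
        K="auto",
        ref_band: BandDefinition | None = None,
        fit_band: BandDefinition | None = None,
        preprocess: bool = True,
        n_restarts: int = 10,
        edge_margin_s: float = 1.0,
        filter_order: int = 2,
        tol: float = 1e-10,
        max_iter: int = 500,
        random_state=None,
    ):
        self.fs = fs
        self.f1 = f1
        self.ratio = ratio
        self.n_reference = n_reference
        self.n_secondary = n_secondary
        self.K = K
        self.ref_band = ref_band
        self.fit_band = fit_band
        self.preprocess = preprocess
        self.n_restarts = n_restarts
        self.edge_margin_s = edge_margin_s
        self.filter_order = filter_order
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- band helpers -----------------------------------------------------
    def _bands(self, ratio: FrequencyRatio) -> tuple[BandDefinition, BandDefinition]:
        f2 = self.f1 * ratio.q / ratio.p
        ref = self.ref_band if self.ref_band is not None else BandDefinition(self.f1)
        fit = self.fit_band if self.fit_band is not None else BandDefinition(f2)
        return ref, fit

    def fit(self, X: np.ndarray, y=None) -> "GCFD":
        """Decompose ``X`` of shape (n_samples, n_channels)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] < X.shape[1]:
            warnings.warn("X has more channels than samples; expected (n_samples, n_channels)")
        ratio = FrequencyRatio.coerce(self.ratio)
        f2 = self.f1 * ratio.q / ratio.p
        if max(self.f1, f2) >= self.fs / 2:
            raise ValueError(f"fit/reference band at {max(self.f1, f2)} Hz reaches Nyquist ({self.fs / 2} Hz)")
        n_ch = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        ref_band, fit_band = self._bands(ratio)

        if self.preprocess:
            high = min(1.5 * max(self.f1, f2), 0.99 * self.fs / 2)
            X = bandpass_two_pass(X, self.fs, 0.5, high, order=self.filter_order)

        n_ref = self.n_reference
        if n_ref > n_ch:
            warnings.warn(f"n_reference={n_ref} clamped to {n_ch} channels")
            n_ref = n_ch

        keep = edge_slice(X.shape[0], self.fs, self.edge_margin_s)

        single_channel = n_ch == 1
        if single_channel:
            ref_signals = bandpass_two_pass(X, self.fs, *ref_band.passband, order=self.filter_order)
            self.ssd_reference_ = None
            n_ref = 1
        else:
            ssd_ref = SSD(
                fs=self.fs,
                band=ref_band,
                n_components=n_ref,
                filter_order=self.filter_order,
                edge_margin_s=self.edge_margin_s,
            ).fit(X)
            ref_signals = ssd_ref.transform(X)
            self.ssd_reference_ = ssd_ref

        n_sec = self.n_secondary
        if n_sec == "auto":
            n_sec = 15 if n_ch > 20 else 0
        n_sec = min(int(n_sec), n_ch)
        use_secondary = n_sec > 0 and not single_channel and n_sec < n_ch
        fit_band_sensor = bandpass_two_pass(X, self.fs, *fit_band.passband, order=self.filter_order)
        if use_secondary:
            ssd_sec = SSD(
                fs=self.fs,
                band=fit_band,
                n_components=n_sec,
                filter_order=self.filter_order,
                edge_margin_s=self.edge_margin_s,
            ).fit(X)
            M = ssd_sec.transform(X)
            self.ssd_secondary_ = ssd_sec
        else:
            M = fit_band_sensor
            self.ssd_secondary_ = None

        ref_sensor_band = bandpass_two_pass(X, self.fs, *ref_band.passband, order=self.filter_order)

        K = self.K
        if K == "auto":
            K = 2 if ratio.p % 2 == 0 else 1

        pairs = []
        for j in range(n_ref):
            r = ref_signals[:, j]
            xpf = XPF(
                ratio=ratio,
                K=K,
                n_restarts=self.n_restarts,
                edge_margin_s=self.edge_margin_s,
                fs=self.fs,
                tol=self.tol,
                max_iter=self.max_iter,
                random_state=int(rng.integers(2**31)),
            ).fit(M, r)
            comp = xpf.component_
            p_local = compute_pattern(M[keep], comp[keep])
            if use_secondary:
                fit_pattern = self.ssd_secondary_.pattern_to_sensor_space(p_local, n_sec)
                fit_filter = self.ssd_secondary_.filters_[:, :n_sec] @ xpf.weights_
            else:
                fit_pattern = p_local
                fit_filter = xpf.weights_
            if single_channel:
                ref_filter = np.ones(1)
                ref_pattern = compute_pattern(ref_sensor_band[keep], r[keep])
            else:
                ref_filter = self.ssd_reference_.filters_[:, j]
                ref_pattern = compute_pattern(ref_sensor_band[keep], r[keep])
            pairs.append(
                CoupledPair(
                    reference_component=r,
                    fit_component=comp,
                    reference_filter=ref_filter,
                    fit_filter=fit_filter,
                    reference_pattern=ref_pattern,
                    fit_pattern=fit_pattern,
                    plv=xpf.plv_,
                    ratio=ratio,
                    base_frequency=self.f1 / ratio.p,
                    offset_k=xpf.offset_k_,
                )
            )
        pairs.sort(key=lambda pr: pr.plv, reverse=True)
        self.pairs_ = pairs
        self.n_features_in_ = n_ch
        return self

    @property
    def best_pair_(self) -> CoupledPair:
        check_is_fitted(self, "pairs_")
        return self.pairs_[0]

    def fit_patterns_(self) -> np.ndarray:
        """Recovered fit-band patterns as a (n_channels, n_pairs) matrix."""
        check_is_fitted(self, "pairs_")
        return np.column_stack([p.fit_pattern for p in self.pairs_])


def run_gcfd(X: np.ndarray, f1: float, ratio, fs: float = 200.0, **kwargs) -> list[CoupledPair]:
    """Functional wrapper: list of coupled pairs sorted by descending PLV."""
    return GCFD(fs=fs, f1=f1, ratio=ratio, **kwargs).fit(X).pairs_


def scan_base_frequency(X: np.ndarray, ratio, grid, fs: float = 200.0, **kwargs):
    """Run the decomposition at each base frequency in ``grid`` (Hz of the
    underlying base rhythm; reference band sits at p*base) and return
    ``(best_base, best_pair, plv_by_base)`` maximizing the top PLV."""
    grid = list(grid)
    if not grid:
        raise ValueError("empty frequency grid")
    ratio = FrequencyRatio.coerce(ratio)
    best = None
    plv_by_base = {}
    for base in grid:
        pairs = run_gcfd(X, f1=base * ratio.p, ratio=ratio, fs=fs, **kwargs)
        top = pairs[0]
        plv_by_base[float(base)] = top.plv
        if best is None or top.plv > best[1].plv:
            best = (float(base), top)
    return best[0], best[1], plv_by_base
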