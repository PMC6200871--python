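"""Spatio-spectral decomposition (SSD).

SSD extracts narrowband oscillatory components by maximizing the ratio of
signal-band power to flanking-band noise power.  With band-limited
covariance ``C_s`` and flanking-noise covariance ``C_f``, the spatial
filters ``W`` solve the generalized eigenproblem ``C_s w = lambda C_f w``;
eigenvalues are narrowband SNR ratios.  Spatial patterns are obtained from
the filters through the band covariance (``A = C_s W (W' C_s W)^-1``), so a
filter's topography can be read off directly.

Used twice in the full decomposition workflow: to extract reference-band
components, and to reduce the fit band to a low-dimensional virtual-sensor
space.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .signal_core import BandDefinition, bandpass_two_pass, bandstop_two_pass, edge_slice

__all__ = ["SSD", "fit_ssd", "ssd_project", "pattern_to_sensor_space"]


def _fix_pattern_signs(patterns: np.ndarray, filters: np.ndarray) -> None:
    """Make each pattern's largest-magnitude entry positive (in place).

    Generalized eigenvectors are sign-ambiguous; a fixed convention makes
    results deterministic.  Filters are flipped together with patterns so
    projected components keep ``component = X @ filter`` consistent.
    """
    for j in range(patterns.shape[1]):
        i = int(np.argmax(np.abs(patterns[:, j])))
        if patterns[i, j] < 0:
            patterns[:, j] *= -1.0
            filters[:, j] *= -1.0


class SSD(BaseEstimator, TransformerMixin):
    """Spatio-spectral decomposition of multichannel oscillatory data.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    band : BandDefinition or float
        Analysis band.  A bare float is taken as the center frequency with
        the default +-1 / +-2 / +-3 Hz pass/stop/flank half-widths.
    n_components : int
        Number of components retained by :meth:`transform`.
    filter_order : int
        Butterworth order per pass for all internal filters.
    shrinkage : float
        Ridge added to both covariances, as a fraction of ``trace/n``;
        guards against rank deficiency (e.g. after ICA cleaning).
    edge_margin_s : float
        Seconds discarded at each end before covariance estimation.

    Attributes
    ----------
    filters_ : ndarray (n_channels, n_channels)
        Generalized eigenvectors (columns), descending SNR order.
    patterns_ : ndarray (n_channels, n_channels)
        Spatial patterns (columns) matching ``filters_``.
    eigenvalues_ : ndarray (n_channels,)
        Narrowband SNR ratios, sorted descending, all positive.
    """

    def __init__(
        self,
        fs: float = 200.0,
        band=10.0,
        n_components: int = 5,
        filter_order: int = 2,
        shrinkage: float = 1e-9,
        edge_margin_s: float = 1.0,
    ):
        self.fs = fs
        self.band = band
        self.n_components = n_components
        self.filter_order = filter_order
        self.shrinkage = shrinkage
        self.edge_margin_s = edge_margin_s

    def _band(self) -> BandDefinition:
        if isinstance(self.band, BandDefinition):
            return self.band
        return BandDefinition(center=float(self.band))

    def band_signal(self, X: np.ndarray) -> np.ndarray:
        """Signal-band component of ``X`` (zero-phase band-pass)."""
        band = self._band()
        return bandpass_two_pass(X, self.fs, *band.passband, order=self.filter_order)

    def flank_signal(self, X: np.ndarray) -> np.ndarray:
        """Flanking-noise component: band-pass into the wide flank band,
        then band-stop the signal-plus-transition band."""
        band = self._band()
        wide = bandpass_two_pass(X, self.fs, *band.flankband, order=self.filter_order)
        return bandstop_two_pass(wide, self.fs, *band.stopband, order=self.filter_order)

    def fit(self, X: np.ndarray, y=None) -> "SSD":
        """Fit on data of shape ``(n_samples, n_channels)``."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be (n_samples, n_channels) with >= 2 channels")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        keep = edge_slice(X.shape[0], self.fs, self.edge_margin_s)
        xs = self.band_signal(X)[keep]
        xf = self.flank_signal(X)[keep]
        n = X.shape[1]
        c_s = xs.T @ xs / xs.shape[0]
        c_f = xf.T @ xf / xf.shape[0]
        ridge_s = self.shrinkage * np.trace(c_s) / n
        ridge_f = self.shrinkage * np.trace(c_f) / n
        c_s = c_s + ridge_s * np.eye(n)
        c_f = c_f + ridge_f * np.eye(n)
        evals, evecs = linalg.eigh(c_s, c_f)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        # patterns via the band covariance; (W' C_s W) is diagonal for
        # generalized eigenvectors but solve keeps this exact numerically
        patterns = c_s @ evecs @ linalg.inv(evecs.T @ c_s @ evecs)
        filters = evecs.copy()
        _fix_pattern_signs(patterns, filters)
        self.filters_ = filters
        self.patterns_ = patterns
        self.eigenvalues_ = evals
        self.cov_band_ = c_s
        self.cov_flank_ = c_f
        self.n_features_in_ = n
        return self

    def transform(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Project band-filtered data onto the leading spatial filters.

        Returns virtual-sensor time courses ``(n_samples, n_components)``.
        """
        check_is_fitted(self, "filters_")
        k = self.n_components if n_components is None else int(n_components)
        if k > self.filters_.shape[1]:
            raise ValueError(f"n_components={k} exceeds available {self.filters_.shape[1]}")
        X = np.asarray(X, dtype=float)
        return self.band_signal(X) @ self.filters_[:, :k]

    def pattern_to_sensor_space(self, p_virtual: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Map a pattern expressed over the retained virtual sensors back to
        the original channel space: ``p = S @ p'`` with ``S`` the retained
        pattern columns."""
        check_is_fitted(self, "patterns_")
        k = self.n_components if n_components is None else int(n_components)
        p_virtual = np.asarray(p_virtual, dtype=float)
        if p_virtual.shape[0] != k:
            raise ValueError(f"virtual pattern length {p_virtual.shape[0]} != n_components {k}")
        return self.patterns_[:, :k] @ p_virtual

    def save(self, prefix: str | Path) -> None:
        """Serialize to ``<prefix>.json`` (metadata) + ``<prefix>.tsv``
        (filters | patterns | eigenvalues stacked as delimited text)."""
        check_is_fitted(self, "filters_")
        prefix = Path(prefix)
        band = self._band()
        meta = {
            "fs": self.fs,
            "band": {
                "center": band.center,
                "pass_halfwidth": band.pass_halfwidth,
                "stop_halfwidth": band.stop_halfwidth,
                "flank_halfwidth": band.flank_halfwidth,
            },
            "n_channels": int(self.n_features_in_),
            "n_components": int(self.n_components),
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        stacked = np.vstack([self.filters_, self.patterns_, self.eigenvalues_[None, :]])
        np.savetxt(prefix.with_suffix(".tsv"), stacked, delimiter="\t")

    @classmethod
    def load(cls, prefix: str | Path) -> "SSD":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        stacked = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
        n = meta["n_channels"]
        model = cls(fs=meta["fs"], band=BandDefinition(**meta["band"]), n_components=meta["n_components"])
        model.filters_ = stacked[:n]
        model.patterns_ = stacked[n : 2 * n]
        model.eigenvalues_ = stacked[2 * n]
        model.n_features_in_ = n
        return model


def fit_ssd(X: np.ndarray, fs: float, band, n_keep: int = 5, **kwargs) -> SSD:
    """Functional wrapper: fit an :class:`SSD` keeping ``n_keep`` components."""
    return SSD(fs=fs, band=band, n_components=n_keep, **kwargs).fit(X)


def ssd_project(X: np.ndarray, model: SSD, n_components: int | None = None) -> np.ndarray:
    """Project ``X`` through a fitted model (see :meth:`SSD.transform`)."""
    return model.transform(X, n_components=n_components)


def pattern_to_sensor_space(p_virtual: np.ndarray, model: SSD, n_components: int | None = None) -> np.ndarray:
    """``p = S @ p'`` (see :meth:`SSD.pattern_to_sensor_space`)."""
    return model.pattern_to_sensor_space(p_virtual, n_components=n_components)
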