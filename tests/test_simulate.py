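"""Synthetic-data generator: coupled pairs, pink noise, mixing patterns and
SNR normalization."""

import numpy as np
import pytest
from scipy import signal as sps

from gcfd.evaluate import divergence_matrix
from gcfd.signal_core import cf_plv
from gcfd.simulate import (
    SimulationSpec,
    electrode_layout,
    gen_coupled_pair,
    gen_dataset,
    gen_patterns,
    gen_pink_noise,
    normalize_snr,
)

FS = 200.0


class TestCoupledPair:
    def test_spectral_peaks_at_harmonics(self):
        spec = SimulationSpec(ratio=(1, 2), duration_s=60.0, seed=0)
        low, high = gen_coupled_pair(spec)
        for x, f_expect in [(low, 10.0), (high, 20.0)]:
            f, pxx = sps.welch(x, fs=FS, nperseg=2048)
            assert abs(f[np.argmax(pxx)] - f_expect) <= 1.0

    def test_unit_ratio_gives_identical_sources(self):
        spec = SimulationSpec(ratio=(1, 1), duration_s=20.0, seed=1)
        low, high = gen_coupled_pair(spec)
        assert np.array_equal(low, high)

    @pytest.mark.parametrize("ratio", [(1, 2), (2, 3), (4, 3)])
    def test_generalized_phase_difference_exactly_zero(self, ratio):
        spec = SimulationSpec(ratio=ratio, duration_s=20.0, seed=2)
        _, _, phi_ref, phi_fit = gen_coupled_pair(spec, return_phases=True)
        interior = slice(int(FS), -int(FS))
        assert cf_plv(phi_ref[interior], phi_fit[interior], ratio) == pytest.approx(1.0, abs=1e-10)

    def test_warp_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec(ratio=(1, 10), fs=200.0)


class TestPinkNoise:
    def test_log_log_psd_slope_near_minus_one(self):
        x = gen_pink_noise(4, 30_000, FS, seed=0)
        f, pxx = sps.welch(x, fs=FS, nperseg=4096, axis=1)
        band = (f >= 1.0) & (f <= 50.0)
        for row in pxx:
            slope = np.polyfit(np.log(f[band]), np.log(row[band]), 1)[0]
            assert -1.3 < slope < -0.7

    def test_rows_mutually_uncorrelated(self):
        x = gen_pink_noise(5, 30_000, FS, seed=1)
        C = np.corrcoef(x)
        off = C[np.triu_indices(5, 1)]
        assert np.max(np.abs(off)) < 0.05

    def test_reproducible_from_seed(self):
        a = gen_pink_noise(2, 1024, FS, seed=7)
        b = gen_pink_noise(2, 1024, FS, seed=7)
        assert np.array_equal(a, b)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            gen_pink_noise(1, 100, FS)


class TestPatterns:
    def test_columns_unit_norm_full_rank_distinct(self):
        P = gen_patterns(110, 64, seed=0)
        assert np.allclose(np.linalg.norm(P, axis=0), 1.0)
        assert np.linalg.matrix_rank(P) == 64
        D = divergence_matrix(P, P)
        assert np.median(D[np.triu_indices(110, 1)]) > 0.2

    def test_single_source(self):
        P = gen_patterns(1, 16, seed=1)
        assert P.shape == (16, 1)
        assert np.linalg.norm(P[:, 0]) == pytest.approx(1.0)

    def test_user_leadfield_columns(self):
        rng = np.random.default_rng(2)
        lf = rng.standard_normal((8, 20, 3))
        P = gen_patterns(5, 8, seed=3, leadfield=lf)
        assert P.shape == (8, 5)
        assert np.allclose(np.linalg.norm(P, axis=0), 1.0)
        # each column lies in the span of some node's 3 orientation fields
        found = 0
        for j in range(5):
            for node in range(20):
                resid = np.linalg.lstsq(lf[:, node], P[:, j], rcond=None)[1]
                if resid.size and resid[0] < 1e-18:
                    found += 1
                    break
        assert found == 5

    def test_layout_deterministic(self):
        assert np.array_equal(electrode_layout(64), electrode_layout(64))


class TestSNRNormalization:
    @staticmethod
    def _setup(seed=0, k=3, m=10, T=5000, n_ch=16):
        rng = np.random.default_rng(seed)
        S = rng.standard_normal((k, T))
        N = rng.standard_normal((m, T))
        P = gen_patterns(k + m, n_ch, seed=rng)
        return S, N, P

    def _per_dipole_ratio(self, S, N, P, scales):
        k = S.shape[0]
        Pn = P[:, k:]
        noise_var = np.mean(np.var((Pn @ N).T, axis=0))
        out = []
        for i in range(k):
            proj = np.outer(P[:, i], scales[i] * S[i]).T
            out.append(np.mean(np.var(proj, axis=0)) / noise_var)
        return np.asarray(out)

    def test_unity_target_matches_noise_variance(self):
        S, N, P = self._setup()
        _, scales = normalize_snr(S, N, P, 1.0)
        assert np.allclose(self._per_dipole_ratio(S, N, P, scales), 1.0, atol=1e-10)

    def test_doubling_target_scales_amplitude_by_sqrt2(self):
        S, N, P = self._setup(seed=1)
        _, s1 = normalize_snr(S, N, P, 1.0)
        _, s2 = normalize_snr(S, N, P, 2.0)
        assert np.allclose(s2 / s1, np.sqrt(2.0), atol=1e-12)

    def test_low_snr_recomputes_exactly(self):
        S, N, P = self._setup(seed=2)
        _, scales = normalize_snr(S, N, P, 0.1)
        assert np.allclose(self._per_dipole_ratio(S, N, P, scales), 0.1, atol=1e-10)

    def test_zero_noise_rejected(self):
        S, N, P = self._setup(seed=3)
        with pytest.raises(ValueError):
            normalize_snr(S, np.zeros_like(N), P, 1.0)

    def test_nonpositive_target_rejected(self):
        S, N, P = self._setup(seed=4)
        with pytest.raises(ValueError):
            normalize_snr(S, N, P, 0.0)


class TestDataset:
    def test_default_dimensions(self):
        spec = SimulationSpec(ratio=(1, 2), seed=0)
        X, truth = gen_dataset(spec)
        assert X.shape == (30_000, 64)
        assert truth.source_patterns.shape == (64, 110)
        assert truth.source_signals.shape == (110, 30_000)
        assert len(truth.coupled_pair_index) == 5

    def test_uncoupled_pairs_are_independent(self):
        spec = SimulationSpec(ratio=(2, 3), coupled=False, duration_s=150.0, n_channels=8, n_noise=5, seed=1)
        _, truth = gen_dataset(spec)
        for phi_ref, phi_fit in truth.pair_phases:
            assert cf_plv(phi_ref, phi_fit, (2, 3)) < 0.1

    def test_noiseless_limit_exact_mixture(self):
        spec = SimulationSpec(ratio=(1, 2), n_noise=0, snr=np.inf, n_channels=8, duration_s=10.0, seed=2)
        X, truth = gen_dataset(spec)
        recon = (truth.source_patterns @ truth.source_signals).T
        assert np.allclose(X, recon, atol=1e-12)

    def test_bit_exact_reproducibility(self):
        spec = dict(ratio=(3, 2), n_pairs=2, n_noise=10, n_channels=8, duration_s=10.0, seed=9)
        X1, t1 = gen_dataset(SimulationSpec(**spec))
        X2, t2 = gen_dataset(SimulationSpec(**spec))
        assert np.array_equal(X1, X2)
        assert np.array_equal(t1.source_patterns, t2.source_patterns)

    def test_sensor_snr_honoured(self):
        spec = SimulationSpec(ratio=(1, 2), n_pairs=2, n_noise=20, n_channels=16, duration_s=20.0, snr=0.5, seed=3)
        X, truth = gen_dataset(spec)
        k = 2 * spec.n_pairs
        noise_proj = (truth.source_patterns[:, k:] @ truth.source_signals[k:]).T
        noise_var = np.mean(np.var(noise_proj, axis=0))
        for i in range(k):
            proj = np.outer(truth.source_patterns[:, i], truth.source_signals[i]).T
            ratio = np.mean(np.var(proj, axis=0)) / noise_var
            assert ratio == pytest.approx(0.5, rel=1e-8)
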