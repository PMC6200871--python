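"""End-to-end decomposition workflow: pattern computation, pair ranking,
secondary-SSD consistency, determinism and the base-frequency scan."""

import numpy as np
import pytest

from conftest import FS
from gcfd.decomposition import GCFD, compute_pattern, run_gcfd, scan_base_frequency
from gcfd.evaluate import greedy_match, pattern_divergence
from gcfd.signal_core import BandDefinition, cf_plv, analytic, edge_slice
from gcfd.simulate import SimulationSpec, gen_dataset


class TestComputePattern:
    def test_self_regression_is_unity(self, rng):
        s = rng.standard_normal(500)
        assert compute_pattern(s[:, None], s) == pytest.approx([1.0])

    def test_exact_rank_one_model(self, rng):
        s = rng.standard_normal(1000)
        v = rng.standard_normal(7)
        M = np.outer(s, v)
        p = compute_pattern(M, s)
        assert pattern_divergence(p, v) < 1e-12

    def test_equivalent_to_covariance_times_filter(self, rng):
        # regression form M's/(s's) with s = Mw is proportional to Cov(M) w
        M = rng.standard_normal((2000, 6))
        M -= M.mean(axis=0)
        w = rng.standard_normal(6)
        p = compute_pattern(M, M @ w)
        cov_w = np.cov(M.T) @ w
        assert pattern_divergence(p, cov_w) < 1e-10

    def test_zero_energy_rejected(self):
        with pytest.raises(ValueError):
            compute_pattern(np.ones((10, 2)), np.zeros(10))


def small_coupled_dataset(ratio=(1, 2), seed=0, n_channels=12, n_pairs=2, n_noise=10,
                          duration_s=30.0, snr=1.0, coupled=True):
    spec = SimulationSpec(
        n_pairs=n_pairs, n_noise=n_noise, n_channels=n_channels,
        duration_s=duration_s, ratio=ratio, snr=snr, coupled=coupled, seed=seed,
    )
    return gen_dataset(spec)


def scaled_bands(ratio):
    # harmonic bands of the 9-11 Hz base rhythm
    return dict(
        ref_band=BandDefinition(10.0).scaled(ratio[0]),
        fit_band=BandDefinition(10.0).scaled(ratio[1]),
    )


class TestRunGcfd:
    def test_recovers_planted_pairs(self):
        X, truth = small_coupled_dataset(ratio=(3, 2), seed=5, n_channels=24, duration_s=40.0, snr=0.5)
        pairs = run_gcfd(
            X, f1=30.0, ratio=(3, 2), fs=FS, n_reference=3, n_secondary=8,
            n_restarts=3, random_state=0, **scaled_bands((3, 2)),
        )
        rec = np.column_stack([p.fit_pattern for p in pairs])
        report = greedy_match(rec, truth.fit_patterns)
        assert np.median(report.divergences) < 0.08

    def test_plvs_sorted_descending_in_unit_interval(self):
        X, _ = small_coupled_dataset(seed=6, duration_s=20.0)
        pairs = run_gcfd(X, f1=10.0, ratio=(1, 2), fs=FS, n_reference=3, n_secondary=0,
                         n_restarts=2, random_state=0, **scaled_bands((1, 2)))
        plvs = [p.plv for p in pairs]
        assert all(0.0 <= v <= 1.0 for v in plvs)
        assert plvs == sorted(plvs, reverse=True)

    def test_pair_plv_recomputable(self):
        X, _ = small_coupled_dataset(seed=7, duration_s=20.0)
        pair = run_gcfd(X, f1=10.0, ratio=(1, 2), fs=FS, n_reference=2, n_secondary=0,
                        n_restarts=2, random_state=1, **scaled_bands((1, 2)))[0]
        keep = edge_slice(len(pair.reference_component), FS, 1.0)
        plv = cf_plv(
            np.angle(analytic(pair.reference_component))[keep],
            np.angle(analytic(pair.fit_component))[keep],
            pair.ratio,
        )
        assert plv == pytest.approx(pair.plv, abs=1e-10)

    def test_single_channel_perfect_pair(self):
        from gcfd.simulate import gen_coupled_pair

        # a narrow base rhythm keeps the pair well inside the analysis bands
        spec = SimulationSpec(n_pairs=1, n_noise=0, n_channels=2, duration_s=20.0,
                              ratio=(1, 2), snr=np.inf, seed=8, base_band=(9.8, 10.2))
        low, high = gen_coupled_pair(spec)
        X = (low + high)[:, None]
        pairs = run_gcfd(X, f1=10.0, ratio=(1, 2), fs=FS, n_restarts=2, random_state=0,
                         **scaled_bands((1, 2)))
        assert len(pairs) == 1
        assert pairs[0].plv > 0.99

    def test_fit_band_above_nyquist_rejected(self):
        X, _ = small_coupled_dataset(seed=9, duration_s=10.0)
        with pytest.raises(ValueError):
            run_gcfd(X, f1=60.0, ratio=(1, 2), fs=FS)

    def test_secondary_ssd_consistent_with_full_space(self):
        X, truth = small_coupled_dataset(ratio=(1, 2), seed=10, n_channels=16,
                                         n_pairs=2, n_noise=8, duration_s=40.0, snr=2.0)
        common = dict(f1=10.0, ratio=(1, 2), fs=FS, n_reference=2, n_restarts=2,
                      random_state=0, **scaled_bands((1, 2)))
        full = run_gcfd(X, n_secondary=0, **common)
        reduced = run_gcfd(X, n_secondary=8, **common)
        assert pattern_divergence(full[0].fit_pattern, reduced[0].fit_pattern) < 0.05

    def test_deterministic_given_seed(self):
        X, _ = small_coupled_dataset(seed=11, duration_s=20.0)
        kw = dict(f1=10.0, ratio=(1, 2), fs=FS, n_reference=2, n_secondary=0,
                  n_restarts=2, random_state=77, **scaled_bands((1, 2)))
        a = run_gcfd(X, **kw)
        b = run_gcfd(X, **kw)
        assert [p.plv for p in a] == [p.plv for p in b]
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.fit_pattern, pb.fit_pattern)

    def test_clamps_reference_count_with_warning(self):
        X, _ = small_coupled_dataset(seed=12, n_channels=3, n_noise=4, duration_s=15.0)
        with pytest.warns(UserWarning, match="clamped"):
            pairs = run_gcfd(X, f1=10.0, ratio=(1, 2), fs=FS, n_reference=10,
                             n_secondary=0, n_restarts=1, random_state=0,
                             **scaled_bands((1, 2)))
        assert len(pairs) == 3


class TestScanBaseFrequency:
    def test_recovers_planted_base_frequency(self):
        spec = SimulationSpec(n_pairs=1, n_noise=4, n_channels=6, duration_s=40.0,
                              ratio=(1, 2), snr=2.0, seed=13, base_band=(9.4, 10.4))
        X, _ = gen_dataset(spec)  # base centred at 9.9 Hz
        grid = np.arange(9.0, 11.01, 0.25)
        base, pair, by_base = scan_base_frequency(
            X, (1, 2), grid, fs=FS, n_reference=1, n_secondary=0,
            n_restarts=1, random_state=0, preprocess=False,
        )
        assert abs(base - 9.9) <= 0.2
        assert by_base[base] == pair.plv

    def test_single_point_grid_matches_run(self):
        X, _ = small_coupled_dataset(seed=14, duration_s=15.0, n_channels=6, n_noise=4)
        base, pair, _ = scan_base_frequency(X, (1, 2), [10.0], fs=FS, n_reference=1,
                                            n_secondary=0, n_restarts=1, random_state=0)
        direct = run_gcfd(X, f1=10.0, ratio=(1, 2), fs=FS, n_reference=1, n_secondary=0,
                          n_restarts=1, random_state=0)[0]
        assert base == 10.0
        assert pair.plv == pytest.approx(direct.plv, abs=1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            scan_base_frequency(np.zeros((100, 2)), (1, 2), [], fs=FS)
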