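"""Analysis metrics: whitening, SNR, tuning, FWHM, Fisher information,
weight-width correlation, receptive-field localization."""

import numpy as np
import pytest

from corrinv.metrics import (
    estimate_tuning,
    fisher_information,
    fwhm,
    optimal_linear_decoder,
    output_snr,
    rf_localization_index,
    weight_width_correlation,
    whitening_matrix,
)
from corrinv.signals import circ_gauss


class TestWhitening:
    def test_identity_covariance(self, rng):
        X = rng.normal(size=(200_000, 3))
        M = whitening_matrix(X)
        assert np.allclose(M, np.eye(3), atol=0.02)

    def test_diagonal_closed_form(self, rng):
        X = rng.normal(size=(500_000, 2)) * np.array([2.0, 1.0])
        M = whitening_matrix(X)
        assert np.allclose(M, np.diag([0.5, 1.0]), atol=0.01)

    def test_whitened_covariance_is_identity(self, rng):
        A = rng.normal(size=(10, 10))
        X = rng.normal(size=(5_000, 10)) @ A
        M = whitening_matrix(X)
        C = (M @ X.T) @ (M @ X.T).T / len(X)
        assert np.allclose(C, np.eye(10), atol=1e-8)
        assert np.allclose(M, M.T)
        assert np.all(np.linalg.eigvalsh(M) > 0)

    def test_rank_deficient_raises_without_flag(self, rng):
        X = rng.normal(size=(1000, 3))
        X[:, 2] = X[:, 0] + X[:, 1]
        with pytest.raises(np.linalg.LinAlgError):
            whitening_matrix(X)
        M = whitening_matrix(X, pseudo_inverse=True)  # deficient mode works
        assert np.all(np.isfinite(M))


class TestOutputSNR:
    def test_exact_reconstruction_flags_inf(self, rng):
        s = rng.normal(size=1000)
        assert output_snr(s, s) == np.inf

    def test_equal_variance_noise_gives_unit_snr(self, rng):
        s = rng.normal(size=500_000)
        y = s + rng.normal(size=500_000)
        assert output_snr(y, s) == pytest.approx(1.0, abs=0.05)

    def test_independent_signal_gives_zero(self, rng):
        assert output_snr(rng.normal(size=100_000), rng.normal(size=100_000)) < 0.01

    def test_constant_output(self, rng):
        assert output_snr(np.ones(100), rng.normal(size=100)) == 0.0


class TestOptimalDecoder:
    def test_single_perfect_channel(self, rng):
        s = rng.normal(size=1000)
        w, snr = optimal_linear_decoder(s[:, None], s)
        assert w[0] == pytest.approx(1.0)
        assert snr == np.inf

    def test_symmetric_channels_get_equal_weights(self, rng):
        s = rng.normal(size=400_000)
        X = np.stack([s + rng.normal(size=len(s)), s + rng.normal(size=len(s))], axis=1)
        w, _ = optimal_linear_decoder(X, s)
        assert w[0] == pytest.approx(w[1], rel=0.02)

    def test_learned_snr_never_beats_decoder_on_linear_readouts(self, rng):
        # OLS optimality among linear readouts of the same inputs
        s = rng.normal(size=100_000)
        X = s[:, None] * np.array([1.0, 0.5]) + rng.normal(size=(100_000, 2))
        w_opt, snr_opt = optimal_linear_decoder(X, s)
        for _ in range(5):
            w = rng.normal(size=2)
            assert output_snr(X @ w, s) <= snr_opt * (1 + 1e-9)


class TestEstimateTuning:
    def test_recovers_noiseless_generator_curve(self):
        theta = np.linspace(0, 1, 64_000, endpoint=False)
        y = circ_gauss(theta, 0.5, 0.05)
        tun = estimate_tuning(y[:, None], theta, n_bins=64, min_count=50)
        expect = circ_gauss(tun.theta_grid, 0.5, 0.05)
        assert np.abs(tun.mean_response[0] - expect).max() < 0.01

    def test_bin_means_match_brute_force(self, rng):
        theta = rng.uniform(0, 1, 20_000)
        Y = rng.normal(size=(20_000, 3)) + theta[:, None]
        tun = estimate_tuning(Y, theta, n_bins=16, min_count=50)
        b = np.minimum((theta * 16).astype(int), 15)
        for k in range(16):
            assert np.allclose(tun.mean_response[:, k], Y[b == k].mean(axis=0))

    def test_sparse_occupancy_rejected(self, rng):
        theta = rng.uniform(0, 0.5, 1000)  # half the circle never visited
        with pytest.raises(ValueError):
            estimate_tuning(rng.normal(size=(1000, 2)), theta, n_bins=32)


class TestFWHM:
    def test_circular_gaussian_width(self):
        grid = (np.arange(256) + 0.5) / 256
        curve = circ_gauss(grid, 0.5, 0.05)
        w = fwhm(curve, grid)
        assert w == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 0.05, abs=0.005)

    def test_triangular_peak_interpolation_exact(self):
        grid = (np.arange(100) + 0.5) / 100
        curve = np.maximum(0.0, 1.0 - np.abs(grid - 0.5) / 0.1)
        assert fwhm(curve, grid) == pytest.approx(0.1, abs=0.005)

    def test_affine_invariance(self, rng):
        grid = (np.arange(128) + 0.5) / 128
        curve = circ_gauss(grid, 0.3, 0.07)
        w0 = fwhm(curve, grid)
        assert fwhm(5.0 * curve + 2.0, grid) == pytest.approx(w0, abs=1e-12)

    def test_peak_wrapping_across_zero(self):
        grid = (np.arange(128) + 0.5) / 128
        curve = circ_gauss(grid, 0.0, 0.05)  # peak at the wrap point
        assert fwhm(curve, grid) == pytest.approx(0.118, abs=0.01)

    def test_flat_curve_rejected(self):
        grid = np.linspace(0, 1, 64, endpoint=False)
        with pytest.raises(ValueError):
            fwhm(np.ones(64), grid)


class TestFisherInformation:
    @staticmethod
    def _single_neuron_tuning(sd_noise, n=400_000, seed=0, n_bins=64):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, 1, n)
        f = circ_gauss(theta, 0.5, 0.1)
        y = f + rng.normal(0, sd_noise, n)
        return estimate_tuning(y[:, None], theta, n_bins=n_bins, min_count=50, with_cov=True)

    def test_single_neuron_closed_form(self):
        sd = 0.5  # large noise so bin-discretization variance is negligible
        tun = self._single_neuron_tuning(sd)
        grid = tun.theta_grid
        d = grid - 0.5
        fp = -d / 0.1**2 * circ_gauss(grid, 0.5, 0.1)
        expect = np.mean(fp**2) / sd**2
        assert fisher_information(tun) == pytest.approx(expect, rel=0.05)

    def test_doubling_noise_quarters_information(self):
        j1 = fisher_information(self._single_neuron_tuning(0.5, seed=1))
        j2 = fisher_information(self._single_neuron_tuning(1.0, seed=1))
        assert j1 / j2 == pytest.approx(4.0, rel=0.1)

    def test_independent_neurons_add(self, rng):
        theta = rng.uniform(0, 1, 400_000)
        f = circ_gauss(theta, 0.5, 0.1)
        y1 = f + rng.normal(0, 0.5, len(theta))
        y2 = f + rng.normal(0, 0.5, len(theta))
        t1 = estimate_tuning(y1[:, None], theta, n_bins=64, min_count=50, with_cov=True)
        t2 = estimate_tuning(np.stack([y1, y2], 1), theta, n_bins=64, min_count=50, with_cov=True)
        assert fisher_information(t2) / fisher_information(t1) == pytest.approx(2.0, rel=0.1)

    def test_invariant_to_neuron_relabeling(self, rng):
        theta = rng.uniform(0, 1, 100_000)
        Y = np.stack([circ_gauss(theta, c, 0.1) + rng.normal(0, 0.3, len(theta)) for c in (0.2, 0.5, 0.8)], 1)
        t_a = estimate_tuning(Y, theta, n_bins=64, min_count=50, with_cov=True)
        t_b = estimate_tuning(Y[:, ::-1], theta, n_bins=64, min_count=50, with_cov=True)
        assert fisher_information(t_a) == pytest.approx(fisher_information(t_b), rel=1e-6)


class TestWeightWidthCorrelation:
    def test_equal_widths_rejected(self, rng):
        with pytest.raises(ValueError):
            weight_width_correlation(rng.normal(size=(4, 10)), np.full(10, 0.05))

    def test_perfect_negative_relation(self):
        widths = np.linspace(0.02, 0.1, 20)
        W = (0.5 - 2.0 * widths)[None, :]
        assert weight_width_correlation(W, widths) == pytest.approx(-1.0)

    def test_random_weights_uncorrelated(self, rng):
        widths = rng.uniform(0.02, 0.1, 100)
        rs = [
            weight_width_correlation(rng.normal(size=(16, 100)), widths)
            for _ in range(40)
        ]
        assert np.mean(np.abs(rs) < 0.2) > 0.9


class TestRFLocalization:
    def test_single_pixel_is_perfectly_localized(self):
        m = np.zeros((16, 16))
        m[7, 3] = 2.0
        assert rf_localization_index(m) == pytest.approx(1.0)

    def test_uniform_map_exact_ratio(self):
        m = np.ones((16, 16))
        assert rf_localization_index(m) == pytest.approx(16 / 256)

    def test_matches_brute_force_window_scan(self, rng):
        m = rng.normal(size=(12, 12))
        k = 3
        best = max(
            (m[i : i + k, j : j + k] ** 2).sum()
            for i in range(10)
            for j in range(10)
        )
        assert rf_localization_index(m, k=3) == pytest.approx(best / (m**2).sum())

    def test_zero_map_rejected(self):
        with pytest.raises(ValueError):
            rf_localization_index(np.zeros((8, 8)))
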