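"""Synthetic input generators: statistics, determinism, degenerate cases."""

import numpy as np
import pytest
from scipy.stats import kurtosis

from corrinv.signals import (
    GroupSpec,
    PatchSpec,
    TuningPopulationSpec,
    apply_linear_mixing,
    gen_fig1_dataset,
    gen_fig2_dataset,
    gen_image_patches,
    gen_ou,
    gen_population_dataset,
    gen_sparse_on_off,
    population_probe,
)

SPARSE = GroupSpec("s", 20, "sparse_on_off", 1.0, 0.5, timescale_ms=1000.0)
OU = GroupSpec("o", 20, "ou", 1.0, 0.5, timescale_ms=200.0)


class TestSparseOnOff:
    def test_zero_amplitude_gives_pure_noise(self):
        spec = GroupSpec("s", 5, "sparse_on_off", 0.0, 0.3, timescale_ms=1000.0)
        x, latent = gen_sparse_on_off(10_000, spec, seed=0)
        assert np.all(latent == 0.0)
        assert abs(x.std() - 0.3) < 0.02

    def test_duty_cycle_matches_renewal_theory(self):
        # ON duration 100, mean ISI 1000 -> ON fraction 100/1100
        _, latent = gen_sparse_on_off(100_000, SPARSE, seed=3)
        on_frac = np.mean(latent > 0)
        assert on_frac == pytest.approx(100 / 1100, abs=0.01)

    def test_per_channel_sd_matches_requested_signal_sd(self):
        spec = GroupSpec("s", 10, "sparse_on_off", 1.0, 0.0, timescale_ms=1000.0)
        x, _ = gen_sparse_on_off(200_000, spec, seed=5)
        x = x - x.mean(axis=0)
        assert x.std() == pytest.approx(1.0, rel=0.05)

    def test_invalid_timescale_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec("s", 5, "sparse_on_off", 1.0, 0.1, timescale_ms=0.0)


class TestOU:
    def test_lag_tau_autocorrelation_is_inv_e(self):
        _, latent = gen_ou(1_000_000, OU, seed=2)
        lag = 200
        r = np.corrcoef(latent[:-lag], latent[lag:])[0, 1]
        assert r == pytest.approx(np.exp(-1), abs=0.05)

    def test_common_component_is_gaussian(self):
        _, latent = gen_ou(1_000_000, OU, seed=4)
        assert kurtosis(latent) == pytest.approx(0.0, abs=0.05)

    def test_stationary_sd(self):
        _, latent = gen_ou(500_000, OU, seed=6)
        assert latent.std() == pytest.approx(1.0, rel=0.05)


class TestFig1Dataset:
    def test_channel_layout(self, fig1_batch):
        assert fig1_batch.n_channels == 60
        assert [g.spec.n_inputs for g in fig1_batch.groups] == [20, 20, 20]

    def test_mean_subtraction(self, fig1_batch):
        assert np.abs(fig1_batch.data.mean(axis=0)).max() < 1e-12

    def test_sparse_group_is_more_kurtotic_than_network(self, fig1_batch):
        sp = fig1_batch.data[:, fig1_batch.group_slice("sparse").channels]
        net = fig1_batch.data[:, fig1_batch.group_slice("network").channels]
        # common-component kurtosis: project on the uniform loading
        k_sp = kurtosis(sp.mean(axis=1))
        k_net = kurtosis(net.mean(axis=1))
        assert k_sp > 1.0
        assert abs(k_net) < 0.5
        assert k_sp > k_net

    def test_deterministic_given_seed(self):
        a = gen_fig1_dataset(5_000, seed=7)
        b = gen_fig1_dataset(5_000, seed=7)
        assert np.array_equal(a.data, b.data)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_sparse_kurtosis_exceeds_gaussian_on_every_seed(self, seed):
        batch = gen_fig1_dataset(100_000, seed=seed)
        sp = batch.data[:, batch.group_slice("sparse").channels].mean(axis=1)
        net = batch.data[:, batch.group_slice("network").channels].mean(axis=1)
        assert kurtosis(sp) > kurtosis(net)


class TestFig2Dataset:
    def test_amplitude_variant_has_equal_subgroup_snr(self):
        b = gen_fig2_dataset("amplitude", 100_000, seed=2)
        snrs = [g.spec.signal_sd / g.spec.noise_sd for g in b.groups[:3]]
        assert max(snrs) / min(snrs) == pytest.approx(1.0, rel=0.02)

    def test_noise_variant_has_equal_signal_sds(self):
        b = gen_fig2_dataset("noise", 50_000, seed=2)
        assert [g.spec.signal_sd for g in b.groups[:3]] == [1.0, 1.0, 1.0]
        assert [g.spec.noise_sd for g in b.groups[:3]] == [1.5, 1.0, 0.7]

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            gen_fig2_dataset("nonsense", 100, seed=0)

    def test_empty_batch_keeps_metadata(self):
        b = gen_fig2_dataset("amplitude", 0, seed=0)
        assert b.n_samples == 0
        assert len(b.groups) == 5

    def test_subgroups_share_one_latent(self):
        b = gen_fig2_dataset("noise", 50_000, seed=3)
        on = b.latent > 0
        means = [b.data[on][:, g.channels].mean() for g in b.groups[:3]]
        # all subgroups rise together during ON states
        assert all(m > 1.0 for m in means)


class TestPopulationDataset:
    def test_homogeneous_widths_and_centers(self):
        b = gen_population_dataset(TuningPopulationSpec(), 1_000, seed=0)
        assert np.allclose(b.meta["widths"], 0.05)
        assert np.allclose(np.diff(b.meta["centers"]), 0.01)

    def test_zero_heterogeneity_multipliers_are_one(self):
        b = gen_population_dataset(TuningPopulationSpec(heterogeneity_sd=0.0), 100, seed=1)
        assert np.allclose(b.meta["amplitudes"], 1.0)
        assert np.allclose(b.meta["noise_sds"], 0.01)

    def test_heterogeneity_multipliers_positive(self):
        b = gen_population_dataset(TuningPopulationSpec(heterogeneity_sd=0.2), 100, seed=1)
        assert np.all(b.meta["widths"] > 0)
        assert np.all(b.meta["amplitudes"] > 0)
        assert not np.allclose(b.meta["widths"], 0.05)

    def test_latent_covers_the_circle(self):
        b = gen_population_dataset(TuningPopulationSpec(), 1_000_000, seed=5)
        hist, _ = np.histogram(b.latent, bins=10, range=(0, 1))
        assert hist.min() > 0
        # the smoothed walk traverses the circle ~100x per 1e6 samples
        d = np.diff(b.latent)
        d = np.where(d > 0.5, d - 1, np.where(d < -0.5, d + 1, d))
        traversals = np.abs(d).sum()
        assert 30 < traversals < 300

    def test_too_few_inputs_rejected(self):
        with pytest.raises(ValueError):
            gen_population_dataset(TuningPopulationSpec(n_inputs=1), 100, seed=0)

    def test_probe_matches_generator_statistics(self):
        b = gen_population_dataset(TuningPopulationSpec(), 50_000, seed=2)
        X, th = population_probe(b, n_samples=6_400, seed=0, mode="grid")
        assert X.shape == (6_400, 100)
        # undoing the stored offsets recovers the tuning curves: under
        # uniform theta each channel's mean is the wrapped-Gaussian integral
        raw_means = (X + b.meta["channel_means"]).mean(axis=0)
        assert np.allclose(raw_means, 0.05 * np.sqrt(2 * np.pi), atol=0.01)


class TestImagePatches:
    def test_on_off_split_is_disjoint(self):
        _, on, off = gen_image_patches(PatchSpec(patch_size=8), 50, seed=1)
        assert np.all(on * off == 0.0)
        assert np.all(on >= 0) and np.all(off >= 0)

    def test_adjacent_pixel_correlation(self):
        p, _, _ = gen_image_patches(PatchSpec(patch_size=16), 1_000, seed=2)
        r = np.corrcoef(p[:, :, :-1].ravel(), p[:, :, 1:].ravel())[0, 1]
        assert r > 0.3

    def test_filter_responses_are_sparse(self):
        # oriented structure appears as heavy-tailed filter responses
        p, _, _ = gen_image_patches(PatchSpec(patch_size=8), 4_000, seed=3)
        g = np.zeros((8, 8))
        g[3:5, 2:6] = 1.0
        g[2, 2:6] = g[5, 2:6] = -0.5
        resp = (p * g).sum(axis=(1, 2))
        assert kurtosis(resp) > 1.0

    def test_patch_size_validation(self):
        with pytest.raises(ValueError):
            PatchSpec(patch_size=3)

    def test_determinism(self):
        a = gen_image_patches(PatchSpec(patch_size=8), 10, seed=9)[0]
        b = gen_image_patches(PatchSpec(patch_size=8), 10, seed=9)[0]
        assert np.array_equal(a, b)


class TestLinearMixing:
    def test_identity_is_noop(self, fig1_batch):
        out = apply_linear_mixing(fig1_batch, np.eye(60))
        assert np.array_equal(out.data, fig1_batch.data)
        assert out.mixed

    def test_scaling_doubles_sds(self, fig1_batch):
        out = apply_linear_mixing(fig1_batch, 2.0 * np.eye(60))
        assert np.allclose(out.data.std(axis=0), 2.0 * fig1_batch.data.std(axis=0))

    def test_covariance_transforms_as_L_C_Lt(self, fig1_batch, rng):
        L = rng.normal(size=(60, 60)) / 8 + np.eye(60)
        out = apply_linear_mixing(fig1_batch, L)
        C = np.cov(fig1_batch.data.T)
        Cm = np.cov(out.data.T)
        assert np.allclose(Cm, L @ C @ L.T, atol=1e-8)

    def test_singular_matrix_rejected(self, fig1_batch):
        L = np.zeros((60, 60))
        with pytest.raises(ValueError):
            apply_linear_mixing(fig1_batch, L)
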