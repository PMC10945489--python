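"""Slab centering, density profiles, and tanh interface fits."""

import numpy as np
import pytest

from aquaphase.constants import A3_TO_L, M_WATER, N_AVOGADRO
from aquaphase.slab import (
    Configuration,
    center_slab,
    density_profile,
    fit_interfaces,
    tanh_profile,
)
from aquaphase.synthetic import SlabSpec, gen_slab_frames

BOX = (20.0, 20.0, 100.0)


def centered_slab_config(seed=0, n=500, half_width=15.0):
    rng = np.random.default_rng(seed)
    z = 50.0 + rng.uniform(-half_width, half_width, n)
    xy = rng.random((n, 2)) * 20.0
    return Configuration(box=BOX, positions=np.column_stack([xy, z]))


def translate_z(config, delta):
    pos = config.positions.copy()
    pos[:, 2] += delta
    return Configuration(box=config.box, positions=pos)


class TestCenterSlab:
    def test_idempotent(self):
        once = center_slab(centered_slab_config())
        twice = center_slab(once)
        np.testing.assert_allclose(
            np.sort(twice.positions[:, 2]), np.sort(once.positions[:, 2]), atol=1e-6
        )

    def test_symmetric_slab_already_centered_is_unchanged(self):
        # mirror-symmetric about Lz/2, so the periodic mass center is exact
        z_half = 50.0 + np.linspace(1.0, 14.0, 40)
        z = np.concatenate([z_half, 100.0 - z_half])
        pos = np.column_stack([np.full(80, 10.0), np.full(80, 10.0), z])
        cfg = Configuration(box=BOX, positions=pos)
        out = center_slab(cfg)
        np.testing.assert_allclose(
            np.sort(out.positions[:, 2]), np.sort(cfg.positions[:, 2]), atol=1e-9
        )

    def test_recovers_slab_straddling_boundary(self):
        centered = center_slab(centered_slab_config())
        split = translate_z(centered, 50.0)  # half near z=0, half near z=Lz
        out = center_slab(split)
        np.testing.assert_allclose(
            np.sort(out.positions[:, 2]), np.sort(centered.positions[:, 2]), atol=1e-6
        )

    @pytest.mark.parametrize("delta", np.linspace(-120.0, 120.0, 9))
    def test_translation_covariance(self, delta):
        cfg = centered_slab_config(seed=3)
        a = center_slab(cfg)
        b = center_slab(translate_z(cfg, delta))
        np.testing.assert_allclose(
            np.sort(a.positions[:, 2]), np.sort(b.positions[:, 2]), atol=1e-6
        )

    def test_pairwise_periodic_distances_preserved(self):
        cfg = centered_slab_config(seed=5, n=40)
        out = center_slab(translate_z(cfg, 37.3))
        lz = BOX[2]

        def pairdists(c):
            dz = np.abs(c.positions[:, 2][:, None] - c.positions[:, 2][None, :])
            return np.sort(np.minimum(dz, lz - dz), axis=None)

        np.testing.assert_allclose(pairdists(out), pairdists(cfg), atol=1e-6)

    def test_uniform_gas_returned_unchanged(self):
        rng = np.random.default_rng(0)
        cfg = Configuration(box=BOX, positions=rng.random((2000, 3)) * np.array(BOX))
        assert center_slab(cfg) is cfg

    def test_empty_configuration_errors(self):
        cfg = Configuration(box=BOX, positions=np.empty((0, 3)))
        with pytest.raises(ValueError):
            center_slab(cfg)


class TestDensityProfile:
    def test_mass_conservation(self, slab_profile_fixture):
        profile, _ = slab_profile_fixture
        lx, ly, _ = profile.box
        total_mass = np.sum(profile.density) * profile.bin_width * lx * ly * A3_TO_L
        expected = profile.n_molecules * profile.mass_per_molecule / N_AVOGADRO
        assert total_mass == pytest.approx(expected, rel=1e-9)

    def test_delta_distribution_single_bin(self):
        n = 64
        pos = np.column_stack([np.full(n, 10.0), np.full(n, 10.0), np.full(n, 50.2)])
        cfg = Configuration(box=BOX, positions=pos)
        profile = density_profile([cfg], bin_width=0.5, center=False)
        occupied = profile.density > 0
        assert occupied.sum() == 1
        expected = n * M_WATER / N_AVOGADRO / (20.0 * 20.0 * 0.5 * A3_TO_L)
        assert profile.density[occupied][0] == pytest.approx(expected, rel=1e-12)

    def test_plateau_and_vapor_levels_match_generator(self, slab_profile_fixture):
        profile, truth = slab_profile_fixture
        z = profile.bin_centers
        plateau = (z > truth.z_lo + 5 * truth.w) & (z < truth.z_hi - 5 * truth.w)
        vapor = (z < truth.z_lo - 5 * truth.w) | (z > truth.z_hi + 5 * truth.w)
        assert np.mean(profile.density[plateau]) == pytest.approx(truth.rho_l, rel=0.02)
        assert np.mean(profile.density[vapor]) == pytest.approx(truth.rho_v, abs=2.0)

    def test_translation_invariance_of_profile(self, slab_frames):
        frames, _ = slab_frames
        subset = frames[:20]
        shifted = [translate_z(c, 13.7) for c in subset]
        a = density_profile(subset, bin_width=0.5)
        b = density_profile(shifted, bin_width=0.5)
        np.testing.assert_allclose(a.density, b.density, atol=1e-9)

    def test_inconsistent_boxes_rejected(self):
        a = centered_slab_config()
        b = Configuration(box=(20.0, 20.0, 90.0), positions=a.positions)
        with pytest.raises(ValueError):
            density_profile([a, b])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            density_profile([])


class TestFitInterfaces:
    def test_noiseless_model_profile_recovered_exactly(self):
        from aquaphase.slab import DensityProfile

        z = np.arange(0.25, 100.0, 0.5)
        rho = tanh_profile(z, 25.0, 900.0, 30.0, 70.0, 3.0)
        profile = DensityProfile(
            bin_centers=z, density=rho, n_frames=1, bin_width=0.5,
            box=BOX, n_molecules=1,
        )
        fit = fit_interfaces(profile)
        assert fit.converged and not fit.indistinct_phases
        assert fit.rho_l == pytest.approx(900.0, rel=1e-6)
        assert fit.rho_v == pytest.approx(25.0, rel=1e-6)
        assert fit.z_lo == pytest.approx(30.0, rel=1e-6)
        assert fit.z_hi == pytest.approx(70.0, rel=1e-6)
        assert fit.w == pytest.approx(3.0, rel=1e-6)
        assert fit.rmse < 1e-8

    def test_synthetic_slab_densities_recovered(self, slab_profile_fixture):
        profile, truth = slab_profile_fixture
        fit = fit_interfaces(profile)
        assert fit.converged and not fit.indistinct_phases
        assert fit.rho_l == pytest.approx(truth.rho_l, rel=0.01)
        assert fit.rho_v == pytest.approx(truth.rho_v, abs=2.0)

    def test_flat_profile_flagged_indistinct(self):
        from aquaphase.slab import DensityProfile

        z = np.arange(0.25, 100.0, 0.5)
        profile = DensityProfile(
            bin_centers=z, density=np.full_like(z, 300.0), n_frames=1,
            bin_width=0.5, box=BOX, n_molecules=1,
        )
        fit = fit_interfaces(profile)
        assert fit.indistinct_phases

    def test_noisy_flat_profile_flagged_not_raised(self):
        from aquaphase.slab import DensityProfile

        rng = np.random.default_rng(7)
        z = np.arange(0.25, 100.0, 0.5)
        rho = 300.0 + rng.normal(0.0, 5.0, z.size)
        profile = DensityProfile(
            bin_centers=z, density=rho, n_frames=1, bin_width=0.5,
            box=BOX, n_molecules=1,
        )
        fit = fit_interfaces(profile)  # must not raise
        assert fit.indistinct_phases or not fit.converged
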