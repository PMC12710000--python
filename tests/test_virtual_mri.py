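"""Voxelization, water noise, Weierstrass transform, and volume I/O."""

import numpy as np
import pytest

import rsaeval as rv
from conftest import straight_root


def capsule_system(radius=0.3, length=2.0, center=(2.0, 2.0, 1.0)):
    """One straight horizontal capsule, fully interior to a 4x4x2 cm grid."""
    c = np.asarray(center)
    nodes = [
        rv.Node(tuple(c - [length / 2, 0, 0]), diameter=2 * radius),
        rv.Node(tuple(c + [length / 2, 0, 0]), diameter=2 * radius),
    ]
    return rv.RootSystem(roots=[rv.Root(root_id="cap", nodes=nodes)])


class TestVoxelize:
    def test_empty_rsa_all_zero(self):
        vol = rv.voxelize(rv.RootSystem(), (8, 8, 8), 0.1)
        assert vol.values.shape == (8, 8, 8)
        assert np.all(vol.values == 0.0)

    def test_thick_segment_interior_voxel_is_full(self):
        rsa = capsule_system(radius=0.5, length=2.0)
        vol = rv.voxelize(rsa, (40, 40, 20), 0.1)
        # voxel at the capsule centre lies deep inside the tube
        i, j, k = 20, 20, 10
        assert vol.values[i, j, k] == pytest.approx(1.0)

    def test_mass_conservation_against_analytic_capsule(self):
        r, L = 0.3, 2.0
        rsa = capsule_system(radius=r, length=L)
        vol = rv.voxelize(rsa, (80, 80, 40), 0.05, supersampling=4)
        mass = float(vol.values.sum()) * 0.05**3
        analytic = np.pi * r**2 * L + (4.0 / 3.0) * np.pi * r**3
        assert mass == pytest.approx(analytic, rel=0.05)

    def test_refinement_consistency(self):
        r, L = 0.3, 2.0
        rsa = capsule_system(radius=r, length=L)
        coarse = rv.voxelize(rsa, (40, 40, 20), 0.1, supersampling=4)
        fine = rv.voxelize(rsa, (80, 80, 40), 0.05, supersampling=4)
        m_coarse = float(coarse.values.sum()) * 0.1**3
        m_fine = float(fine.values.sum()) * 0.05**3
        assert abs(m_fine - m_coarse) / m_coarse < 0.02

    def test_deterministic(self):
        rsa = capsule_system()
        a = rv.voxelize(rsa, (40, 40, 20), 0.1)
        b = rv.voxelize(rsa, (40, 40, 20), 0.1)
        np.testing.assert_array_equal(a.values, b.values)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            rv.voxelize(rv.RootSystem(), (8, 8, 8), -0.1)
        with pytest.raises(ValueError):
            rv.voxelize(rv.RootSystem(), (8, 8, 8), 0.1, supersampling=0)


class TestWeierstrassTransform:
    def test_sigma_zero_is_identity(self):
        vol = rv.VolumeGrid(np.random.default_rng(0).random((10, 10, 10)), 0.1)
        out = rv.weierstrass_transform(vol, 0.0)
        np.testing.assert_array_equal(out.values, vol.values)

    def test_constant_volume_unchanged_in_interior(self):
        vol = rv.VolumeGrid(np.full((30, 30, 30), 0.5, dtype=np.float32), 0.1)
        out = rv.weierstrass_transform(vol, 0.2)
        np.testing.assert_allclose(
            out.values[10:20, 10:20, 10:20], 0.5, atol=1e-6
        )

    def test_impulse_matches_sampled_gaussian_kernel(self):
        n, sigma_cm, vox = 41, 0.15, 0.05
        field = np.zeros((n, n, n), dtype=np.float64)
        field[n // 2, n // 2, n // 2] = 1.0
        out = rv.weierstrass_transform(rv.VolumeGrid(field, vox), sigma_cm)
        s = sigma_cm / vox  # kernel in voxel units
        ax = np.arange(n) - n // 2
        g1 = np.exp(-(ax**2) / (2 * s * s))
        g1 /= g1.sum()
        kernel = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
        np.testing.assert_allclose(out.values, kernel, atol=1e-6)

    def test_interior_mass_preserved(self):
        field = np.zeros((40, 40, 40), dtype=np.float64)
        field[15:25, 15:25, 15:25] = 1.0
        vol = rv.VolumeGrid(field, 0.1)
        out = rv.weierstrass_transform(vol, 0.15)
        assert float(out.values.sum()) == pytest.approx(
            float(vol.values.sum()), rel=1e-6
        )

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            rv.weierstrass_transform(rv.VolumeGrid(np.zeros((4, 4, 4)), 0.1), -1)


def small_phantom_inputs():
    """A thin vertical root in a 3x3x4 cm grid; fast to voxelize."""
    root = straight_root("tap", start=(1.5, 1.5, 0.5), n_nodes=13,
                         spacing=0.25, diameter=0.3)
    rsa = rv.RootSystem(roots=[root])
    clean = rv.voxelize(rsa, (60, 60, 80), 0.05)
    return clean


class TestWaterNoise:
    def test_same_seed_is_bit_identical(self):
        clean = small_phantom_inputs()
        conf = rv.NoiseConfig(seed=5)
        a = rv.seed_water_noise(clean, conf)
        b = rv.seed_water_noise(clean, conf)
        np.testing.assert_array_equal(a.values, b.values)

    def test_outside_cylinder_unchanged(self):
        clean = small_phantom_inputs()
        conf = rv.NoiseConfig(seed=5)
        seeded = rv.seed_water_noise(clean, conf)
        mask = rv.cylinder_mask(clean, conf)
        np.testing.assert_array_equal(
            seeded.values[~mask], clean.values[~mask]
        )

    def test_snr_round_trip(self):
        clean = small_phantom_inputs()
        snrs = []
        for s in range(5):
            conf = rv.NoiseConfig(seed=s)
            seeded = rv.seed_water_noise(clean, conf)
            noisy = rv.weierstrass_transform(seeded, conf.kernel_sigma)
            clean_s = rv.weierstrass_transform(clean, conf.kernel_sigma)
            snrs.append(rv.measure_snr(
                clean_s, noisy, rv.cylinder_mask(clean, conf),
                peak_dilation_vox=conf.peak_dilation_vox))
        assert np.mean(snrs) == pytest.approx(4.3, rel=0.10)

    def test_cylinder_outside_grid_rejected(self):
        clean = small_phantom_inputs()
        conf = rv.NoiseConfig(cylinder_center=(50.0, 50.0), seed=0)
        with pytest.raises(ValueError):
            rv.seed_water_noise(clean, conf)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            rv.NoiseConfig(snr=0)
        with pytest.raises(ValueError):
            rv.NoiseConfig(impulse_density=0)

    def test_config_from_toml(self, tmp_path):
        f = tmp_path / "noise.toml"
        f.write_text('snr = 3.0\nseed = 9\nkernel_sigma = 0.2\n')
        conf = rv.NoiseConfig.from_file(f)
        assert conf.snr == 3.0 and conf.seed == 9 and conf.kernel_sigma == 0.2


class TestMeasureSNR:
    def test_zero_noise_reports_infinity(self):
        clean = small_phantom_inputs()
        region = rv.cylinder_mask(clean, rv.NoiseConfig())
        assert rv.measure_snr(clean, clean, region) == float("inf")

    def test_known_ratio(self):
        values = np.zeros((20, 20, 20), dtype=np.float64)
        values[10, 10, 10] = 1.0
        clean = rv.VolumeGrid(values, 0.1)
        rng = np.random.default_rng(0)
        region = np.zeros((20, 20, 20), dtype=bool)
        region[5:15, 5:15, 5:15] = True
        noise = np.zeros_like(values)
        noise[region] = rng.choice([-0.25, 0.25], size=int(region.sum()))
        noisy = rv.VolumeGrid(values + noise, 0.1)
        assert rv.measure_snr(clean, noisy, region) == pytest.approx(4.0)

    def test_incongruent_grids_rejected(self):
        a = rv.VolumeGrid(np.zeros((4, 4, 4)), 0.1)
        b = rv.VolumeGrid(np.zeros((4, 4, 5)), 0.1)
        with pytest.raises(ValueError):
            rv.measure_snr(a, b, np.ones((4, 4, 4), dtype=bool))


class TestVolumeIO:
    def test_raw_round_trip_bit_exact(self, tmp_path):
        vol = rv.VolumeGrid(
            np.random.default_rng(1).random((8, 9, 10)).astype(np.float32),
            0.05, origin=(1.0, -2.0, 0.5))
        path = tmp_path / "vol.raw"
        rv.write_volume(vol, path)
        back = rv.read_volume(path)
        np.testing.assert_array_equal(back.values, vol.values)
        assert back.voxel_size == vol.voxel_size
        assert back.origin == vol.origin

    def test_nifti_round_trip(self, tmp_path):
        vol = rv.VolumeGrid(
            np.random.default_rng(2).random((6, 7, 8)).astype(np.float32),
            0.05, origin=(0.5, 0.5, 0.0))
        path = tmp_path / "vol.nii.gz"
        rv.write_volume(vol, path)
        back = rv.read_volume(path)
        np.testing.assert_allclose(back.values, vol.values, atol=1e-7)
        assert back.voxel_size == pytest.approx(vol.voxel_size, abs=1e-6)

    def test_missing_sidecar_is_format_error(self, tmp_path):
        vol = rv.VolumeGrid(np.zeros((4, 4, 4), dtype=np.float32), 0.1)
        path = tmp_path / "vol.raw"
        rv.write_volume(vol, path)
        path.with_suffix(".json").unlink()
        with pytest.raises(ValueError, match="sidecar"):
            rv.read_volume(path)

    def test_unknown_format_rejected(self, tmp_path):
        vol = rv.VolumeGrid(np.zeros((4, 4, 4), dtype=np.float32), 0.1)
        with pytest.raises(ValueError):
            rv.write_volume(vol, tmp_path / "vol.tiff")
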