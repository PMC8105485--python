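import numpy as np
import pytest
from skimage.transform import radon

from petqa.phantoms import (
    HoffmanSurrogateSpec,
    NemaIQSpec,
    add_poisson_noise,
    forward_project,
    generate_hoffman_surrogate,
    generate_nema_phantom,
)
from petqa.volumes import GeometryError, Grid, ImageVolume


class TestNemaPhantom:
    def test_hot_to_background_ratio_is_four(self):
        vol, labels = generate_nema_phantom(
            NemaIQSpec(), Grid((128, 128, 40), (3.0, 3.0, 3.0))
        )
        hot = vol.voxels[labels.mask("sphere_0")]
        bg = vol.voxels[labels.mask("background")]
        assert np.all(hot == 4.0 * 5.6)
        assert np.all(bg == 5.6)
        assert hot.mean() / bg.mean() == pytest.approx(4.0)

    def test_unit_ratio_makes_hot_spheres_invisible(self):
        vol, labels = generate_nema_phantom(
            NemaIQSpec(hot_to_background_ratio=1.0),
            Grid((128, 128, 40), (3.0, 3.0, 3.0)),
        )
        hot = vol.voxels[labels.mask("sphere_0")]
        assert np.max(np.abs(hot - 5.6)) == 0.0

    def test_sphere_voxel_count_matches_numeric_integration(self):
        # 39 mm sphere voxelized at 1 mm: compare against an independent
        # subsampled integration of the sphere indicator (and pi/6 d^3).
        vol, labels = generate_nema_phantom(
            NemaIQSpec(), Grid((320, 320, 64), (1.0, 1.0, 1.0))
        )
        count = int(labels.mask("sphere_5").sum())
        r = 39.0 / 2.0
        sub = np.linspace(-r - 1, r + 1, 161)  # 0.5 mm subsampling oracle
        X, Y, Z = np.meshgrid(sub, sub, sub, indexing="ij")
        step = sub[1] - sub[0]
        numeric = ((X**2 + Y**2 + Z**2 <= r**2).sum()) * step**3
        assert numeric == pytest.approx((np.pi / 6) * 39.0**3, rel=0.01)
        assert count == pytest.approx(31059, rel=0.05)

    def test_voxelized_volume_converges_with_resolution(self):
        truth = (np.pi / 6) * 39.0**3
        errs = []
        for dx, n in ((3.0, 128), (1.0, 320)):
            _, labels = generate_nema_phantom(
                NemaIQSpec(), Grid((n, n, int(128 * 1 // dx) if dx == 1 else 48), (dx, dx, dx))
            )
            v = labels.mask("sphere_5").sum() * dx**3
            errs.append(abs(v - truth) / truth)
        assert errs[1] < errs[0]

    def test_sphere_outside_fov_is_geometry_error(self):
        with pytest.raises(GeometryError):
            generate_nema_phantom(
                NemaIQSpec(ring_radius_mm=130.0), Grid((64, 64, 16), (4.0, 4.0, 4.0))
            )


class TestHoffmanSurrogate:
    def test_deterministic_for_fixed_seed(self):
        grid = Grid((48, 48, 16), (3.0, 3.0, 3.0))
        v1, l1 = generate_hoffman_surrogate(HoffmanSurrogateSpec(seed=1), grid)
        v2, l2 = generate_hoffman_surrogate(HoffmanSurrogateSpec(seed=1), grid)
        np.testing.assert_array_equal(v1.voxels, v2.voxels)
        np.testing.assert_array_equal(l1.labels, l2.labels)
        v3, _ = generate_hoffman_surrogate(HoffmanSurrogateSpec(seed=2), grid)
        assert not np.array_equal(v1.voxels, v3.voxels)

    def test_scaled_mode_gray_white_ratio_exact(self):
        grid = Grid((64, 64, 24), (2.5, 2.5, 2.78))
        vol, labels = generate_hoffman_surrogate(
            HoffmanSurrogateSpec(seed=3, wm_activity_mode="scaled", gm_wm_ratio=4.0),
            grid,
        )
        gray = vol.voxels[labels.mask("gray")]
        white = vol.voxels[labels.mask("white")]
        assert gray.mean() / white.mean() == pytest.approx(4.0)

    def test_putamen_volume_within_voxel_shell(self):
        grid = Grid((192, 192, 48), (1.0, 1.0, 2.78))
        _, labels = generate_hoffman_surrogate(HoffmanSurrogateSpec(seed=1), grid)
        n = labels.mask("putamen_R").sum()
        vol_mm3 = n * 1.0 * 1.0 * 2.78
        # one voxel-shell tolerance: surface area x max voxel dimension
        r_eq = (3 * 2400.0 / (4 * np.pi)) ** (1 / 3)
        shell = 4 * np.pi * r_eq**2 * 2.78
        assert abs(vol_mm3 - 2400.0) < shell

    def test_background_voi_devoid_of_activity(self, small_hoffman):
        vol, labels = small_hoffman["volume"], small_hoffman["labels"]
        assert np.all(vol.voxels[labels.mask("wm_background_voi")] == 0.0)
        # devoid mode: white matter carries no activity either
        assert np.all(vol.voxels[labels.mask("white")] == 0.0)

    def test_oversized_putamen_rejected(self):
        with pytest.raises(ValueError, match="10%"):
            generate_hoffman_surrogate(
                HoffmanSurrogateSpec(putamen_volume_mm3=5e5),
                Grid((48, 48, 16), (3.0, 3.0, 3.0)),
            )


class TestForwardProjection:
    def test_central_point_peaks_at_zero_offset_every_angle(self):
        n = 64
        img = np.zeros((n, n, 1))
        img[n // 2, n // 2, 0] = 1.0
        sino = forward_project(ImageVolume(img, (2.0, 2.0, 2.0)), 32)
        peaks = np.argmax(sino.counts[:, :, 0], axis=1)
        assert np.all(peaks == n // 2)

    def test_uniform_disk_profile_matches_chord_length(self):
        # fine 0.5 mm grid so disk-boundary voxelization error sits inside
        # the 2% closed-form chord tolerance
        n = 256
        x = (np.arange(n) - n // 2) * 0.5
        X, Y = np.meshgrid(x, x, indexing="ij")
        r = 55.0
        disk = ((X**2 + Y**2) <= r**2).astype(float) * 3.0
        sino = forward_project(ImageVolume(disk[:, :, None], (0.5, 0.5, 0.5)), 32)
        s = (np.arange(n) - n // 2) * 0.5
        # chord length in pixel-length units (0.5 mm bins)
        chord = 2 * np.sqrt(np.maximum(r**2 - s**2, 0)) * 3.0 / 0.5
        inner = np.abs(s) <= 0.8 * r
        for a in (0, 10, 25):
            prof = sino.counts[a, :, 0]
            np.testing.assert_allclose(prof[inner], chord[inner], rtol=0.02)

    def test_sum_preservation_per_slice(self, disk_volume):
        sino = forward_project(disk_volume["volume"], 48)
        slice_sum = disk_volume["volume"].voxels[:, :, 0].sum()
        assert sino.counts[:, :, 0].sum() == pytest.approx(48 * slice_sum, rel=0.01)

    def test_zero_volume_projects_to_zero_and_linearity(self, disk_volume):
        vol = disk_volume["volume"]
        zero = vol.copy_with(np.zeros_like(vol.voxels))
        assert np.all(forward_project(zero, 32).counts == 0)
        rng = np.random.default_rng(0)
        other = vol.copy_with(rng.random(vol.voxels.shape))
        lhs = forward_project(vol.copy_with(2.0 * vol.voxels + 3.0 * other.voxels), 32)
        rhs = 2.0 * forward_project(vol, 32).counts + 3.0 * forward_project(other, 32).counts
        np.testing.assert_allclose(lhs.counts, rhs, rtol=1e-12, atol=1e-9)

    def test_matches_skimage_radon_oracle(self, disk_volume):
        """Dual-route check: the sparse pixel-driven projector against the
        rotation-based radon transform on a smooth slice."""
        vol = disk_volume["volume"]
        from scipy.ndimage import gaussian_filter

        smooth = gaussian_filter(vol.voxels[:, :, 0], 2.0)
        # 30 angles avoids exact 45-degree views, where the pixel-driven
        # interpolation shows a known zigzag that rotation-based radon lacks
        sino = forward_project(
            ImageVolume(smooth[:, :, None], vol.voxel_size), 30
        ).counts[:, :, 0]
        theta = np.rad2deg(np.arange(30) * np.pi / 30)
        oracle = radon(smooth, theta=theta, circle=True).T
        scale = np.abs(oracle).max()
        assert np.max(np.abs(sino - oracle)) / scale < 0.02

    def test_geometry_preconditions(self, disk_volume):
        vol = disk_volume["volume"]
        with pytest.raises(ValueError):
            forward_project(vol, 8)  # too few angles
        aniso = ImageVolume(vol.voxels, (2.0, 3.0, 2.0))
        with pytest.raises(GeometryError, match="anisotropic"):
            forward_project(aniso, 32)


class TestPoissonNoise:
    def test_expectation_preserved_over_seeds(self, disk_volume):
        sino = forward_project(disk_volume["volume"], 32)
        totals = [
            add_poisson_noise(sino, 1e6, seed).counts.sum() for seed in range(50)
        ]
        assert np.mean(totals) == pytest.approx(1e6, rel=0.005)

    def test_integer_counts_zero_input_and_determinism(self, disk_volume):
        sino = forward_project(disk_volume["volume"], 32)
        noisy = add_poisson_noise(sino, 1e5, seed=7)
        assert np.all(noisy.counts == np.round(noisy.counts))
        np.testing.assert_array_equal(
            noisy.counts, add_poisson_noise(sino, 1e5, seed=7).counts
        )
        zero = add_poisson_noise(
            forward_project(
                disk_volume["volume"].copy_with(
                    np.zeros_like(disk_volume["volume"].voxels)
                ),
                32,
            ),
            1e6,
            seed=1,
        )
        assert np.all(zero.counts == 0)
        with pytest.raises(ValueError):
            add_poisson_noise(sino, -1.0, seed=0)
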