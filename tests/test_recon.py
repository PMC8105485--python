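import numpy as np
import pytest
from scipy.optimize import curve_fit

from petqa.phantoms import add_poisson_noise, forward_project
from petqa.projector import system_matrix
from petqa.recon import (
    ConfigError,
    ReconConfig,
    bsrem_reconstruct,
    fbp_reconstruct,
    gaussian_postfilter,
    osem_reconstruct,
    rdp_gradient,
    rdp_gradient_reference,
    rdp_value,
)
from petqa.volumes import Grid, ImageVolume


def interior_mean(rec, disk):
    return rec.voxels[:, :, 0][disk["interior_2d"]].mean()


class TestFBP:
    def test_recovers_uniform_disk_activity(self, disk_volume):
        sino = forward_project(disk_volume["volume"], 360)
        rec = fbp_reconstruct(sino, ReconConfig("FBP"), disk_volume["grid"])
        assert interior_mean(rec, disk_volume) == pytest.approx(3.0, rel=0.03)

    def test_zero_sinogram_gives_zero_image(self, disk_volume):
        sino = forward_project(disk_volume["volume"], 64)
        zero = sino.__class__(np.zeros_like(sino.counts), sino.angles, sino.radial_spacing_mm)
        rec = fbp_reconstruct(zero, ReconConfig("FBP"), disk_volume["grid"])
        assert np.all(rec.voxels == 0)

    def test_wider_postfilter_blurs_more(self, small_hoffman):
        from petqa.hoffman import estimate_fwhm

        sino = forward_project(small_hoffman["volume"], 180)
        grid = small_hoffman["grid"]
        f5 = fbp_reconstruct(sino, ReconConfig("FBP", post_filter_fwhm_mm=5.0), grid)
        f15 = fbp_reconstruct(sino, ReconConfig("FBP", post_filter_fwhm_mm=15.0), grid)
        e5 = estimate_fwhm(f5, small_hoffman["volume"], (3.0, 18.0, 0.5))
        e15 = estimate_fwhm(f15, small_hoffman["volume"], (3.0, 18.0, 0.5))
        assert e15.fwhm_xy_mm > e5.fwhm_xy_mm

    def test_invalid_config_rejected(self, disk_volume):
        with pytest.raises(ConfigError):
            ReconConfig("FBP", post_filter_fwhm_mm=-1.0)
        sino = forward_project(disk_volume["volume"], 64)
        with pytest.raises(ConfigError):
            fbp_reconstruct(sino, ReconConfig("OSEM"), disk_volume["grid"])


class TestOSEM:
    def test_recovers_uniform_disk_activity(self, disk_volume):
        sino = forward_project(disk_volume["volume"], 160)
        rec = osem_reconstruct(
            sino, ReconConfig("OSEM", iterations=4, subsets=8), disk_volume["grid"]
        )
        assert interior_mean(rec, disk_volume) == pytest.approx(3.0, rel=0.03)
        assert np.all(rec.voxels >= 0)

    def test_zero_initialization_is_a_fixed_point(self, disk_volume):
        """The multiplicative EM update cannot leave zero, which is why the
        implementation starts from ones (asserted via a nonzero output)."""
        sino = forward_project(disk_volume["volume"], 32)
        A = system_matrix(96, 32)
        g = sino.counts.reshape(32 * 96, 4)
        f = np.zeros((96 * 96, 4))
        sens = np.asarray(A.sum(axis=0)).ravel()
        for _ in range(3):
            ratio = g / np.maximum(A @ f, 1e-12)
            f *= (A.T @ ratio) / np.maximum(sens, 1e-12)[:, None]
        assert np.all(f == 0)
        rec = osem_reconstruct(
            sino, ReconConfig("OSEM", iterations=1, subsets=8), disk_volume["grid"]
        )
        assert rec.voxels.max() > 0

    def test_single_subset_equals_independent_mlem(self, disk_volume):
        sino = forward_project(disk_volume["volume"], 32)
        noisy = add_poisson_noise(sino, 2e5, seed=3)
        rec = osem_reconstruct(
            noisy, ReconConfig("OSEM", iterations=5, subsets=1), disk_volume["grid"]
        )
        # independent MLEM oracle written directly from the EM update rule
        A = system_matrix(96, 32)
        g = noisy.counts.reshape(32 * 96, 4)
        sens = np.asarray(A.sum(axis=0)).ravel()
        f = np.ones((96 * 96, 4))
        f[sens <= 0] = 0.0
        for _ in range(5):
            ratio = g / np.maximum(A @ f, 1e-12)
            f *= (A.T @ ratio) / np.maximum(sens, 1e-12)[:, None]
        np.testing.assert_allclose(rec.voxels, f.reshape(96, 96, 4), rtol=1e-10, atol=1e-12)

    def test_subsets_must_divide_angles(self, disk_volume):
        sino = forward_project(disk_volume["volume"], 180)
        with pytest.raises(ConfigError, match="divide"):
            osem_reconstruct(
                sino, ReconConfig("OSEM", iterations=1, subsets=8), disk_volume["grid"]
            )


class TestBSREM:
    def test_zero_beta_equals_osem(self, disk_volume):
        sino = add_poisson_noise(forward_project(disk_volume["volume"], 96), 5e5, seed=1)
        cfg_o = ReconConfig("OSEM", iterations=4, subsets=8)
        cfg_b = ReconConfig("BSREM", iterations=4, subsets=8, beta=0.0)
        a = osem_reconstruct(sino, cfg_o, disk_volume["grid"]).voxels
        b = bsrem_reconstruct(sino, cfg_b, disk_volume["grid"]).voxels
        np.testing.assert_allclose(b, a, rtol=1e-9, atol=1e-12)

    def test_nonnegative_and_recovers_disk(self, disk_volume):
        sino = forward_project(disk_volume["volume"], 96)
        rec = bsrem_reconstruct(
            sino, ReconConfig("BSREM", iterations=10, subsets=8, beta=100.0),
            disk_volume["grid"],
        )
        assert np.all(rec.voxels >= 0)
        assert interior_mean(rec, disk_volume) == pytest.approx(3.0, rel=0.03)

    def test_penalized_objective_ascends(self, disk_volume):
        sino = add_poisson_noise(forward_project(disk_volume["volume"], 96), 5e5, seed=2)
        _, info = bsrem_reconstruct(
            sino,
            ReconConfig("BSREM", iterations=10, subsets=8, beta=300.0),
            disk_volume["grid"],
            return_info=True,
        )
        obj = info["objective"]
        span = obj[-1] - obj[0]
        assert span > 0
        # non-decreasing within a small relaxation tolerance
        assert np.all(np.diff(obj) > -1e-4 * abs(span))

    def test_gamma_must_be_nonnegative(self):
        with pytest.raises(ConfigError):
            ReconConfig("BSREM", beta=100.0, rdp_gamma=-1.0)


class TestRelativeDifferencePrior:
    def test_kernel_matches_reference(self):
        rng = np.random.default_rng(0)
        f = rng.gamma(2.0, 1.0, (14, 12, 7))
        g1 = rdp_gradient(f, (2.0, 2.0, 2.78))
        g2 = rdp_gradient_reference(f, (2.0, 2.0, 2.78))
        np.testing.assert_allclose(g1, g2, rtol=1e-12, atol=1e-12)

    def test_constant_image_has_zero_penalty_and_gradient(self):
        f = np.full((10, 10, 5), 3.7)
        assert rdp_value(f, (2.0, 2.0, 2.0)) == 0.0
        assert np.all(rdp_gradient(f, (2.0, 2.0, 2.0)) == 0.0)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        f = rng.gamma(2.0, 1.0, (6, 5, 4))
        grad = rdp_gradient(f, (2.0, 2.0, 2.78))
        eps = 1e-6
        for idx in [(2, 2, 1), (0, 0, 0), (5, 4, 3), (3, 1, 2)]:
            fp, fm = f.copy(), f.copy()
            fp[idx] += eps
            fm[idx] -= eps
            num = (
                rdp_value(fp, (2.0, 2.0, 2.78)) - rdp_value(fm, (2.0, 2.0, 2.78))
            ) / (2 * eps)
            assert grad[idx] == pytest.approx(num, rel=1e-5, abs=1e-8)


class TestGaussianPostfilter:
    def test_zero_fwhm_is_identity(self, disk_volume):
        out = gaussian_postfilter(disk_volume["volume"], 0.0, 0.0)
        np.testing.assert_array_equal(out.voxels, disk_volume["volume"].voxels)

    def test_delta_yields_fitted_fwhm(self):
        n = 64
        img = np.zeros((n, n, n))
        img[n // 2, n // 2, n // 2] = 1.0
        vol = ImageVolume(img, (1.0, 1.0, 1.0))
        out = gaussian_postfilter(vol, 8.0, 8.0)
        profile = out.voxels[:, n // 2, n // 2]
        x = np.arange(n, dtype=float)

        def gauss(x, a, mu, sigma):
            return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

        popt, _ = curve_fit(gauss, x, profile, p0=(profile.max(), n // 2, 3.0))
        fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * abs(popt[2])
        assert fwhm == pytest.approx(8.0, abs=0.1)

    def test_cascade_identity(self):
        # compact random blob away from the volume boundary (the identity is
        # a statement about the interior; border truncation differs)
        rng = np.random.default_rng(2)
        from scipy.ndimage import gaussian_filter

        img = np.zeros((64, 64, 64))
        img[24:40, 24:40, 24:40] = rng.random((16, 16, 16))
        vol = ImageVolume(gaussian_filter(img, 1.5), (1.0, 1.0, 1.0))
        twice = gaussian_postfilter(gaussian_postfilter(vol, 6.0, 6.0), 6.0, 6.0)
        once = gaussian_postfilter(vol, np.sqrt(72.0), np.sqrt(72.0))
        scale = once.voxels.max()
        assert np.max(np.abs(twice.voxels - once.voxels)) / scale < 0.005

    def test_total_activity_conserved_away_from_boundaries(self):
        img = np.zeros((48, 48, 48))
        img[16:32, 16:32, 16:32] = 1.0
        vol = ImageVolume(img, (2.0, 2.0, 2.0))
        out = gaussian_postfilter(vol, 8.0, 8.0)
        assert out.voxels.sum() == pytest.approx(img.sum(), rel=1e-3)
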