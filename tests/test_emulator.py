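"""Point-spread, projection, attenuation and noise contracts of the emulator."""

import numpy as np
import pytest

from volumetrix import (AcquisitionConfig, EmptyRoiError, InvalidParameterError,
                        TomoImage, emulate_planar, emulate_tomo, max_uptake,
                        poissonize_tomo)
from volumetrix.phantom import ActivityMap


def _activity(grid, voxel=1.0, target=1.0, tb=1e6):
    grid = np.asarray(grid, dtype=float)
    return ActivityMap(concentration_grid=grid, voxel_size=voxel,
                       target_concentration=target, background_concentration=target / tb,
                       tb_ratio=tb)


class TestTomoEmulation:
    def test_constant_field_is_convolution_fixed_point(self):
        """Blurring a uniform medium leaves it unchanged away from the edges."""
        act = _activity(np.full((60, 60, 60), 7.0))
        out = emulate_tomo(act, AcquisitionConfig(), noisy=False)
        core = out.counts_grid[25:35, 25:35, 25:35]
        assert np.allclose(core, 7.0, rtol=1e-6)

    def test_blur_preserves_mass(self):
        rng = np.random.default_rng(0)
        grid = np.zeros((64, 64, 64))
        grid[24:40, 24:40, 24:40] = rng.uniform(0.5, 2.0, (16, 16, 16))
        out = emulate_tomo(_activity(grid), AcquisitionConfig(), noisy=False)
        assert out.counts_grid.sum() == pytest.approx(grid.sum(), rel=1e-6)

    def test_blurred_sphere_matches_fft_oracle(self, blurred_sphere):
        """Separable-filter output equals direct FFT convolution of the sphere."""
        act = _activity(blurred_sphere["sphere"], voxel=blurred_sphere["voxel"])
        out = emulate_tomo(act, AcquisitionConfig(tomo_fwhm=10.59), noisy=False)
        assert np.allclose(out.counts_grid, blurred_sphere["image"], atol=2e-4)

    def test_sphere_center_and_edge_profile(self, blurred_sphere):
        """d = 40 mm sphere: near-full recovery at the center; the boundary value
        sits below half the plateau by the 3D curvature term (oracle-pinned)."""
        img = blurred_sphere["image"]
        c = blurred_sphere["n"] // 2
        assert img[c, c, c] >= 0.99
        boundary = img[c + int(blurred_sphere["radius"]), c, c]
        assert boundary == pytest.approx(0.4035, abs=0.005)

    def test_flat_interface_edge_is_half_plateau(self):
        """Gaussian-blurred half-space: the erf profile crosses 0.5 at the interface."""
        grid = np.zeros((80, 40, 40))
        grid[:40] = 1.0
        out = emulate_tomo(_activity(grid), AcquisitionConfig(), noisy=False)
        edge = out.counts_grid[39:41, 20, 20].mean()  # interface lies between voxels
        assert edge == pytest.approx(0.5, abs=0.01)

    def test_psf_fwhm_contract(self):
        """FWHM measured from an emulated point source equals the configured value."""
        fwhm = 10.59
        grid = np.zeros((61, 61, 61))
        grid[30, 30, 30] = 1.0
        out = emulate_tomo(_activity(grid), AcquisitionConfig(tomo_fwhm=fwhm), noisy=False)
        profile = out.counts_grid[:, 30, 30]
        half = profile.max() / 2.0
        above = np.nonzero(profile >= half)[0]
        measured = above.max() - above.min() + 1  # voxels
        assert abs(measured - fwhm) <= 1.0  # within one voxel of 10.59 mm

    def test_poisson_noise_is_unbiased_and_calibrated(self):
        """Replicate mean tracks the noiseless expectation; variance ~ mean."""
        cfg = AcquisitionConfig()
        act = _activity(np.full((40, 40, 40), 500.0), voxel=2.0)
        noiseless = emulate_tomo(act, cfg, noisy=False)
        cps = cfg.sensitivity * 1e-6
        expected = 500.0 * act.voxel_volume_ml * cps * cfg.tomo_total_seconds
        reps = []
        for seed in range(50):
            img = poissonize_tomo(noiseless, cfg, rng=np.random.default_rng(seed))
            reps.append(img.counts_grid[20, 20, 20])
        se = np.sqrt(expected / 50)
        assert abs(np.mean(reps) - expected) < 3 * se
        core = poissonize_tomo(noiseless, cfg,
                               rng=np.random.default_rng(99)).counts_grid[5:-5, 5:-5, 5:-5]
        assert core.var() == pytest.approx(core.mean(), rel=0.10)  # >= 1e4 voxels

    def test_negative_activity_rejected(self):
        act = _activity(np.zeros((8, 8, 8)))
        act.concentration_grid[0, 0, 0] = -1.0
        with pytest.raises(InvalidParameterError):
            emulate_tomo(act, AcquisitionConfig(), noisy=False)


class TestPlanarEmulation:
    def test_point_source_projects_to_gaussian_blob(self):
        grid = np.zeros((41, 41, 41))
        grid[20, 20, 20] = 3.0
        cfg = AcquisitionConfig(attenuation_mu=0.0)
        out = emulate_planar(_activity(grid), cfg, noisy=False)
        assert out.counts_grid.sum() == pytest.approx(3.0 * 1.0 / 1000.0, rel=1e-6)
        assert np.unravel_index(out.counts_grid.argmax(), out.counts_grid.shape) == (20, 20)

    def test_projection_conserves_total_signal(self):
        rng = np.random.default_rng(1)
        grid = np.zeros((48, 24, 48))
        grid[14:34, :, 14:34] = rng.uniform(0, 2, (20, 24, 20))  # >3 sigma of padding
        out = emulate_planar(_activity(grid), AcquisitionConfig(attenuation_mu=0.0), noisy=False)
        assert out.counts_grid.sum() == pytest.approx(grid.sum() / 1000.0, rel=1e-6)

    def test_beer_lambert_depth_ratio(self):
        """Source 5 cm deeper is attenuated by exp(-0.15 * 5) ~ 0.472."""
        cfg = AcquisitionConfig(attenuation_mu=0.15, planar_fwhm=4.0)
        ratios = []
        grid_a = np.zeros((41, 81, 41))
        grid_a[20, 80, 20] = 1.0  # at the anterior face
        grid_b = np.zeros((41, 81, 41))
        grid_b[20, 30, 20] = 1.0  # 50 mm deeper
        for g in (grid_a, grid_b):
            ratios.append(emulate_planar(_activity(g), cfg, noisy=False).counts_grid.sum())
        assert ratios[1] / ratios[0] == pytest.approx(np.exp(-0.75), rel=0.01)

    def test_noisy_total_counts_hit_target(self):
        grid = np.zeros((40, 40, 40))
        grid[15:25, 15:25, 15:25] = 1.0
        cfg = AcquisitionConfig(planar_target_counts=300.0, rng_seed=7)
        out = emulate_planar(_activity(grid), cfg, noisy=True)
        assert out.counts_grid.sum() == pytest.approx(300_000.0, rel=0.05)
        assert np.all(out.counts_grid >= 0)


class TestMaxUptake:
    def test_constant_and_spike(self):
        img = TomoImage(np.full((5, 5, 5), 2.5), 1.0)
        region = np.ones((5, 5, 5), bool)
        assert max_uptake(img, region) == 2.5
        img.counts_grid[2, 2, 2] = 40.0
        assert max_uptake(img, region) == 40.0

    def test_blur_moves_max_off_boundary(self, blurred_sphere):
        img = TomoImage(blurred_sphere["image"], blurred_sphere["voxel"])
        idx = np.unravel_index(img.counts_grid.argmax(), img.counts_grid.shape)
        c = blurred_sphere["n"] // 2
        r = np.linalg.norm(np.array(idx) - c) * blurred_sphere["voxel"]
        assert r < blurred_sphere["radius"] * 0.5  # interior, nowhere near the edge

    def test_hottest_n_mean_leq_raw_max(self):
        rng = np.random.default_rng(3)
        img = TomoImage(rng.poisson(10.0, (12, 12, 12)).astype(float), 1.0)
        region = np.ones(img.counts_grid.shape, bool)
        raw = max_uptake(img, region, model="raw")
        robust = max_uptake(img, region, model="hottest-n", hottest_n=8)
        assert robust <= raw

    def test_empty_region_rejected(self):
        img = TomoImage(np.ones((4, 4, 4)), 1.0)
        with pytest.raises(EmptyRoiError):
            max_uptake(img, np.zeros((4, 4, 4), bool))
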