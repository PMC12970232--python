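import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.special import j1

from mmfscope import scanner as sc
from mmfscope.fiber_optics import OpticalConfig, generate_tm
from mmfscope.phantoms import Phantom, alveolar_phantom, two_point_target
from mmfscope.texture_features import glcm_features


@pytest.fixture(scope="module")
def scan_config():
    return OpticalConfig(
        wavelength=0.785, na=0.37, core_diameter=24.0,
        pixel_size=0.4, grid_shape=(64, 64),
    )


def _uniform_phantom(scan_config, value=1.0):
    return Phantom(
        np.full(scan_config.grid_shape, value), scan_config.pixel_size, "target"
    )


class TestPsf:
    def test_first_zero_matches_rayleigh(self, scan_config):
        r0 = sc.psf_first_zero_radius(scan_config)
        rayleigh = 0.61 * scan_config.wavelength / scan_config.na
        assert r0 == pytest.approx(rayleigh, rel=0.02)

    def test_psf_normalized(self, scan_config):
        assert sc.airy_psf(scan_config).sum() == pytest.approx(1.0)


class TestAcquireScan:
    def test_uniform_phantom_flat_inside_mask(self, scan_config):
        img = sc.acquire_scan(None, _uniform_phantom(scan_config),
                              config=scan_config)
        # away from the frame boundary (one PSF support) the result is flat
        psf_extent_um = sc.airy_psf(scan_config).shape[0] // 2 * 0.4
        interior = img.fov_mask.copy()
        yy, xx = np.mgrid[:64, :64]
        r = np.hypot(yy - 31.5, xx - 31.5) * 0.4
        interior &= r <= 12.0 - psf_extent_um
        vals = img.pixels[interior]
        assert np.allclose(vals, vals[0], rtol=1e-5)

    def test_linearity_in_phantom(self, scan_config):
        p1 = alveolar_phantom(shape=(64, 64), seed=0, mean_radius_um=4.0)
        p2 = Phantom(2 * p1.density, p1.pixel_size, "normal")
        i1 = sc.acquire_scan(None, p1, config=scan_config)
        i2 = sc.acquire_scan(None, p2, config=scan_config)
        assert np.allclose(i2.pixels, 2 * i1.pixels)

    def test_rayleigh_separation_shows_dip(self):
        cfg = OpticalConfig(0.785, 0.37, 12.0, 0.1, (128, 128))
        sep = 0.61 * 0.785 / 0.37  # Rayleigh distance, ~1.29 um
        target = two_point_target(sep, 0.1, shape=(128, 128))
        img = sc.acquire_scan(None, target, config=cfg)
        row = img.pixels[64]
        mid = row[63] if row[63] < row[64] else row[64]
        # oracle: numeric superposition of two 1-D Airy intensity profiles
        x = (np.arange(128) - 63.5) * 0.1
        airy = lambda r: np.where(  # noqa: E731
            np.abs(r) < 1e-9, 1.0,
            (2 * j1(2 * np.pi * 0.37 * np.abs(r) / 0.785)
             / (2 * np.pi * 0.37 * np.abs(r) / 0.785)) ** 2,
        )
        oracle = airy(x - sep / 2) + airy(x + sep / 2)
        assert oracle[63:65].min() < oracle.max() * 0.95  # dip exists in oracle
        peak = row.max()
        assert mid < 0.95 * peak

    def test_poisson_noise_seeded(self, scan_config):
        p = alveolar_phantom(shape=(64, 64), seed=1, mean_radius_um=4.0)
        a = sc.acquire_scan(None, p, config=scan_config, noise_peak=200, seed=3)
        b = sc.acquire_scan(None, p, config=scan_config, noise_peak=200, seed=3)
        c = sc.acquire_scan(None, p, config=scan_config, noise_peak=200, seed=4)
        assert np.array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_grid_outside_aperture_rejected(self, scan_config):
        p = _uniform_phantom(scan_config)
        with pytest.raises(ValueError, match="aperture"):
            sc.acquire_scan(None, p, grid=np.array([[0, 0]]), config=scan_config)

    def test_speckle_mode_images_structure(self):
        cfg = OpticalConfig(0.785, 0.37, 11.0, 0.4, (28, 28))
        tm = generate_tm(cfg, 512, seed=2)
        density = np.zeros((28, 28))
        density[10:18, 10:18] = 1.0
        p = Phantom(density, 0.4, "target")
        img = sc.acquire_scan(tm, p, mode="speckle")
        m = img.fov_mask
        corr = np.corrcoef(img.pixels[m], density[m])[0, 1]
        assert corr > 0.5

    def test_speckle_mode_linear(self):
        cfg = OpticalConfig(0.785, 0.37, 8.0, 0.4, (20, 20))
        tm = generate_tm(cfg, 128, seed=5)
        rng = np.random.default_rng(0)
        d = rng.uniform(size=(20, 20))
        i1 = sc.acquire_scan(tm, Phantom(d, 0.4, "target"), mode="speckle")
        i2 = sc.acquire_scan(tm, Phantom(3 * d, 0.4, "target"), mode="speckle")
        assert np.allclose(i2.pixels, 3 * i1.pixels)


class TestReconstruct:
    def test_identity_no_denoise(self, rng):
        vals = rng.uniform(size=(16, 16))
        img = sc.reconstruct(vals.ravel(), (16, 16), 0.4, denoise=None)
        assert np.allclose(img.pixels[img.fov_mask], vals[img.fov_mask])

    def test_median_removes_impulse(self):
        flat = np.full((17, 17), 5.0)
        flat[8, 8] = 500.0
        img = sc.reconstruct(flat.ravel(), (17, 17), 0.4, denoise="median")
        assert np.allclose(img.pixels[img.fov_mask], 5.0)

    def test_outside_mask_zero(self, rng):
        vals = rng.uniform(1, 2, size=(16, 16))
        img = sc.reconstruct(vals.ravel(), (16, 16), 0.4, denoise=None)
        assert np.all(img.pixels[~img.fov_mask] == 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="layout"):
            sc.reconstruct(np.zeros(10), (4, 4), 0.4)


class TestBrenner:
    def test_constant_zero(self):
        assert sc.brenner_score(np.full((8, 8), 3.0)) == 0.0

    def test_hand_summation_single_row(self):
        row = np.array([[0.0, 1.0, 2.0, 3.0]])
        # horizontal pairs: (2-0)^2 + (3-1)^2 = 8
        assert sc.brenner_score(row, normalize=False) == 8.0

    def test_blur_monotonically_reduces_score(self, rng):
        base = rng.uniform(size=(64, 64))
        scores = [
            sc.brenner_score(gaussian_filter(base, s) if s else base)
            for s in (0, 1, 2, 4)
        ]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_offset_invariance(self, rng):
        img = rng.uniform(size=(32, 32))
        assert sc.brenner_score(img) == pytest.approx(
            sc.brenner_score(img + 100.0)
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            sc.brenner_score(np.ones((8, 8)), mask=np.zeros((8, 8), dtype=bool))


def _layered_volume(scan_config, textured_z, zs, seed=0):
    """Volume with strong texture only at one plane."""
    rng = np.random.default_rng(seed)
    slices = []
    for z in zs:
        if z == textured_z:
            slices.append(rng.uniform(0, 1, scan_config.grid_shape))
        else:
            slices.append(np.full(scan_config.grid_shape, 0.5))
    return Phantom(
        np.stack(slices), scan_config.pixel_size, "target",
        z_positions=np.asarray(zs, dtype=float),
    )


class TestAutofocus:
    def test_recovers_textured_plane(self, scan_config):
        zs = [0.0, 20.0, 40.0, 60.0]
        vol = _layered_volume(scan_config, 40.0, zs)
        z_best, img = sc.autofocus(None, vol, zs, config=scan_config)
        assert z_best == 40.0
        assert img.z == 40.0

    def test_tie_breaks_to_smallest_abs_z(self, scan_config):
        zs = [-20.0, 0.0, 20.0]
        vol = Phantom(
            np.stack([np.full(scan_config.grid_shape, 1.0)] * 3),
            scan_config.pixel_size, "target", z_positions=zs,
        )
        z_best, _ = sc.autofocus(None, vol, zs, config=scan_config)
        assert z_best == 0.0

    def test_single_candidate(self, scan_config):
        vol = _layered_volume(scan_config, 10.0, [0.0, 10.0])
        z_best, _ = sc.autofocus(None, vol, [10.0], config=scan_config)
        assert z_best == 10.0

    def test_empty_candidates_rejected(self, scan_config):
        vol = _layered_volume(scan_config, 0.0, [0.0, 10.0])
        with pytest.raises(ValueError):
            sc.autofocus(None, vol, [], config=scan_config)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovery_across_seeds(self, scan_config, seed):
        zs = [0.0, 15.0, 30.0, 45.0]
        rng = np.random.default_rng(seed)
        true_z = float(rng.choice(zs))
        vol = _layered_volume(scan_config, true_z, zs, seed=seed)
        z_best, _ = sc.autofocus(None, vol, zs, config=scan_config)
        assert abs(z_best - true_z) <= 15.0


class TestPunctureSeries:
    def _coarsening_volume(self, scan_config, seed=0):
        # texture fineness decreases with depth by construction
        rng = np.random.default_rng(seed)
        base = rng.uniform(size=scan_config.grid_shape)
        slices = [gaussian_filter(base, s) for s in (0.0, 1.5, 4.0)]
        return Phantom(
            np.stack(slices), scan_config.pixel_size, "target",
            z_positions=[0.0, 20.0, 40.0],
        )

    def test_contrast_monotone_with_coarsening(self, scan_config):
        vol = self._coarsening_volume(scan_config)
        series = sc.puncture_series(None, vol, [0.0, 20.0, 40.0],
                                    config=scan_config)
        contrasts = [
            glcm_features(img.pixels, mask=img.fov_mask)[0]
            for _, img in series
        ]
        assert contrasts[0] > contrasts[1] > contrasts[2]

    def test_single_depth(self, scan_config):
        vol = self._coarsening_volume(scan_config)
        series = sc.puncture_series(None, vol, [20.0], config=scan_config)
        assert len(series) == 1

    def test_deterministic(self, scan_config):
        vol = self._coarsening_volume(scan_config)
        s1 = sc.puncture_series(None, vol, [0.0, 20.0], config=scan_config,
                                noise_peak=300, seed=1)
        s2 = sc.puncture_series(None, vol, [0.0, 20.0], config=scan_config,
                                noise_peak=300, seed=1)
        for (_, a), (_, b) in zip(s1, s2):
            assert np.array_equal(a.pixels, b.pixels)

    def test_depth_outside_volume_rejected(self, scan_config):
        vol = self._coarsening_volume(scan_config)
        with pytest.raises(ValueError, match="range"):
            sc.puncture_series(None, vol, [0.0, 99.0], config=scan_config)

    def test_depths_must_increase(self, scan_config):
        vol = self._coarsening_volume(scan_config)
        with pytest.raises(ValueError):
            sc.puncture_series(None, vol, [20.0, 0.0], config=scan_config)


class TestPersistence:
    def test_scan_tiff_roundtrip(self, tmp_path, scan_config):
        p = alveolar_phantom(shape=(64, 64), seed=2, mean_radius_um=4.0)
        img = sc.acquire_scan(None, p, config=scan_config, z=12.5)
        path = tmp_path / "scan.tiff"
        sc.save_scan(img, path)
        back = sc.load_scan(path)
        assert back.pixel_size == img.pixel_size
        assert back.z == 12.5
        assert np.allclose(back.pixels, img.pixels, atol=img.pixels.max() / 1e4)

    def test_depth_series_index(self, tmp_path, scan_config):
        vol = Phantom(
            np.stack([np.full(scan_config.grid_shape, 0.5)] * 2),
            scan_config.pixel_size, "target", z_positions=[0.0, 10.0],
        )
        series = sc.puncture_series(None, vol, [0.0, 10.0], config=scan_config)
        sc.save_depth_series(series, tmp_path / "series")
        index = (tmp_path / "series" / "index.csv").read_text().splitlines()
        assert index[0] == "z_um,filename"
        assert len(index) == 3
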