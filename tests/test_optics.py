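"""Simulator: phantoms, propagation, imaging, tiling, dataset assembly."""

import dataclasses

import numpy as np
import pytest
from scipy.ndimage import label

from qpigan.optics import (
    DefocusStack,
    IntensityImage,
    OpticalConfig,
    Sphere,
    SpherePhantomSpec,
    acquire_defocus_stack,
    build_unpaired_dataset,
    image_through_system,
    make_blob_phantom,
    make_sphere_phantom,
    propagate_angular_spectrum,
    random_sphere_spec,
    tile_to_fov,
)


# -- phantoms ---------------------------------------------------------------

class TestSpherePhantom:
    def test_peak_phase_matches_chord_thickness(self):
        # sphere of diameter D has max projected thickness D at its centre,
        # hence peak phase (2pi/lambda)*dn*D
        spec = SpherePhantomSpec(
            spheres=[Sphere(5.0, 5.0, 3.0, 0.1)], grid_size=128, pitch=0.08)
        pm = make_sphere_phantom(spec, wavelength=0.55)
        expected_peak = 2 * np.pi * 0.1 * 3.0 / 0.55  # ~3.427 rad
        assert pm.values.max() == pytest.approx(expected_peak, rel=1e-3)
        # thickness itself: phase / (2pi dn / lambda) = 3 um at centre
        thickness = pm.values.max() * 0.55 / (2 * np.pi * 0.1)
        assert thickness == pytest.approx(3.0, rel=1e-3)

    def test_overlapping_spheres_add_thickness(self):
        spec = SpherePhantomSpec(
            spheres=[Sphere(5.0, 5.0, 3.0, 0.1), Sphere(5.0, 5.0, 3.0, 0.1)],
            grid_size=64, pitch=0.16)
        pm = make_sphere_phantom(spec, wavelength=0.55)
        single = make_sphere_phantom(
            SpherePhantomSpec(spheres=[Sphere(5.0, 5.0, 3.0, 0.1)],
                              grid_size=64, pitch=0.16), wavelength=0.55)
        np.testing.assert_allclose(pm.values, 2 * single.values, rtol=1e-12)

    def test_out_of_grid_sphere_names_index(self):
        spec = SpherePhantomSpec(
            spheres=[Sphere(5.0, 5.0, 2.0, 0.1), Sphere(0.3, 5.0, 3.0, 0.1)],
            grid_size=64, pitch=0.16)
        with pytest.raises(ValueError, match="sphere 1"):
            make_sphere_phantom(spec, wavelength=0.55)

    def test_fifty_random_spheres_give_fifty_components(self):
        # flood-fill count above half-max equals the number of spheres
        spec = random_sphere_spec(50, 512, 0.2, seed=7, diameter=3.0, margin=0.5)
        pm = make_sphere_phantom(spec, wavelength=0.55)
        mask = pm.values > 0.5 * pm.values.max()
        _, n = label(mask)
        assert n == 50

    def test_blob_phantom_nonnegative_and_seeded(self):
        a = make_blob_phantom(64, 0.3, seed=3)
        b = make_blob_phantom(64, 0.3, seed=3)
        c = make_blob_phantom(64, 0.3, seed=4)
        assert a.values.min() >= 0
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)


# -- propagation ------------------------------------------------------------

class TestAngularSpectrum:
    def test_zero_distance_is_identity(self, rng):
        field = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        out = propagate_angular_spectrum(field, 0.0, 0.55, 0.2)
        np.testing.assert_allclose(out, field, atol=1e-12)

    def test_energy_conserved_for_bandlimited_field(self, rng):
        # band-limited (smooth) field: no evanescent loss, unitary transfer
        noise = rng.standard_normal((128, 128))
        from numpy.fft import fft2, ifft2, fftfreq
        f = fftfreq(128, d=0.2)
        fx, fy = np.meshgrid(f, f)
        field = ifft2(fft2(noise) * (fx**2 + fy**2 < 0.5**2))
        for z in (1.0, 5.0, -3.0):
            out = propagate_angular_spectrum(field, z, 0.55, 0.2)
            assert np.sum(np.abs(out) ** 2) == pytest.approx(
                np.sum(np.abs(field) ** 2), rel=1e-6)

    def test_gaussian_beam_waist_matches_analytic(self):
        # w(z) = w0 sqrt(1 + (z/zR)^2), zR = pi w0^2 / lambda
        lam, w0, pitch, n = 0.55, 3.0, 0.2, 512
        y, x = (np.mgrid[0:n, 0:n] - n / 2) * pitch
        r2 = x**2 + y**2
        field = np.exp(-r2 / w0**2)
        z_r = np.pi * w0**2 / lam
        for z in (0.5 * z_r, z_r):
            out = propagate_angular_spectrum(field, z, lam, pitch)
            intensity = np.abs(out) ** 2
            mean_r2 = float((intensity * r2).sum() / intensity.sum())
            w_meas = np.sqrt(2.0 * mean_r2)
            w_true = w0 * np.sqrt(1 + (z / z_r) ** 2)
            assert w_meas == pytest.approx(w_true, rel=0.01)

    def test_nonfinite_field_rejected(self):
        field = np.ones((32, 32), complex)
        field[0, 0] = np.nan
        with pytest.raises(ValueError):
            propagate_angular_spectrum(field, 1.0, 0.55, 0.2)


# -- imaging ----------------------------------------------------------------

class TestImaging:
    def _flat(self, pitch=0.1625, n=64):
        from qpigan.optics import PhaseMap
        return PhaseMap(np.zeros((n, n)), pitch)

    def test_empty_phase_object_gives_uniform_intensity(self, cfg_40x):
        img = image_through_system(self._flat(), cfg_40x, z_offset=3.0)
        assert img.values.std() / img.values.mean() < 1e-6

    def test_defocus_contrast_exceeds_infocus_for_weak_phase(self, cfg_40x_coherent):
        from qpigan.optics import PhaseMap
        y, x = np.mgrid[0:64, 0:64] * 0.1625
        phi = 0.1 * np.exp(-((x - 5.2) ** 2 + (y - 5.2) ** 2) / 2.0)
        pm = PhaseMap(phi, 0.1625)
        def contrast(z):
            v = image_through_system(pm, cfg_40x_coherent, z).values
            return (v.max() - v.min()) / v.mean()
        assert contrast(0.0) < contrast(3.0)

    def test_weak_phase_defocus_difference_has_zero_mean(self, cfg_40x_coherent):
        from qpigan.optics import PhaseMap
        y, x = np.mgrid[0:64, 0:64] * 0.1625
        phi = 0.1 * np.exp(-((x - 5.2) ** 2 + (y - 5.2) ** 2) / 2.0)
        pm = PhaseMap(phi, 0.1625)
        plus = image_through_system(pm, cfg_40x_coherent, +3.0).values
        minus = image_through_system(pm, cfg_40x_coherent, -3.0).values
        assert abs(np.mean(plus - minus)) < 1e-3 * plus.mean()

    def test_contrast_grows_with_defocus_in_weak_phase_regime(self, cfg_40x_coherent):
        from qpigan.optics import PhaseMap
        y, x = np.mgrid[0:64, 0:64] * 0.1625
        phi = 0.05 * np.exp(-((x - 5.2) ** 2 + (y - 5.2) ** 2) / 3.0)
        pm = PhaseMap(phi, 0.1625)
        contrasts = []
        for z in (0.5, 1.5, 3.0):
            v = image_through_system(pm, cfg_40x_coherent, z).values
            contrasts.append((v.max() - v.min()) / v.mean())
        assert contrasts[0] < contrasts[1] < contrasts[2]

    def test_unresolvable_na_raises(self):
        from qpigan.optics import PhaseMap
        pm = PhaseMap(np.zeros((8, 8)), 0.5)  # df = 0.25/um > NA/lambda
        cfg = OpticalConfig(na_objective=0.1)
        with pytest.raises(ValueError, match="NA unresolvable"):
            image_through_system(pm, cfg, 0.0)

    def test_noise_is_seeded_and_reproducible(self, cfg_40x):
        from qpigan.optics import PhaseMap
        pm = PhaseMap(np.zeros((32, 32)), 0.1625)
        a = image_through_system(pm, cfg_40x, 3.0, noise_seed=5)
        b = image_through_system(pm, cfg_40x, 3.0, noise_seed=5)
        c = image_through_system(pm, cfg_40x, 3.0, noise_seed=6)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)


class TestDefocusStack:
    def test_stack_offsets_match_config(self, cfg_40x):
        spec = random_sphere_spec(1, 64, 0.1625, seed=1)
        pm = make_sphere_phantom(spec, cfg_40x.wavelength)
        stack = acquire_defocus_stack(pm, cfg_40x)
        assert stack.minus.z_offset == -cfg_40x.defocus_dz
        assert stack.plus.z_offset == +cfg_40x.defocus_dz
        assert stack.focus.z_offset == 0.0

    def test_empty_object_gives_three_uniform_planes(self, cfg_40x):
        from qpigan.optics import PhaseMap
        stack = acquire_defocus_stack(PhaseMap(np.zeros((32, 32)), 0.1625), cfg_40x)
        for plane in (stack.minus, stack.focus, stack.plus):
            assert plane.values.std() / plane.values.mean() < 1e-6

    def test_mismatched_planes_rejected(self):
        a = IntensityImage(np.ones((16, 16)), 0.2, -3.0)
        b = IntensityImage(np.ones((16, 16)), 0.2, 0.0)
        c = IntensityImage(np.ones((32, 32)), 0.2, 3.0)
        with pytest.raises(ValueError, match="shape"):
            DefocusStack(minus=a, focus=b, plus=c)


# -- tiling and datasets ----------------------------------------------------

class TestTiling:
    def test_10x_to_40x_gives_16_tiles(self, rng):
        img = IntensityImage(rng.random((64, 64)), 0.65)
        tiles = tile_to_fov(img, mag_low=10, mag_high=40)
        assert len(tiles) == 16
        assert all(t.shape == (16, 16) for t in tiles)

    def test_equal_magnification_is_identity(self, rng):
        img = IntensityImage(rng.random((32, 32)), 0.65)
        tiles = tile_to_fov(img, 20, 20)
        assert len(tiles) == 1
        np.testing.assert_array_equal(tiles[0].values, img.values)

    def test_tiles_partition_input_exactly(self, rng):
        img = IntensityImage(rng.random((32, 32)), 0.65)
        tiles = tile_to_fov(img, 20, 40)
        assert len(tiles) == 4
        top = np.concatenate([tiles[0].values, tiles[1].values], axis=1)
        bottom = np.concatenate([tiles[2].values, tiles[3].values], axis=1)
        np.testing.assert_array_equal(np.concatenate([top, bottom], axis=0), img.values)

    def test_nonintegral_ratio_rejected(self, rng):
        img = IntensityImage(rng.random((30, 30)), 0.65)
        with pytest.raises(ValueError, match="not integral"):
            tile_to_fov(img, 10, 25)
        with pytest.raises(ValueError, match="divisible"):
            tile_to_fov(IntensityImage(rng.random((30, 30)), 0.65), 10, 40)


def _specs(n, seed0=100, grid=48, pitch=0.1625):
    return [random_sphere_spec(1, grid, pitch, seed=seed0 + i, margin=0.5)
            for i in range(n)]


class TestUnpairedDataset:
    CFG_LOW = OpticalConfig(na_objective=0.25, magnification=10.0,
                            camera_pitch=0.65, coherence_s=0.0)
    CFG_HIGH = OpticalConfig(na_objective=0.65, magnification=40.0,
                             camera_pitch=0.1625, coherence_s=0.0)

    def test_split_sizes_85_15(self):
        cfg = OpticalConfig(na_objective=0.4, magnification=20.0,
                            camera_pitch=0.325, coherence_s=0.0)
        train, test = build_unpaired_dataset(_specs(20), cfg, cfg,
                                             split_fraction=0.85, seed=1)
        assert len(train.set_a) == len(train.set_b) == 17
        assert len(test.set_a) == len(test.set_b) == 3

    def test_same_seed_reproduces_dataset(self):
        cfg = OpticalConfig(na_objective=0.4, magnification=20.0,
                            camera_pitch=0.325, coherence_s=0.0)
        t1, _ = build_unpaired_dataset(_specs(4), cfg, cfg, seed=9)
        t2, _ = build_unpaired_dataset(_specs(4), cfg, cfg, seed=9)
        for a, b in zip(t1.set_a, t2.set_a):
            np.testing.assert_array_equal(a.values, b.values)
        for a, b in zip(t1.set_b, t2.set_b):
            np.testing.assert_array_equal(a.values, b.values)

    def test_lr_side_downsampled_by_magnification_ratio(self):
        train, test = build_unpaired_dataset(_specs(4, grid=48), self.CFG_LOW,
                                             self.CFG_HIGH, seed=2)
        items = train.set_a + test.set_a
        assert all(im.shape == (12, 12) for im in items)  # 48 / (40/10)
        assert all(pm.shape == (48, 48) for pm in train.set_b + test.set_b)

    def test_sides_are_shuffled_independently(self):
        # match items back to their generating spec by array identity; the
        # two sides' generation orders should be uncorrelated across seeds
        from scipy.stats import spearmanr
        cfg = OpticalConfig(na_objective=0.4, magnification=20.0,
                            camera_pitch=0.325, coherence_s=0.0)
        specs = _specs(12)
        ref_a = [image_through_system(
            make_sphere_phantom(s, cfg.wavelength), cfg, 0.0).values
            for s in specs]
        corrs = []
        for seed in range(10):
            train, test = build_unpaired_dataset(specs, cfg, cfg,
                                                 split_fraction=0.99, seed=seed)
            items = train.set_a + test.set_a
            order_a = [next(i for i, r in enumerate(ref_a)
                            if np.array_equal(r, im.values)) for im in items]
            corrs.append(spearmanr(order_a, np.arange(len(order_a))).statistic)
        assert abs(np.mean(corrs)) < 0.35

    def test_too_few_phantoms_rejected(self):
        cfg = OpticalConfig(na_objective=0.4, magnification=20.0,
                            camera_pitch=0.325)
        with pytest.raises(ValueError, match="at least 2"):
            build_unpaired_dataset(_specs(1), cfg, cfg, seed=0)
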