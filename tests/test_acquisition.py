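"""Camera model, spectral film, filtering, rendering and development."""

import numpy as np
import pytest

from lsfmsim.acquisition import (
    OrthographicThinLensCamera,
    SpectralFilm,
    apply_emission_filter,
    concentric_disk,
    detect_photons,
    develop_image,
    generate_camera_rays,
    render_section,
)
from lsfmsim.spectral import EmissionFilter, SpectralDistribution, WavelengthGrid


def make_camera(**kw):
    defaults = dict(
        film_width_um=4.0,
        film_height_um=4.0,
        resolution=(32, 32),
        samples_per_pixel=4,
        focus_distance_um=1000.0,
    )
    defaults.update(kw)
    return OrthographicThinLensCamera(**defaults)


class TestCameraRays:
    def test_pinhole_rays_parallel_to_view_axis(self):
        cam = make_camera(aperture_radius_um=0.0)
        pix = np.array([[0.5, 0.5], [16.0, 16.0], [31.5, 31.5]])
        origins, dirs = generate_camera_rays(cam, pix)
        np.testing.assert_allclose(dirs, [[0.0, 0.0, -1.0]] * 3)
        # film center pixel maps to the camera center axis
        np.testing.assert_allclose(origins[1][:2], [0.0, 0.0], atol=1e-12)
        # corner-to-corner span equals the film size
        assert origins[2][0] - origins[0][0] == pytest.approx(
            4.0 * 31.0 / 32.0
        )

    def test_lens_rays_converge_on_focal_plane_point(self):
        cam = make_camera(aperture_radius_um=50.0, focal_plane_z_um=3.0)
        pix = np.tile([[8.0, 4.0]], (64, 1))
        uv = np.random.default_rng(0).random((64, 2))
        origins, dirs = generate_camera_rays(cam, pix, uv)
        t = (cam.focal_plane_z_um - origins[:, 2]) / dirs[:, 2]
        hits = origins + t[:, None] * dirs
        assert np.ptp(hits[:, 0]) < 1e-9
        assert np.ptp(hits[:, 1]) < 1e-9

    def test_defocus_blur_radius_follows_similar_triangles(self):
        """Spread at dz off focus = aperture * dz / focus_distance."""
        aperture, dz, fd = 100.0, 10.0, 1000.0
        cam = make_camera(
            aperture_radius_um=aperture, focal_plane_z_um=0.0,
            focus_distance_um=fd,
        )
        pix = np.tile([[16.0, 16.0]], (1000, 1))
        uv = np.random.default_rng(1).random((1000, 2))
        origins, dirs = generate_camera_rays(cam, pix, uv)
        t = (dz - origins[:, 2]) / dirs[:, 2]  # plane z = +dz (off focus)
        hits = origins + t[:, None] * dirs
        center = np.array([0.0, 0.0])
        radii = np.linalg.norm(hits[:, :2] - center, axis=1)
        expected = aperture * dz / fd
        assert radii.max() <= expected * (1.0 + 1e-9)
        assert radii.max() > expected * 0.9  # disk samples reach the rim

    def test_concentric_disk_stays_in_unit_disk_and_is_uniform(self):
        rng = np.random.default_rng(2)
        u, v = rng.random(20000), rng.random(20000)
        x, y = concentric_disk(u, v)
        r2 = x * x + y * y
        assert r2.max() <= 1.0 + 1e-12
        # uniform disk: E[r^2] = 1/2
        assert r2.mean() == pytest.approx(0.5, abs=0.01)

    def test_invalid_camera_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_camera(aperture_radius_um=-1.0)
        with pytest.raises(ValueError):
            make_camera(resolution=(0, 4))


class TestEmissionFilterApplication:
    def test_unity_filter_is_identity(self, grid5):
        spd = SpectralDistribution(grid5, np.linspace(0, 1, grid5.n_bins))
        out = apply_emission_filter(spd, EmissionFilter.unity(grid5))
        np.testing.assert_array_equal(out.values, spd.values)

    def test_notch_zeroes_only_the_laser_line(self, grid5):
        spd = SpectralDistribution(grid5, np.ones(grid5.n_bins))
        out = apply_emission_filter(spd, EmissionFilter.notch(grid5, 488.0))
        i = grid5.bin_index(488.0)
        assert np.all(out.values[i - 1 : i + 2] == 0.0)
        assert out.values[i + 3] == 1.0

    def test_bandpass_keeps_in_band_integral(self, gfp, grid5):
        filt = EmissionFilter.bandpass(grid5, 500.0, 550.0)
        out = apply_emission_filter(gfp.f_em, filt)
        c = grid5.centers
        band = (c >= 500.0) & (c <= 550.0)
        assert out.integrate() == pytest.approx(
            gfp.f_em.values[band].sum() * grid5.step_nm
        )

    def test_grid_mismatch_rejected(self, gfp):
        other = WavelengthGrid(300.0, 800.0, 10.0)
        with pytest.raises(ValueError):
            apply_emission_filter(gfp.f_em, EmissionFilter.unity(other))


class TestFilmArithmetic:
    def test_black_film_detects_nothing(self, grid5):
        film = SpectralFilm(grid5, (8, 8), 1e-8)
        assert detect_photons(film) == 0.0

    def test_uniform_film_detection_formula(self, grid5):
        v, area = 3.0, 2.0e-8
        values = np.full((4, 4, grid5.n_bins), v)
        film = SpectralFilm(grid5, (4, 4), area, values)
        expected = v * 16 * grid5.n_bins * grid5.step_nm * area
        assert detect_photons(film) == pytest.approx(expected)

    def test_develop_black_film(self, grid5):
        film = SpectralFilm(grid5, (8, 8), 1e-8)
        img, meta = develop_image(film)
        assert img.dtype == np.uint16
        assert np.all(img == 0)

    def test_develop_scale_round_trips_photon_counts(self, grid5):
        rng = np.random.default_rng(3)
        values = rng.random((8, 8, grid5.n_bins))
        film = SpectralFilm(grid5, (8, 8), 1e-8, values)
        img, meta = develop_image(film)
        recovered = img.astype(float) * meta["scale"]
        np.testing.assert_allclose(
            recovered, film.photon_image(), atol=meta["scale"]
        )

    def test_develop_linearity_between_films(self, grid5):
        values = np.random.default_rng(4).random((8, 8, grid5.n_bins))
        f1 = SpectralFilm(grid5, (8, 8), 1e-8, values)
        f2 = SpectralFilm(grid5, (8, 8), 1e-8, 2.0 * values)
        img1, m1 = develop_image(f1)
        img2, m2 = develop_image(f2)
        # shared scaling: gray = photons / scale, scale doubles with the peak
        assert m2["scale"] == pytest.approx(2.0 * m1["scale"])
        np.testing.assert_allclose(
            img2.astype(int), img1.astype(int), atol=1
        )

    def test_pseudocolor_mode_returns_rgb(self, grid5):
        values = np.zeros((4, 4, grid5.n_bins))
        values[:, :, grid5.bin_index(530.0)] = 1.0
        film = SpectralFilm(grid5, (4, 4), 1e-8, values)
        rgb, _ = develop_image(film, mode="pseudocolor_by_dye")
        assert rgb.shape == (4, 4, 3)
        assert rgb[..., 1].max() > 0  # 530 nm is green


class TestRenderSection:
    def test_zero_density_specimen_renders_black(self, cube_scene):
        cube_scene.grid.density[:] = 0.0
        cube_scene.grid.dye_index[:] = -1
        film = render_section(cube_scene, make_camera())
        assert np.all(film.values == 0.0)

    def test_deterministic_for_fixed_seed(self, cube_scene):
        f1 = render_section(cube_scene, make_camera(seed=5))
        f2 = render_section(cube_scene, make_camera(seed=5))
        np.testing.assert_array_equal(f1.values, f2.values)
        f3 = render_section(cube_scene, make_camera(seed=6))
        assert not np.array_equal(f1.values, f3.values)

    def test_pinhole_image_independent_of_focus_distance(self, cube_scene):
        """Zero aperture means infinite depth of field (equal to roundoff:
        the march parametrisation shifts with the lens distance)."""
        f1 = render_section(
            cube_scene, make_camera(seed=5, focus_distance_um=500.0)
        )
        f2 = render_section(
            cube_scene, make_camera(seed=5, focus_distance_um=1500.0)
        )
        np.testing.assert_allclose(f1.values, f2.values, rtol=1e-12)

    def test_centered_cube_image_is_symmetric(self, cube_scene):
        """Flip asymmetry is pure MC noise, not a geometric bias."""
        img = render_section(
            cube_scene, make_camera(samples_per_pixel=8, seed=0)
        ).photon_image()
        img_b = render_section(
            cube_scene, make_camera(samples_per_pixel=8, seed=1)
        ).photon_image()
        noise = np.abs(img - img_b).mean()  # seed-to-seed MC scale
        assert noise > 0
        assert np.abs(img - img[::-1, :]).mean() < 2.0 * noise
        assert np.abs(img - img[:, ::-1]).mean() < 2.0 * noise

    def test_notch_filtered_spd_vanishes_at_excitation_bin(self, grid5, cube_scene):
        cube_scene.grid.sigma_s_elastic_cm = 5.0
        film = render_section(
            cube_scene, make_camera(), EmissionFilter.notch(grid5, 488.0)
        )
        assert np.all(film.values[:, :, grid5.bin_index(488.0)] == 0.0)

    def test_opposing_cameras_reciprocal_on_symmetric_scene(self, cube_scene):
        """±z detections agree within 3x the combined MC standard error."""
        results = {}
        for sign in (-1, 1):
            film, totals = render_section(
                cube_scene,
                make_camera(view_sign=sign, samples_per_pixel=16,
                            seed=7 if sign < 0 else 8),
                return_sample_totals=True,
            )
            totals = np.asarray(totals)
            results[sign] = (
                detect_photons(film),
                totals.std(ddof=1) / np.sqrt(len(totals)),
            )
        (c1, se1), (c2, se2) = results[-1], results[1]
        assert abs(c1 - c2) <= 3.0 * np.hypot(se1, se2) + 1e-9 * c1

    def test_mc_error_shrinks_with_sample_count(self, cube_scene):
        """Per-pixel spread across replicate renders falls ~sqrt(spp)."""
        spreads = {}
        for spp in (4, 32):
            stack = [
                render_section(
                    cube_scene,
                    make_camera(samples_per_pixel=spp, seed=100 + r,
                                aperture_radius_um=100.0),
                ).photon_image()
                for r in range(6)
            ]
            spreads[spp] = np.stack(stack).std(axis=0, ddof=1).mean()
        ratio = spreads[4] / spreads[32]
        assert 1.7 <= ratio <= 4.5  # ideal sqrt(8) ~ 2.83
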