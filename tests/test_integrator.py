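"""Single-scattering integrator: transmittance, source term, slab oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from lsfmsim.illumination import LightSheet
from lsfmsim.integrator import (
    FOUR_PI,
    MarchSettings,
    Ray,
    Scene,
    integrate_ray,
    integrate_rays,
    phase_hg,
    phase_isotropic,
    source_term,
    transmittance,
)
from lsfmsim.specimen import (
    AnnotatedFluorescentVolumeGrid,
    FluorophoreTable,
    make_homogeneous_cube,
    sample_density,
)
from lsfmsim.units import um_to_cm

from conftest import gaussian_line_dye


def make_slab_scene(
    grid5,
    n_cm3=1.0e15,
    nz=4,
    voxel_um=0.25,
    nxy=40,
    photons=1.0e12,
    sigma_s=0.0,
    jitter=False,
):
    """Homogeneous fluorescent slab filling the whole grid (thin along z)."""
    dims = (nxy, nxy, nz)
    dens = np.full(dims, n_cm3)
    dye = np.zeros(dims, dtype=np.int32)
    size = np.array(dims) * voxel_um
    grid = AnnotatedFluorescentVolumeGrid(
        dims, voxel_um, -size / 2.0, dens, dye, sigma_s
    )
    sheet = LightSheet(
        thickness_um=size[2] + 2.0,
        height_um=size[1] + 2.0,
        lambda_ex_nm=488.0,
        photons=photons,
    )
    dyes = FluorophoreTable([gaussian_line_dye(grid5)])
    return Scene(grid, sheet, dyes, MarchSettings.for_grid(grid, jitter=jitter), grid5)


class TestTransmittance:
    def test_vacuum_transmits_everything(self):
        grid = make_homogeneous_cube(2.0, 0.0, 0, 0.1)

        def sigma_fn(p):
            return 3e-16 * sample_density(grid, p)

        assert transmittance((-5, 0, 0), (5, 0, 0), sigma_fn, 0.05) == 1.0

    def test_homogeneous_medium_closed_form(self):
        grid = make_homogeneous_cube(2.0, 1.0e18, 0, 0.1)
        sigma_n = 3e-16 * 1.0e18  # 300 /cm

        def sigma_fn(p):
            return 3e-16 * sample_density(grid, p)

        # segment strictly inside the uniform core: midpoint rule is exact
        got = transmittance((0, 0, -0.9), (0, 0, 0.9), sigma_fn, 0.05)
        assert got == pytest.approx(np.exp(-sigma_n * um_to_cm(1.8)), rel=1e-9)

    def test_multiplicative_over_concatenated_segments(self):
        grid = make_homogeneous_cube(2.0, 1.0e18, 0, 0.1)

        def sigma_fn(p):
            return 3e-16 * sample_density(grid, p)

        whole = transmittance((0, 0, -0.9), (0, 0, 0.9), sigma_fn, 0.045)
        t1 = transmittance((0, 0, -0.9), (0, 0, 0.0), sigma_fn, 0.045)
        t2 = transmittance((0, 0, 0.0), (0, 0, 0.9), sigma_fn, 0.045)
        assert whole == pytest.approx(t1 * t2, rel=1e-6)

    def test_linear_gradient_matches_quadrature_oracle(self):
        """Ray-marched optical depth vs adaptive quadrature, <=0.5%."""
        grid = make_homogeneous_cube(2.0, 1.0e18, 0, 0.1)
        k = np.arange(20, dtype=float)
        grid.density[:] = 1.0e18 * (1.0 + k[None, None, :]) / 10.0

        def sigma_fn(p):
            return 3e-16 * sample_density(grid, p)

        got = transmittance((0.3, 0.1, -1.05), (0.3, 0.1, 1.05), sigma_fn, 0.05)
        tau, _ = quad(
            lambda z: sigma_fn(np.array([[0.3, 0.1, z]]))[0] * um_to_cm(1.0),
            -1.05,
            1.05,
            limit=400,
        )
        assert got == pytest.approx(np.exp(-tau), rel=0.005)

    def test_scene_chromatic_extinction_follows_excitation_spectrum(
        self, grid5, line_dye
    ):
        """At a wavelength where the dye does not absorb, the medium is clear."""
        grid = make_homogeneous_cube(2.0, 1.0e18, 0, 0.1)
        sheet = LightSheet(2.0, 2.0, 488.0, 1e12)
        scene = Scene(
            grid, sheet, FluorophoreTable([line_dye]),
            MarchSettings.for_grid(grid), grid5,
        )
        t_peak = transmittance((0, 0, -0.9), (0, 0, 0.9), scene, 0.05, 488.0)
        t_red = transmittance((0, 0, -0.9), (0, 0, 0.9), scene, 0.05, 700.0)
        sigma_n = line_dye.sigma_cm2 * 1.0e18
        assert t_peak == pytest.approx(
            np.exp(-sigma_n * float(line_dye.excitation(488.0)) * um_to_cm(1.8)),
            rel=1e-6,
        )
        assert t_red == pytest.approx(1.0, abs=1e-9)


class TestPhaseFunctions:
    def test_isotropic_is_inverse_four_pi(self):
        assert phase_isotropic((1, 0, 0), (0, 0, 1)) == pytest.approx(
            0.0795775, abs=1e-7
        )

    @pytest.mark.parametrize("g", [-0.7, -0.2, 0.0, 0.3, 0.8])
    def test_henyey_greenstein_normalizes_over_sphere(self, g):
        total, _ = quad(
            lambda ct: phase_hg(ct, g) * 2.0 * np.pi, -1.0, 1.0, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_henyey_greenstein_reduces_to_isotropic(self):
        ct = np.linspace(-1, 1, 11)
        np.testing.assert_allclose(phase_hg(ct, 0.0), 1.0 / FOUR_PI)

    def test_invalid_anisotropy_rejected(self):
        with pytest.raises(ValueError):
            phase_hg(0.5, 1.0)


class TestSourceTerm:
    def test_zero_without_dye_or_scatterer(self, grid5, line_dye):
        grid = make_homogeneous_cube(2.0, 0.0, 0, 0.1)
        sheet = LightSheet(4.0, 4.0, 488.0, 1e12)
        scene = Scene(
            grid, sheet, FluorophoreTable([line_dye]),
            MarchSettings.for_grid(grid), grid5,
        )
        for lam in (488.0, 530.0):
            assert source_term((0, 0, 0), (0, 0, 1), lam, scene) == 0.0

    def test_zero_where_emission_spectrum_is_zero(self, cube_scene):
        assert source_term((0, 0, 0), (0, 0, 1), 700.0, cube_scene) == 0.0
        assert source_term((0, 0, 0), (0, 0, 1), 330.0, cube_scene) == 0.0

    def test_emission_bins_sum_to_absorbed_times_yield(self, cube_scene):
        """4*pi * sum_bins S * dlam = sigma*N*phi*f_ex(lam_ex)*flux."""
        sg = cube_scene.spectral_grid
        dye = cube_scene.fluos[0]
        flux = cube_scene.sheet.flux_density_cm2
        total = sum(
            source_term((0, 0, 0), (0, 0, 1), lam, cube_scene) * sg.step_nm
            for lam in sg.centers
        )
        expected = (
            dye.sigma_cm2
            * 1.0e18
            * dye.phi
            * float(dye.excitation(488.0))
            * flux
            / FOUR_PI
        )
        assert total == pytest.approx(expected, rel=1e-6)

    def test_outside_sheet_is_dark(self, cube_scene):
        assert source_term((0, 0, 1.5), (0, 0, 1), 530.0, cube_scene) == 0.0

    def test_elastic_point_returns_at_excitation_wavelength_only(self, grid5):
        scene = make_slab_scene(grid5, n_cm3=0.0, sigma_s=1.0)
        scene.grid.dye_index[:] = -1
        sg = scene.spectral_grid
        flux = scene.sheet.flux_density_cm2
        got = source_term((0, 0, 0), (0, 0, 1), 488.0, scene)
        expected = 1.0 * phase_hg(0.0, 0.0) * flux / sg.step_nm
        assert got == pytest.approx(expected, rel=1e-9)
        assert source_term((0, 0, 0), (0, 0, 1), 530.0, scene) == 0.0


class TestIntegrateRay:
    def test_ray_missing_specimen_is_black(self, cube_scene):
        ray = Ray((10.0, 10.0, 5.0), (0.0, 0.0, -1.0))
        spd = integrate_ray(ray, cube_scene)
        assert np.all(spd.values == 0.0)

    def test_thin_slab_matches_single_scatter_closed_form(self, grid5):
        """L(lam) = (1/4pi) sigma N phi f_ex Phi f_em(lam) d within 1%."""
        scene = make_slab_scene(grid5)
        dye = scene.fluos[0]
        spd = integrate_ray(Ray((0.0, 0.0, 5.0), (0.0, 0.0, -1.0)), scene)
        d_cm = um_to_cm(scene.grid.size_um[2])
        pref = (
            dye.sigma_cm2
            * 1.0e15
            * dye.phi
            * float(dye.excitation(488.0))
            * scene.sheet.flux_density_cm2
            * d_cm
            / FOUR_PI
        )
        band = dye.f_em.values > dye.f_em.values.max() * 1e-3
        np.testing.assert_allclose(
            spd.values[band], pref * dye.f_em.values[band], rtol=0.01
        )

    def test_halving_step_changes_slab_result_marginally(self, grid5):
        scene = make_slab_scene(grid5)
        ray = Ray((0.1, -0.2, 5.0), (0.0, 0.0, -1.0))
        coarse = integrate_ray(ray, scene).integrate()
        scene.march.step_um /= 2.0
        fine = integrate_ray(ray, scene).integrate()
        assert abs(coarse - fine) / fine < 0.005

    def test_radiance_linear_in_photon_budget(self, grid5):
        scene = make_slab_scene(grid5, photons=1.0e12)
        ray = Ray((0.0, 0.0, 5.0), (0.0, 0.0, -1.0))
        l1 = integrate_ray(ray, scene).values
        scene.sheet.photons = 2.0e12
        l2 = integrate_ray(ray, scene).values
        np.testing.assert_allclose(l2, 2.0 * l1, rtol=1e-12)

    def test_emitted_wavelengths_confined_to_emission_support(self, grid5):
        scene = make_slab_scene(grid5)
        spd = integrate_ray(Ray((0.0, 0.0, 5.0), (0.0, 0.0, -1.0)), scene)
        dye = scene.fluos[0]
        assert np.all(spd.values[dye.f_em.values == 0.0] == 0.0)

    def test_elastic_only_scene_reproduces_elastic_slab_form(self, grid5):
        """F(p)=0 everywhere: a pure elastic single-scatter renderer."""
        scene = make_slab_scene(grid5, n_cm3=0.0, sigma_s=1.0)
        scene.grid.dye_index[:] = -1
        spd = integrate_ray(Ray((0.0, 0.0, 5.0), (0.0, 0.0, -1.0)), scene)
        sg = scene.spectral_grid
        i_ex = sg.bin_index(488.0)
        d_cm = um_to_cm(scene.grid.size_um[2])
        expected = (
            1.0 * phase_hg(0.0, 0.0) * scene.sheet.flux_density_cm2 * d_cm
            / sg.step_nm
        )
        assert spd.values[i_ex] == pytest.approx(expected, rel=1e-3)
        off = np.ones(sg.n_bins, dtype=bool)
        off[i_ex] = False
        assert np.all(spd.values[off] == 0.0)

    def test_jittered_march_is_seeded_and_unbiased(self, grid5):
        scene = make_slab_scene(grid5, jitter=True)
        o = np.tile([[0.0, 0.0, 5.0]], (400, 1))
        d = np.tile([[0.0, 0.0, -1.0]], (400, 1))
        rng = np.random.default_rng(11)
        a = integrate_rays(o, d, scene, rng=np.random.default_rng(11))
        b = integrate_rays(o, d, scene, rng=np.random.default_rng(11))
        np.testing.assert_array_equal(a, b)
        scene.march.jitter = False
        ref = integrate_rays(o[:1], d[:1], scene)[0]
        mean_jit = integrate_rays(o, d, scene, rng=rng).mean(axis=0)
        band = ref > ref.max() * 1e-2
        np.testing.assert_allclose(mean_jit[band], ref[band], rtol=0.02)

    def test_ray_validation(self):
        with pytest.raises(ValueError):
            Ray((0, 0, 0), (0, 0, 2.0))
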