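"""Executable validation experiments for the simulator.

Three studies mirror how a physically-based fluorescence renderer is
validated:

* **Brightness validation** — a small homogeneous fluorescent cube, fully
  and uniformly illuminated, is imaged from two opposite directions.  Under
  isotropic emission the photon count expected at one detection plane is the
  fluorescence brightness equation (FBE)
  ``F = (1/4π) · I · σ · N · φ · l`` (I: sheet photons, σ: absorption cross
  section, N: concentration, l: path length through the cube).  The
  simulated film totals must match this closed form, scale linearly with I,
  and agree between the two opposing cameras to Monte Carlo precision.
* **Emission-SPD recovery** — the film-integrated spectrum of a rendered
  section must reproduce the dye's emission line shape f_em for every
  excitation wavelength, with amplitudes across excitations scaling as the
  excitation spectrum f_ex (the separability of the fluorescence
  efficiency).
* **Sheet-thickness blur** — with a finite aperture, thicker sheets admit
  more out-of-focus light, so image sharpness must fall monotonically with
  sheet thickness and be thickness-invariant for a pinhole aperture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acquisition import (
    EmissionFilter,
    OrthographicThinLensCamera,
    detect_photons,
    render_section,
)
from .illumination import LightSheet
from .integrator import FOUR_PI, MarchSettings, Scene
from .specimen import (
    Cylinder,
    FluorophoreTable,
    make_homogeneous_cube,
    voxelize_primitives,
)
from .spectral import Fluorophore, SpectralDistribution, WavelengthGrid
from .units import um_to_cm, um3_to_cm3

__all__ = [
    "FBEExperimentConfig",
    "fbe_expected_photons",
    "run_fbe_experiment",
    "measure_emission_spd",
    "blur_vs_thickness",
    "make_axial_rod_phantom",
    "sharpness",
    "total_emitted_photons",
]


def fbe_expected_photons(
    intensity_photons: float, sigma_cm2: float, n_cm3: float, phi: float,
    path_length_cm: float,
) -> float:
    """Fluorescence brightness equation: photons at one detection plane.

    ``F = (1/4π) · I · σ · N · φ · l`` — the isotropically emitted photons
    of a uniformly excited thin volume, apportioned per unit solid angle to
    a single detection direction.
    """
    if min(intensity_photons, sigma_cm2, n_cm3, phi, path_length_cm) < 0:
        raise ValueError("FBE parameters must be non-negative")
    return intensity_photons * sigma_cm2 * n_cm3 * phi * path_length_cm / FOUR_PI


@dataclass
class FBEExperimentConfig:
    """Brightness-validation setup: cube phantom, full-face sheet, ±z cameras."""

    cube_side_um: float = 2.0
    sigma_cm2: float = 3.0e-16  # low molecular absorption cross section
    n_cm3: float = 1.0e18
    phi: float = 0.8
    intensities: tuple = tuple((i + 1) * 1.0e12 for i in range(10))
    voxel_size_um: float = 0.05
    resolution: int = 128
    samples_per_pixel: int = 64
    lambda_ex_nm: float = 488.0
    seed: int = 0

    @property
    def optical_depth(self) -> float:
        return self.sigma_cm2 * self.n_cm3 * um_to_cm(self.cube_side_um)


def _fbe_fluorophore(cfg: FBEExperimentConfig, grid: WavelengthGrid) -> Fluorophore:
    """Idealized dye for the brightness phantom: Gaussian excitation band
    peaking exactly at the laser line (so f_ex(λex) = 1, as the brightness
    equation assumes maximal excitation), Stokes-shifted Gaussian emission."""
    centers = grid.centers
    ex = np.exp(-0.5 * ((centers - cfg.lambda_ex_nm) / 20.0) ** 2)
    em = np.exp(-0.5 * ((centers - (cfg.lambda_ex_nm + 42.0)) / 18.0) ** 2)
    ex[ex < 1e-6] = 0.0  # truncate tails as tabulated spectra do
    em[em < 1e-6] = 0.0
    f_ex = SpectralDistribution(grid, ex).normalized_to_peak()
    f_em = SpectralDistribution(grid, em).normalized_to_unit_integral()
    return Fluorophore("fbe_dye", f_ex, f_em, cfg.phi, cfg.sigma_cm2)


def build_fbe_scene(cfg: FBEExperimentConfig, intensity: float,
                    spectral_grid: WavelengthGrid | None = None) -> Scene:
    sg = spectral_grid or WavelengthGrid()
    grid = make_homogeneous_cube(
        cfg.cube_side_um, cfg.n_cm3, dye_index=0, voxel_size_um=cfg.voxel_size_um
    )
    # sheet sized to the cube face: the sheet area then cancels exactly as in
    # the brightness equation (flux density I / l², collected over area l²)
    sheet = LightSheet(
        thickness_um=cfg.cube_side_um,
        height_um=cfg.cube_side_um,
        lambda_ex_nm=cfg.lambda_ex_nm,
        photons=intensity,
        z_um=0.0,
    )
    fluos = FluorophoreTable([_fbe_fluorophore(cfg, sg)])
    march = MarchSettings.for_grid(grid)
    return Scene(grid, sheet, fluos, march, sg)


def _fbe_camera(cfg: FBEExperimentConfig, view_sign: int, seed: int
                ) -> OrthographicThinLensCamera:
    fov = cfg.cube_side_um * 1.6  # covers the half-voxel interpolation skirt
    return OrthographicThinLensCamera(
        film_width_um=fov,
        film_height_um=fov,
        resolution=(cfg.resolution, cfg.resolution),
        aperture_radius_um=0.0,
        view_sign=view_sign,
        samples_per_pixel=cfg.samples_per_pixel,
        seed=seed,
    )


def run_fbe_experiment(
    cfg: FBEExperimentConfig | None = None,
    spectral_grid: WavelengthGrid | None = None,
) -> pd.DataFrame:
    """Render the brightness-validation cube for each laser intensity.

    Returns one row per intensity with the analytic expectation, both
    cameras' detected photons, their per-camera Monte Carlo standard errors,
    and the sim/analytic ratios.  Warns (does not fail) if the cube is not
    optically thin, since uniform excitation then no longer holds.
    """
    cfg = cfg or FBEExperimentConfig()
    if cfg.optical_depth > 0.1:
        import warnings

        warnings.warn(
            f"optical depth {cfg.optical_depth:.3g} > 0.1: the uniform-"
            "excitation assumption behind the brightness equation is weak",
            stacklevel=2,
        )
    l_cm = um_to_cm(cfg.cube_side_um)
    rows = []
    for i, intensity in enumerate(cfg.intensities):
        scene = build_fbe_scene(cfg, intensity, spectral_grid)
        expected = fbe_expected_photons(
            intensity, cfg.sigma_cm2, cfg.n_cm3, cfg.phi, l_cm
        )
        photons = {}
        stderr = {}
        for cam_id, view_sign in (("cam1", -1), ("cam2", 1)):
            camera = _fbe_camera(cfg, view_sign, seed=cfg.seed + 1000 * i + (0 if view_sign < 0 else 1))
            film, totals = render_section(
                scene, camera, return_sample_totals=True
            )
            photons[cam_id] = detect_photons(film)
            totals = np.asarray(totals)
            stderr[cam_id] = float(
                totals.std(ddof=1) / np.sqrt(len(totals))
            ) if len(totals) > 1 else 0.0
        rows.append(
            {
                "intensity_photons": intensity,
                "f_analytic": expected,
                "f_cam1": photons["cam1"],
                "f_cam2": photons["cam2"],
                "stderr_cam1": stderr["cam1"],
                "stderr_cam2": stderr["cam2"],
                "ratio_cam1": photons["cam1"] / expected,
                "ratio_cam2": photons["cam2"] / expected,
            }
        )
    return pd.DataFrame(rows)


def measure_emission_spd(
    fluo: Fluorophore,
    lambda_ex_list,
    density_cm3: float = 1.0e18,
    cube_side_um: float = 2.0,
    voxel_size_um: float = 0.1,
    photons: float = 1.0e12,
    resolution: int = 128,
    samples_per_pixel: int = 8,
    spectral_grid: WavelengthGrid | None = None,
    seed: int = 0,
    emission_filter: EmissionFilter | None = None,
) -> dict:
    """Detected film-integrated SPD per excitation wavelength.

    Returns ``{"spds": {λex: SpectralDistribution}, "normalized": DataFrame}``
    where the normalized table holds each detected curve divided by the peak
    of the curve at the maximally exciting wavelength (the conventional
    presentation of excitation-sweep measurements).
    """
    sg = spectral_grid or fluo.f_em.grid
    grid = make_homogeneous_cube(cube_side_um, density_cm3, 0, voxel_size_um)
    fluos = FluorophoreTable([fluo])
    spds = {}
    for k, lam in enumerate(lambda_ex_list):
        sheet = LightSheet(
            thickness_um=cube_side_um,
            height_um=cube_side_um,
            lambda_ex_nm=float(lam),
            photons=photons,
        )
        scene = Scene(grid, sheet, fluos, MarchSettings.for_grid(grid), sg)
        camera = OrthographicThinLensCamera(
            film_width_um=cube_side_um * 1.6,
            film_height_um=cube_side_um * 1.6,
            resolution=(resolution, resolution),
            samples_per_pixel=samples_per_pixel,
            seed=seed + k,
        )
        film = render_section(scene, camera, emission_filter)
        spds[float(lam)] = film.total_spd()
    ex_eff = {lam: float(fluo.excitation(lam)) for lam in spds}
    lam_max = max(ex_eff, key=ex_eff.get)
    ref_peak = spds[lam_max].values.max()
    table = pd.DataFrame(
        {"wavelength_nm": sg.centers}
        | {
            f"lambda_ex_{lam:g}": spds[lam].values / ref_peak if ref_peak > 0 else spds[lam].values
            for lam in spds
        }
    )
    return {"spds": spds, "normalized": table, "lambda_ex_max": lam_max}


def make_axial_rod_phantom(
    n_rods: int = 12,
    seed: int = 7,
    box_um: float = 40.0,
    z_extent_um: float = 30.0,
    radius_um: float = 1.5,
    density_cm3: float = 1.0e18,
    voxel_size_um: float = 0.5,
):
    """Random thin rods parallel to the detection axis, for the blur study.

    Because each rod spans the full z extent, every z-slice of the phantom
    has the same x–y pattern: a pinhole camera sees the same image whatever
    the sheet thickness (up to photon scaling), while a finite aperture blurs
    the off-focal-plane slices — isolating depth-of-field from structure.
    """
    rng = np.random.default_rng(seed)
    half = box_um / 2.0
    shapes = []
    for _ in range(n_rods):
        x, y = rng.uniform(-half + 2 * radius_um, half - 2 * radius_um, size=2)
        shapes.append(
            Cylinder(
                (x, y, -z_extent_um / 2.0),
                (x, y, z_extent_um / 2.0),
                radius_um,
                density_cm3,
                0,
            )
        )
    lo = (-half, -half, -z_extent_um / 2.0 - voxel_size_um)
    hi = (half, half, z_extent_um / 2.0 + voxel_size_um)
    return voxelize_primitives(shapes, voxel_size_um, lo, hi)


def sharpness(image: np.ndarray) -> float:
    """Mean squared gradient of the mean-normalised image.

    Scale-invariant: multiplying the image by a constant leaves it unchanged,
    so photon-budget differences between renders do not masquerade as focus
    differences.
    """
    img = np.asarray(image, dtype=float)
    mean = img.mean()
    if mean == 0:
        return 0.0
    img = img / mean
    gy, gx = np.gradient(img)
    return float(np.mean(gx * gx + gy * gy))


def blur_vs_thickness(
    grid,
    fluo: Fluorophore,
    thicknesses_um=(5.0, 7.5, 10.0, 12.5),
    aperture_radius_um: float = 300.0,
    focus_distance_um: float = 1000.0,
    lambda_ex_nm: float = 488.0,
    photons: float = 1.0e12,
    resolution: int = 128,
    samples_per_pixel: int = 8,
    spectral_grid: WavelengthGrid | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Render one section per sheet thickness and score image sharpness.

    The sheet center (and, through synchronization, the focal plane) stays at
    z = 0; only the slab thickness varies.  Returns a thickness → sharpness
    table; with a finite aperture the sharpness falls as thickness grows.
    """
    sg = spectral_grid or fluo.f_em.grid
    fluos = FluorophoreTable([fluo])
    size = grid.size_um
    center = grid.origin_um + size / 2.0
    rows = []
    for k, t in enumerate(thicknesses_um):
        sheet = LightSheet(
            thickness_um=float(t),
            height_um=float(size[1] + 2.0),
            lambda_ex_nm=lambda_ex_nm,
            photons=photons,
            z_um=0.0,
        )
        scene = Scene(grid, sheet, fluos, MarchSettings.for_grid(grid), sg)
        camera = OrthographicThinLensCamera(
            film_width_um=float(size[0]),
            film_height_um=float(size[1]),
            resolution=(resolution, resolution),
            aperture_radius_um=aperture_radius_um,
            focus_distance_um=focus_distance_um,
            samples_per_pixel=samples_per_pixel,
            center_um=(float(center[0]), float(center[1])),
            seed=seed,  # same seed for every thickness: paired comparison
        )
        film = render_section(scene, camera)
        img = film.photon_image()
        rows.append(
            {
                "thickness_um": float(t),
                "sharpness": sharpness(img),
                "total_photons": detect_photons(film),
            }
        )
    return pd.DataFrame(rows)


def total_emitted_photons(scene: Scene) -> float:
    """Analytic total fluorescence emission of the scene over 4π sr.

    Σ_voxels σ·N·φ·f_ex(λex)·Φ(center)·V — the energy-conservation reference
    for the non-attenuating limit.
    """
    grid = scene.grid
    xs, ys, zs = grid.voxel_centers()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    from .illumination import sheet_flux_density

    flux = sheet_flux_density(scene.sheet, pts).reshape(grid.dims)
    v_cm3 = um3_to_cm3(grid.voxel_size_um**3)
    lam = scene.sheet.lambda_ex_nm
    total = 0.0
    for d, f in enumerate(scene.fluos.entries):
        mask = grid.dye_index == d
        if not mask.any():
            continue
        total += (
            f.sigma_cm2
            * f.phi
            * float(f.excitation(lam))
            * float((grid.density[mask] * flux[mask]).sum())
            * v_cm3
        )
    return total
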