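"""Acquisition: orthographic thin-lens camera, emission filter plane,
spectral film, and optical-section rendering.

The detection objective + tube lens pair of a light-sheet microscope is
telecentric: magnification does not change with depth.  It is modeled as an
orthographic camera with a finite-aperture thin lens.  Each film point spawns
a base ray along the detection axis; with a non-zero aperture the ray origin
is displaced by a concentric-disk-mapped lens sample and redirected through
the base ray's intersection with the focal plane.  Points on the focal plane
image sharply; a point Δz off-plane blurs into a circle of confusion of
radius ``aperture_radius · |Δz| / focus_distance`` (similar triangles with
the lens-to-focal-plane distance), independent of magnification.

The film accumulates, per pixel, the arriving spectral photon surface
density (photons·cm⁻²·nm⁻¹); summing over pixel area and wavelength yields
detected photon counts.  The radiance→photon calibration is the identity:
the per-steradian radiance delivered by the integrator is counted directly,
which is exactly the convention under which the fluorescence brightness
equation assigns 1/4π of the emitted photons to one detection plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .integrator import Scene, march_rays
from .spectral import EmissionFilter, SpectralDistribution, WavelengthGrid
from .units import um2_to_cm2

__all__ = [
    "OrthographicThinLensCamera",
    "SpectralFilm",
    "generate_camera_rays",
    "apply_emission_filter",
    "render_section",
    "detect_photons",
    "develop_image",
    "concentric_disk",
]


@dataclass
class OrthographicThinLensCamera:
    """Telecentric detection model: orthographic view + thin-lens aperture."""

    film_width_um: float
    film_height_um: float
    resolution: tuple[int, int]  # (nx, ny) pixels
    aperture_radius_um: float = 0.0  # 0 = pinhole-orthographic (infinite DOF)
    focal_plane_z_um: float = 0.0  # synchronized to the sheet at render time
    focus_distance_um: float = 1000.0  # lens plane to focal plane distance
    view_sign: int = -1  # -1: camera at +z looking along -z; +1: opposite
    samples_per_pixel: int = 8
    center_um: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.aperture_radius_um < 0:
            raise ValueError("aperture radius must be non-negative")
        nx, ny = self.resolution
        if nx < 1 or ny < 1:
            raise ValueError("resolution must be at least 1x1")
        if self.view_sign not in (-1, 1):
            raise ValueError("view_sign must be -1 or +1")
        if self.focus_distance_um <= 0:
            raise ValueError("focus distance must be positive")

    @property
    def pixel_area_cm2(self) -> float:
        nx, ny = self.resolution
        return um2_to_cm2(
            (self.film_width_um / nx) * (self.film_height_um / ny)
        )

    @property
    def lens_z_um(self) -> float:
        """World z of the camera/lens plane (behind the focal plane)."""
        return self.focal_plane_z_um - self.view_sign * self.focus_distance_um


def concentric_disk(u: np.ndarray, v: np.ndarray):
    """Map unit-square samples to the unit disk (Shirley–Chiu concentric map)."""
    a = 2.0 * u - 1.0
    b = 2.0 * v - 1.0
    r = np.where(np.abs(a) > np.abs(b), a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(
            np.abs(a) > np.abs(b),
            (np.pi / 4.0) * (b / a),
            (np.pi / 2.0) - (np.pi / 4.0) * (a / b),
        )
    theta = np.where((a == 0) & (b == 0), 0.0, theta)
    r = np.where((a == 0) & (b == 0), 0.0, r)
    return r * np.cos(theta), r * np.sin(theta)


def generate_camera_rays(
    camera: OrthographicThinLensCamera,
    pixel_xy: np.ndarray,
    lens_uv: np.ndarray | None = None,
):
    """Camera rays for continuous pixel coordinates, shape (M, 2).

    Returns (origins (M,3), directions (M,3)).  With zero aperture the rays
    are exactly parallel to the view axis; otherwise each ray passes through
    the base ray's focal-plane point from a disk-sampled lens offset.
    """
    nx, ny = camera.resolution
    px = np.atleast_2d(np.asarray(pixel_xy, dtype=float))
    x = camera.center_um[0] + (px[:, 0] / nx - 0.5) * camera.film_width_um
    y = camera.center_um[1] + (px[:, 1] / ny - 0.5) * camera.film_height_um
    M = len(px)
    z_lens = camera.lens_z_um
    origins = np.column_stack([x, y, np.full(M, z_lens)])
    if camera.aperture_radius_um == 0.0 or lens_uv is None:
        dirs = np.tile([0.0, 0.0, float(camera.view_sign)], (M, 1))
        return origins, dirs
    uv = np.atleast_2d(np.asarray(lens_uv, dtype=float))
    dx, dy = concentric_disk(uv[:, 0], uv[:, 1])
    offsets = np.column_stack([dx, dy]) * camera.aperture_radius_um
    focal_pts = np.column_stack(
        [x, y, np.full(M, camera.focal_plane_z_um)]
    )
    origins = origins.copy()
    origins[:, 0] += offsets[:, 0]
    origins[:, 1] += offsets[:, 1]
    dirs = focal_pts - origins
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return origins, dirs


@dataclass
class SpectralFilm:
    """Per-pixel SPD accumulator on the virtual CCD.

    ``values[iy, ix, k]`` is the spectral photon surface density
    (photons·cm⁻²·nm⁻¹) in wavelength bin k.
    """

    grid: WavelengthGrid
    resolution: tuple[int, int]
    pixel_area_cm2: float
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        nx, ny = self.resolution
        if self.values is None:
            self.values = np.zeros((ny, nx, self.grid.n_bins))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (ny, nx, self.grid.n_bins):
            raise ValueError("film values shape must be (ny, nx, n_bins)")

    def photon_image(self) -> np.ndarray:
        """Per-pixel detected photons: Σ_λ value·Δλ·pixel_area, shape (ny, nx)."""
        return self.values.sum(axis=2) * self.grid.step_nm * self.pixel_area_cm2

    def total_spd(self) -> SpectralDistribution:
        """Film-integrated SPD (photons·nm⁻¹): Σ_pixels value·pixel_area."""
        return SpectralDistribution(
            self.grid, self.values.sum(axis=(0, 1)) * self.pixel_area_cm2
        )


def apply_emission_filter(spd, emission_filter: EmissionFilter):
    """Bin-wise product of an SPD (or film value array) with the filter."""
    t = emission_filter.transmission
    if isinstance(spd, SpectralDistribution):
        if spd.grid != t.grid:
            raise ValueError("filter and SPD wavelength grids must match")
        return SpectralDistribution(spd.grid, spd.values * t.values)
    arr = np.asarray(spd, dtype=float)
    if arr.shape[-1] != t.grid.n_bins:
        raise ValueError("filter grid does not match spectral axis")
    return arr * t.values


def render_section(
    scene: Scene,
    camera: OrthographicThinLensCamera,
    emission_filter: EmissionFilter | None = None,
    return_sample_totals: bool = False,
):
    """Render one optical section onto a spectral film.

    The camera focal plane is synchronized to the sheet center plane (the
    defining alignment of light-sheet microscopy).  Each pixel averages
    ``samples_per_pixel`` stratified pixel/lens samples; deterministic for a
    fixed camera seed.

    With ``return_sample_totals`` the per-sample detected photon totals are
    returned alongside the film — their spread estimates the Monte Carlo
    standard error of the photon count.
    """
    camera.focal_plane_z_um = scene.sheet.z_um
    nx, ny = camera.resolution
    sg = scene.spectral_grid
    if emission_filter is not None and emission_filter.transmission.grid != sg:
        raise ValueError("emission filter grid must match the scene spectral grid")
    rng = np.random.default_rng(camera.seed)
    iy, ix = np.mgrid[0:ny, 0:nx]
    base = np.column_stack([ix.ravel(), iy.ravel()]).astype(float)
    M = nx * ny
    spp = camera.samples_per_pixel
    n_dyes = len(scene.fluos)
    # batch samples to bound per-march memory at ~a few hundred MB
    chunk = max(1, min(spp, int(np.ceil(2.0e6 / M))))
    A_mean = np.zeros((M, n_dyes))
    E_mean = np.zeros(M)
    sample_totals = []
    filt = (
        emission_filter.transmission.values if emission_filter is not None else None
    )
    em = scene.emission_matrix()
    em_filt = em * filt if filt is not None else em
    # photons per unit A / unit E after filtering, for per-sample totals
    a_to_photons = em_filt.sum(axis=1) * sg.step_nm * camera.pixel_area_cm2
    i_ex = sg.bin_index(scene.sheet.lambda_ex_nm)
    e_to_photons = camera.pixel_area_cm2 * (
        (filt[i_ex] if filt is not None else 1.0) if i_ex >= 0 else 0.0
    )
    done = 0
    while done < spp:
        n_s = min(chunk, spp - done)
        jitter = rng.random((n_s * M, 2))
        lens_uv = (
            rng.random((n_s * M, 2)) if camera.aperture_radius_um > 0 else None
        )
        pix = np.tile(base, (n_s, 1)) + jitter
        origins, dirs = generate_camera_rays(camera, pix, lens_uv)
        A, E = march_rays(origins, dirs, scene, rng=rng)
        A = A.reshape(n_s, M, n_dyes)
        E = E.reshape(n_s, M)
        A_mean += A.sum(axis=0)
        E_mean += E.sum(axis=0)
        if return_sample_totals:
            for s in range(n_s):
                sample_totals.append(
                    float((A[s] @ a_to_photons).sum())
                    + float(E[s].sum()) * e_to_photons
                )
        done += n_s
    A_mean /= spp
    E_mean /= spp
    acc = A_mean @ em if n_dyes else np.zeros((M, sg.n_bins))
    if E_mean.any() and i_ex >= 0:
        acc[:, i_ex] += E_mean / sg.step_nm
    if emission_filter is not None:
        acc = apply_emission_filter(acc, emission_filter)
    film = SpectralFilm(
        sg, (nx, ny), camera.pixel_area_cm2, acc.reshape(ny, nx, sg.n_bins)
    )
    if return_sample_totals:
        return film, sample_totals
    return film


def detect_photons(film: SpectralFilm) -> float:
    """Total photons on the film: double midpoint sum over pixels and bins."""
    return float(
        film.values.sum() * film.grid.step_nm * film.pixel_area_cm2
    )


def develop_image(film: SpectralFilm, mode: str = "photon_sum_gray16"):
    """Develop the spectral film into a raster image.

    ``photon_sum_gray16``: per-pixel photon count linearly scaled to uint16;
    returns ``(image, metadata)`` with ``metadata['scale']`` such that
    ``image * scale`` recovers photons per pixel.

    ``pseudocolor_by_dye``: RGB float image colouring each pixel by its
    spectral centroid wavelength (a fixed wavelength→RGB lookup, not a
    colorimetric CIE transform), intensity-scaled by photon count.
    """
    photons = film.photon_image()
    if mode == "photon_sum_gray16":
        peak = photons.max()
        scale = peak / 65535.0 if peak > 0 else 1.0
        img = np.round(photons / scale).astype(np.uint16) if peak > 0 else (
            np.zeros_like(photons, dtype=np.uint16)
        )
        return img, {"scale": scale, "units": "photons_per_pixel"}
    if mode == "pseudocolor_by_dye":
        centers = film.grid.centers
        total = film.values.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            centroid = (film.values * centers).sum(axis=2) / total
        centroid = np.where(total > 0, centroid, 0.0)
        rgb = wavelength_to_rgb(centroid)
        peak = photons.max()
        intensity = photons / peak if peak > 0 else photons
        return rgb * intensity[..., None], {"units": "relative"}
    raise ValueError(f"unknown develop mode {mode!r}")


def wavelength_to_rgb(lambda_nm: np.ndarray) -> np.ndarray:
    """Piecewise-linear visible-wavelength → RGB lookup (display only)."""
    lam = np.asarray(lambda_nm, dtype=float)
    r = np.zeros_like(lam)
    g = np.zeros_like(lam)
    b = np.zeros_like(lam)
    seg = (lam >= 380) & (lam < 440)
    r[seg] = (440 - lam[seg]) / 60.0
    b[seg] = 1.0
    seg = (lam >= 440) & (lam < 490)
    g[seg] = (lam[seg] - 440) / 50.0
    b[seg] = 1.0
    seg = (lam >= 490) & (lam < 510)
    g[seg] = 1.0
    b[seg] = (510 - lam[seg]) / 20.0
    seg = (lam >= 510) & (lam < 580)
    r[seg] = (lam[seg] - 510) / 70.0
    g[seg] = 1.0
    seg = (lam >= 580) & (lam < 645)
    r[seg] = 1.0
    g[seg] = (645 - lam[seg]) / 65.0
    seg = (lam >= 645) & (lam <= 780)
    r[seg] = 1.0
    return np.stack([r, g, b], axis=-1)
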