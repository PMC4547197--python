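"""Single-scattering fluorescence volume integrator.

A camera ray is marched through the specimen with a fixed step; at each
sample point the extended source term is evaluated and attenuated by the
Beer–Lambert transmittance back to the ray origin.  The source term couples
the monochromatic directional light sheet to the medium through a binary
fluorescence function F(p):

* fluorescent point (F = 1): inelastic scattering redistributes the
  excitation flux over the dye's emission band,
  ``S(λ) = (1/4π) · σ·N(p) · f_ex(λex) · f_em(λ) · φ · Φ(p)``,
  with isotropic emission (phase = 1/4π) and Φ the sheet flux density;
* non-fluorescent point (F = 0): elastic scattering returns light at the
  excitation wavelength only,
  ``S(λex) = σ_s · p_HG(ω′·ω) · Φ(p)``.

Because the sheet is monochromatic and directional, the wavelength and
direction integrals of the general in-scattering term collapse to point
evaluations — the integrator is exact in those variables and Monte Carlo
noise enters only through pixel/lens sampling and optional step jitter.

Extinction is chromatic: a dye's relative absorption spectrum is its
excitation spectrum, so the absorption coefficient at wavelength λ is
``σ_a(p, λ) = σ·N(p)·f_ex_local(λ)`` (plus the achromatic elastic
coefficient σ_s).  The Stokes shift therefore makes the medium nearly
transparent to its own emission, as it is for real fluorophores.  To keep
full-spectrum accumulation factorable per dye, the camera-path transmittance
for light emitted by dye d is evaluated once per dye at d's mean emission
wavelength rather than per wavelength bin; the excitation path uses λex
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .illumination import LightSheet, sheet_flux_density
from .specimen import (
    AnnotatedFluorescentVolumeGrid,
    FluorophoreTable,
    sample_density,
    sample_dye,
)
from .spectral import SpectralDistribution, WavelengthGrid
from .units import um_to_cm

__all__ = [
    "Ray",
    "MarchSettings",
    "Scene",
    "phase_isotropic",
    "phase_hg",
    "transmittance",
    "source_term",
    "integrate_ray",
    "integrate_rays",
    "march_rays",
    "FOUR_PI",
]

FOUR_PI = 4.0 * np.pi


@dataclass(frozen=True)
class Ray:
    origin_um: tuple[float, float, float]
    direction: tuple[float, float, float]
    t_min_um: float = 0.0
    t_max_um: float = np.inf

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("ray direction must be a unit vector")
        if not self.t_min_um < self.t_max_um:
            raise ValueError("t_min must be < t_max")


@dataclass
class MarchSettings:
    """Ray-marching quadrature settings.

    ``step_um`` defaults to half the specimen voxel size when built through
    :meth:`for_grid`.  With ``jitter`` on, the sample point within each step
    is drawn uniformly instead of at the midpoint (stratified sampling),
    decorrelating banding at the cost of Monte Carlo noise.
    """

    step_um: float
    jitter: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.step_um <= 0:
            raise ValueError("marching step must be positive")

    @classmethod
    def for_grid(cls, grid: AnnotatedFluorescentVolumeGrid, jitter: bool = False,
                 seed: int = 0) -> "MarchSettings":
        return cls(step_um=grid.voxel_size_um / 2.0, jitter=jitter, seed=seed)


@dataclass
class Scene:
    """Everything a ray needs: specimen, sheet, dye table, quadrature, spectra."""

    grid: AnnotatedFluorescentVolumeGrid
    sheet: LightSheet
    fluos: FluorophoreTable
    march: MarchSettings
    spectral_grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    phase_g: float = 0.0  # Henyey-Greenstein anisotropy of the elastic term

    def __post_init__(self):
        if not (-1.0 < self.phase_g < 1.0):
            raise ValueError("phase_g must lie in (-1, 1)")
        if int(self.grid.dye_index.max(initial=-1)) >= len(self.fluos):
            raise ValueError(
                "grid references a dye index with no fluorophore table entry"
            )

    # -- per-dye constants -------------------------------------------------
    def sigma_by_dye(self) -> np.ndarray:
        """Peak cross sections (cm²) indexed by dye, leading 0 for dye −1."""
        return np.array([0.0] + [f.sigma_cm2 for f in self.fluos.entries])

    def emission_weight_by_dye(self) -> np.ndarray:
        """(1/4π)·σ_d·φ_d·f_ex_d(λex) per dye — the per-molecule inelastic
        coupling at the sheet wavelength (leading 0 for dye −1)."""
        lam = self.sheet.lambda_ex_nm
        w = [0.0] + [
            f.sigma_cm2 * f.phi * float(f.excitation(lam)) / FOUR_PI
            for f in self.fluos.entries
        ]
        return np.array(w)

    def emission_matrix(self) -> np.ndarray:
        """f_em per dye on the spectral grid, shape (n_dyes, n_bins)."""
        if not len(self.fluos):
            return np.zeros((0, self.spectral_grid.n_bins))
        return np.vstack(
            [f.f_em.value_at(self.spectral_grid.centers) for f in self.fluos.entries]
        )

    def mean_emission_wavelengths(self) -> np.ndarray:
        """Mean emission wavelength λ̄ = ∫λ·f_em dλ per dye."""
        sg = self.spectral_grid
        return np.array(
            [
                float((f.f_em.value_at(sg.centers) * sg.centers).sum() * sg.step_nm)
                for f in self.fluos.entries
            ]
        )

    def absorption_matrix(self, wavelengths) -> np.ndarray:
        """Relative absorption f_ex_a(λ) of each dye a at each wavelength.

        Shape (n_wavelengths, n_dyes): row w scales the per-dye optical
        depths into the total optical depth at wavelength w.
        """
        return np.array(
            [[float(f.excitation(w)) for f in self.fluos.entries] for w in np.atleast_1d(wavelengths)]
        )

    def sigma_t(self, points, lambda_nm: float | None = None) -> np.ndarray:
        """Extinction coefficient (cm⁻¹) at world points.

        At a given wavelength: σ·N·f_ex_local(λ) + σ_s inside the specimen.
        With ``lambda_nm=None`` the peak (λ-independent upper envelope)
        absorption σ·N + σ_s is returned.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rho = sample_density(self.grid, pts)
        dye = sample_dye(self.grid, pts)
        sigma = self.sigma_by_dye()[dye + 1]
        if lambda_nm is not None and len(self.fluos):
            fex = np.concatenate(
                [[0.0], self.absorption_matrix(lambda_nm)[0]]
            )[dye + 1]
            sigma = sigma * fex
        st = sigma * rho
        if self.grid.sigma_s_elastic_cm > 0:
            # the elastic medium fills the specimen box, fluorescent or not
            inside = np.all(
                (pts >= self.grid.origin_um) & (pts < self.grid.max_corner_um),
                axis=1,
            )
            st = st + self.grid.sigma_s_elastic_cm * inside
        return st

    def flux(self, points) -> np.ndarray:
        sigma_fn = None
        if self.sheet.attenuate:
            lam = self.sheet.lambda_ex_nm
            sigma_fn = lambda p: self.sigma_t(p, lam)  # noqa: E731
        return sheet_flux_density(
            self.sheet, points, grid=self.grid, sigma_t_fn=sigma_fn,
            step_um=self.march.step_um,
        )


def phase_isotropic(omega_in=None, omega_out=None) -> float:
    """Isotropic phase function, 1/(4π) sr⁻¹ for any direction pair."""
    return 1.0 / FOUR_PI


def phase_hg(cos_theta, g: float):
    """Henyey–Greenstein phase function (sr⁻¹); reduces to 1/4π at g = 0."""
    if not (-1.0 < g < 1.0):
        raise ValueError("anisotropy g must lie in (-1, 1)")
    ct = np.asarray(cos_theta, dtype=float)
    denom = (1.0 + g * g - 2.0 * g * ct) ** 1.5
    out = (1.0 - g * g) / (FOUR_PI * denom)
    return out if out.ndim else float(out)


def transmittance(
    p0_um, p1_um, scene_or_sigma_fn, step_um: float,
    lambda_nm: float | None = None,
) -> float:
    """Beer–Lambert transmittance exp(−∫σ_t ds) along the segment p0→p1.

    Midpoint ray marching with an exact partial last step; 1 in vacuum and
    multiplicative over concatenated segments to quadrature accuracy.  When a
    :class:`Scene` is passed, ``lambda_nm`` selects the wavelength of the
    chromatic extinction (None = peak absorption).
    """
    if isinstance(scene_or_sigma_fn, Scene):
        scene = scene_or_sigma_fn
        sigma_fn = lambda p: scene.sigma_t(p, lambda_nm)  # noqa: E731
    else:
        sigma_fn = scene_or_sigma_fn
    p0 = np.asarray(p0_um, dtype=float)
    p1 = np.asarray(p1_um, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    if length == 0:
        return 1.0
    d = (p1 - p0) / length
    tau = 0.0
    s = 0.0
    while s < length:
        ds = min(step_um, length - s)
        mid = p0 + d * (s + 0.5 * ds)
        tau += float(sigma_fn(mid[None, :])[0]) * um_to_cm(ds)
        s += ds
    return float(np.exp(-tau))


def source_term(p_um, omega, lambda_nm, scene: Scene):
    """Extended source term S(p, ω, λ) in photons·cm⁻³·sr⁻¹·nm⁻¹.

    Fluorescent points emit inelastically over the dye emission band with an
    isotropic 1/4π phase; non-fluorescent scattering points return the
    elastic term at the excitation wavelength only (as a per-nm bin density).
    Self-emission is zero (the media are not luminous).
    """
    p = np.atleast_2d(np.asarray(p_um, dtype=float))
    rho = sample_density(scene.grid, p)[0]
    dye = int(sample_dye(scene.grid, p)[0])
    phi_flux = scene.flux(p)[0]
    if phi_flux == 0.0:
        return 0.0
    if dye >= 0 and rho > 0:
        f = scene.fluos[dye]
        return (
            (1.0 / FOUR_PI)
            * f.sigma_cm2
            * rho
            * float(f.excitation(scene.sheet.lambda_ex_nm))
            * float(f.emission_density(lambda_nm))
            * f.phi
            * phi_flux
        )
    # elastic: monochromatic return at λex, spread over its wavelength bin
    if scene.grid.sigma_s_elastic_cm <= 0 or dye >= 0 and rho > 0:
        return 0.0
    p0 = p[0]
    if not np.all((p0 >= scene.grid.origin_um) & (p0 < scene.grid.max_corner_um)):
        return 0.0
    sg = scene.spectral_grid
    if sg.bin_index(lambda_nm) != sg.bin_index(scene.sheet.lambda_ex_nm):
        return 0.0
    omega = np.asarray(omega, dtype=float)
    cos_theta = float(np.dot([1.0, 0.0, 0.0], omega))
    return (
        scene.grid.sigma_s_elastic_cm
        * phase_hg(cos_theta, scene.phase_g)
        * phi_flux
        / sg.step_nm
    )


def march_rays(
    origins_um: np.ndarray,
    directions: np.ndarray,
    scene: Scene,
    rng: np.random.Generator | None = None,
):
    """March a batch of rays; return factored accumulators (A, E).

    ``A`` has shape (M, n_dyes): the attenuated, flux-weighted inelastic
    line integral per ray and dye, so that the arriving spectral radiance is
    ``L(λ) = Σ_d A_d · f_em_d(λ)``.  ``E`` (shape (M,)) is the elastic
    radiance returned at the excitation wavelength.  Lockstep vectorised
    marching: all rays advance with the same base step, each with an exact
    partial last step at its far bounds exit.  Camera-path attenuation for
    dye d is evaluated at d's mean emission wavelength (chromatic
    absorption, see module docstring); the elastic path uses λex.
    """
    origins = np.atleast_2d(np.asarray(origins_um, dtype=float))
    dirs = np.atleast_2d(np.asarray(directions, dtype=float))
    M_full = len(origins)
    n_dyes = len(scene.fluos)
    A_full = np.zeros((M_full, n_dyes))  # per-dye inelastic accumulators
    E_full = np.zeros(M_full)  # elastic accumulator at λex
    lo, hi = scene.grid.world_bounds()
    t0, t1 = _aabb_clip(origins, dirs, lo, hi)
    hit_idx = np.nonzero(t1 > t0)[0]
    if len(hit_idx) == 0:
        return A_full, E_full
    # compact to rays that intersect the specimen bounds
    origins = origins[hit_idx]
    dirs = dirs[hit_idx]
    t0 = t0[hit_idx]
    t1 = t1[hit_idx]
    M = len(hit_idx)
    A = np.zeros((M, n_dyes))
    E = np.zeros(M)
    step = scene.march.step_um
    n_steps = int(np.ceil((t1 - t0).max() / step))
    if scene.march.jitter:
        rng = rng or np.random.default_rng(scene.march.seed)

    sheet = scene.sheet
    sigma_by_dye = scene.sigma_by_dye()
    emis_w = scene.emission_weight_by_dye()
    # W[d, a]: relative absorption of dye a at dye d's mean emission λ;
    # w_ex[a]: relative absorption of dye a at the excitation wavelength
    if n_dyes:
        lam_bar = scene.mean_emission_wavelengths()
        W = scene.absorption_matrix(lam_bar)  # (n_dyes, n_dyes)
        w_ex = scene.absorption_matrix(sheet.lambda_ex_nm)[0]
    tau_abs = np.zeros((M, n_dyes))  # per-absorbing-dye ∫σ·N ds
    tau_s = np.zeros(M)  # achromatic elastic extinction depth
    sigma_s = scene.grid.sigma_s_elastic_cm
    glo, ghi = scene.grid.origin_um, scene.grid.max_corner_um
    cos_theta = -dirs[:, 0]  # sheet direction +x scattered into −ray.direction

    for k in range(n_steps):
        seg_start = t0 + k * step
        ds = np.clip(t1 - seg_start, 0.0, step)
        active = ds > 0
        if not active.any():
            break
        frac = rng.random(M) if scene.march.jitter else 0.5
        t_mid = seg_start + frac * ds
        p = origins + t_mid[:, None] * dirs
        rho = sample_density(scene.grid, p)
        dye = sample_dye(scene.grid, p)
        flux = scene.flux(p)
        ds_cm = um_to_cm(ds) * active
        d_tau = sigma_by_dye[dye + 1] * rho * ds_cm  # peak-absorption depth
        fluor = (dye >= 0) & (rho > 0)
        emitting = fluor & (flux > 0) & active
        if emitting.any():
            rows = np.nonzero(emitting)[0]
            cols = dye[emitting]
            # transmittance at each emitting dye's mean emission wavelength,
            # including the chromatic half-step of the local absorber
            tau_em = (
                (tau_abs[rows] * W[cols]).sum(axis=1)
                + tau_s[rows]
                + (frac if np.isscalar(frac) else frac[rows])
                * (d_tau[emitting] * W[cols, cols] + sigma_s * ds_cm[emitting])
            )
            # rows are unique within a step: direct indexed add is safe
            A[rows, cols] += (
                np.exp(-tau_em)
                * flux[emitting]
                * ds_cm[emitting]
                * rho[emitting]
                * emis_w[cols + 1]
            )
        if sigma_s > 0:
            inside = np.all((p >= glo) & (p < ghi), axis=1)
            elastic = inside & ~fluor & (flux > 0) & active
            if elastic.any():
                rows = np.nonzero(elastic)[0]
                tau_el = (
                    (tau_abs[rows] * w_ex).sum(axis=1)
                    + tau_s[rows]
                    + (frac if np.isscalar(frac) else frac[rows])
                    * sigma_s
                    * ds_cm[elastic]
                )
                E[rows] += (
                    np.exp(-tau_el)
                    * flux[elastic]
                    * ds_cm[elastic]
                    * sigma_s
                    * phase_hg(cos_theta[elastic], scene.phase_g)
                )
        if n_dyes:
            absorbing = dye >= 0
            if absorbing.any():
                rows = np.nonzero(absorbing)[0]
                tau_abs[rows, dye[absorbing]] += d_tau[absorbing]
        if sigma_s > 0:
            tau_s += sigma_s * ds_cm * inside
    A_full[hit_idx] = A
    E_full[hit_idx] = E
    return A_full, E_full


def integrate_rays(
    origins_um: np.ndarray,
    directions: np.ndarray,
    scene: Scene,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """March a batch of rays and return spectral radiance, shape (M, n_bins).

    Radiance units: photons·cm⁻²·sr⁻¹·nm⁻¹ arriving at each ray origin along
    −direction; ``L(λ) = Σ_d A_d · f_em_d(λ)`` plus the elastic line at λex.
    """
    A, E = march_rays(origins_um, directions, scene, rng)
    sg = scene.spectral_grid
    if len(scene.fluos):
        L = A @ scene.emission_matrix()
    else:
        L = np.zeros((len(A), sg.n_bins))
    if E.any():
        i_ex = sg.bin_index(scene.sheet.lambda_ex_nm)
        if i_ex >= 0:
            L[:, i_ex] += E / sg.step_nm
    return L


def integrate_ray(ray: Ray, scene: Scene) -> SpectralDistribution:
    """March a single ray; returns the arriving spectral radiance as an SPD."""
    L = integrate_rays(
        np.asarray(ray.origin_um)[None, :],
        np.asarray(ray.direction)[None, :],
        scene,
    )[0]
    return SpectralDistribution(scene.spectral_grid, L)


def _aabb_clip(origins: np.ndarray, dirs: np.ndarray, lo, hi):
    """Per-ray [t0, t1] overlap with the axis-aligned box (slab method)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dirs
        ta = (lo - origins) * inv
        tb = (hi - origins) * inv
    # parallel rays: ±inf handled by min/max; NaN (0·inf on the boundary) → ignore axis
    near = np.minimum(ta, tb)
    far = np.maximum(ta, tb)
    tnear = np.where(np.isnan(near), -np.inf, near).max(axis=1)
    tfar = np.where(np.isnan(far), np.inf, far).min(axis=1)
    hit = (tfar > tnear) & (tfar > 0) & np.isfinite(tfar)
    t0 = np.where(hit, np.maximum(tnear, 0.0), 0.0)
    t1 = np.where(hit, tfar, 0.0)
    return t0, t1
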