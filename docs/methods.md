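# Methods

## Scope and geometry

`lsfmsim` models light sheet fluorescence microscopy with geometric optics:
ray transport, Beer–Lambert attenuation, elastic scattering, and inelastic
(fluorescent) wavelength redistribution. Wave effects — diffraction,
interference, polarization — are outside the model, as are quenching,
photobleaching, and multiple scattering (one medium interaction per
sheet-to-camera path).

World coordinates are µm in a right-handed frame: the light sheet propagates
along +x, its plane spans x–y, and the detection axis is ±z. Cross sections
are cm² and concentrations cm⁻³ as is conventional for fluorophore data;
every µm↔cm conversion passes through `lsfmsim.units` so the bridge is
audited in one place.

## Spectral representation

All light and all spectra live on a shared uniform `WavelengthGrid`
(default 300–800 nm in 5 nm bins, midpoint convention). The default covers
every excitation line used in practice (355–561 nm) and all visible
emission; it is configurable when finer line shapes matter.

Normalisation conventions (these are package conventions, stated because
photon bookkeeping depends on them):

- `f_ex` is peak-normalised to 1 — a dimensionless efficiency relative to
  the peak absorption cross section σ;
- `f_em` is normalised to unit integral over wavelength — a probability
  density (nm⁻¹) for the emitted photon's wavelength.

With these choices the per-molecule photon yield at excitation λ_ex is
σ·f_ex(λ_ex)·φ and summing the emission over wavelength returns exactly that
yield — the spectral model and the brightness equation agree by
construction, not by fitted calibration.

The excitation laser is a scalar wavelength, not a delta-spike SPD, which
avoids any bin-width ambiguity in the photon budget.

Spectra read from CSV are linearly interpolated onto the working grid and
clamped to zero outside their tabulated support; out-of-support lookups
return 0 rather than raising, because spectra are physically zero far from
their bands.

### Bundled fluorophores

The packaged GFP/RFP/CFP-like spectra are *synthetic* — sums of one or two
Gaussians with literature-plausible peaks and widths, truncated below 10⁻⁶
of peak — not digitised measurements. Every experiment and test is written
against whatever spectra are loaded, so replacing them with real tabulated
spectra (two-column CSV) changes nothing structurally.

## Source term

The binary fluorescence function F(p) switches a point between two
behaviours:

- **F = 1 (fluorescent):** the point absorbs σ·N(p)·f_ex(λ_ex) of the local
  excitation flux Φ(p) per cm of path, re-emits a fraction φ distributed as
  f_em(λ), isotropically (phase 1/4π). Fluorescent points do not also
  scatter elastically.
- **F = 0 (non-fluorescent):** elastic scattering returns light at λ_ex
  with a Henyey–Greenstein phase (g = 0 by default, i.e. isotropic). The
  elastic medium occupies the whole specimen box — tissue scatters whether
  or not it carries dye; the elastic coefficient σ_s defaults to 0 (a purely
  fluorescent specimen) because no measured tissue value ships with the
  package, and is exposed in the specimen/config.

Self-emission is identically zero: fluorescent media are not luminous
without excitation.

Because the sheet is monochromatic and directional, the general in-scattering
double integral (over incoming direction and excitation wavelength) collapses
to a point evaluation. The integrator is therefore exact in those variables;
the only Monte Carlo dimensions are pixel position, lens position, and
(optionally) the jittered march offset.

## Extinction model

The absorption coefficient is chromatic: a dye's relative absorption
spectrum is taken to be its excitation spectrum, so

    σ_a(p, λ) = σ · N(p) · f_ex_local(λ),    σ_t = σ_a + σ_s.

This makes the medium nearly transparent in its own emission band (the
Stokes shift), which matters quantitatively: at the brightness-validation
concentration (N = 10¹⁸ cm⁻³, σ·N = 300 cm⁻¹) a wavelength-flat extinction
would silently re-absorb ~3% of the emitted light, a bias the brightness
equation does not contain.

To keep full-spectrum accumulation cheap, the camera-path transmittance for
light emitted by dye d is evaluated at d's *mean emission wavelength*
(one scalar per dye per ray) instead of per wavelength bin; the excitation
path uses λ_ex exactly. The approximation error is second order in the
variation of f_ex across the emission band, and vanishes entirely in the
optically thin scenes used for validation. The march keeps one optical-depth
accumulator per absorbing dye plus one for σ_s, so multi-dye specimens
attenuate each dye's emission correctly.

## Ray marching

Fixed-step midpoint marching (default step = voxel/2) with an exact partial
last step at the bounds exit; transmittance is accumulated as running
optical depth with a half-step correction at the sample point. Optional
per-step jitter (uniform offset within the step, seed-controlled) trades
banding for noise; it is off by default because the default scenes are
smooth enough for the midpoint rule.

Density lookups are trilinear over voxel-center values with zero ghost
cells (`scipy.ndimage.map_coordinates`, order 1, grid-constant). The
resulting half-voxel linear taper at the specimen boundary integrates to
exactly the boxcar mass — interpolation neither creates nor destroys dye.
Dye-identity lookups are nearest-voxel, clamped to the boundary voxel inside
the taper skirt so tapered density always carries the dye of the voxel it
spills from; beyond the skirt the medium reads as empty (density 0,
dye −1).

## Illumination

The sheet is a uniform rectangular slab: flux density photons/(thickness ×
height) inside, zero outside, propagating along +x. `photons` is the budget
of one exposure. Hard lateral edges are the literal reading of a uniform
profile; no y-falloff is modelled. Excitation-path attenuation is off by
default (the validation scenes assume uniform maximal excitation) and
switchable for realism.

`GaussianBeamProfile` quantifies when the slab approximation holds:
w(x) = w₀·√(1 + (x/x_R)²), so the beam is √2 − 1 ≈ 41% thicker one Rayleigh
range from the waist. `rectangular_approximation_error` reports the relative
thickening across a field of view for warning purposes.

## Acquisition

The detection objective + tube lens pair is telecentric and is modelled as
an orthographic camera with a thin-lens aperture. Lens samples are mapped to
the aperture disk with the concentric (Shirley–Chiu) mapping; each ray is
redirected through its pixel's focal-plane point, giving a circle of
confusion of radius aperture·|Δz|/focus_distance — magnification-invariant,
as a telecentric system blurs. `focus_distance` (lens plane to focal plane,
default 1000 µm) is a free lens parameter: real systems' depth of field
derives from a lens prescription this model deliberately does not have, so
the ratio aperture/focus_distance plays the role of the detection NA. The
camera focal plane is set equal to the sheet center plane on every render —
the defining synchronization of LSFM.

The film accumulates spectral photon surface density per pixel; photon
counts are the double midpoint sum over pixel area and wavelength. The
radiance→photon calibration is the identity: the integrator's per-steradian
radiance is counted directly, which is precisely the convention under which
the brightness equation assigns 1/4π of isotropic emission to one detection
plane. Emission filters are transmission spectra multiplied bin-wise onto
the film (default: a notch of the excitation bin ± one neighbour). The film
is an ideal detector — no shot or read noise.

## Validation experiments and their scales

- **Brightness equation.** 2 µm homogeneous cube (σ = 3×10⁻¹⁶ cm²,
  N = 10¹⁸ cm⁻³, φ = 0.8, optical depth 0.06 — thin enough for uniform
  excitation), sheet sized exactly to the cube face so the sheet area
  cancels as it does in the closed form, ten photon budgets (1–10)×10¹²,
  two opposing pinhole cameras, 128² film, 64 samples/pixel, 0.05 µm
  voxels. The known residual biases are the unilluminated interpolation
  skirt (~1.3%) and the sub-peak excitation of the 488 nm line on a 5 nm
  grid (~0.3%); both are inherent to the discretisation, documented here,
  and well inside the 5% acceptance band.
- **Emission-SPD recovery.** Each bundled dye, excitations 355/405/488/561
  nm, 128²×8 spp. The pipeline is linear in the spectrum, so the detected
  shape equals f_em and amplitudes scale as f_ex to numerical precision;
  the experiment exists to prove that end-to-end, not to fit anything.
- **Sheet-thickness blur.** Phantom of rods parallel to the detection axis
  spanning the full z range, so every z-slice has the same x–y pattern: a
  pinhole camera sees a thickness-invariant image (isolation of depth of
  field from structure), while a finite aperture (300 µm at 1000 µm focus
  distance, NA ≈ 0.29) blurs off-plane slices. Sharpness is the mean squared
  gradient of the mean-normalised image — scale-invariant, so photon-budget
  differences cannot masquerade as focus. The metric choice is ours; the
  underlying claim (thicker sheet ⇒ more out-of-focus light ⇒ less sharp)
  is qualitative.

These scales (128² film, 8–64 spp) are the package's desk-scale defaults;
production renders at 1024²×32 spp are configuration changes, not code
changes.

## What the synthetic phantoms do and do not show

The generators produce homogeneous cubes, primitive-based "neurons" (soma
spheres + tapering random-walk neurites), and axial rods. They exercise the
full transport and acquisition pipeline with exactly known ground truth,
which is what the closed-form validations need. They do not reproduce real
tissue morphology, spatially varying optical properties, refractive-index
mismatch, or labeling noise — so passing tests demonstrate the correctness
of the physics implementation, not image-level realism for any particular
specimen.

## Numerical choices and degenerate inputs

- Marching step voxel/2; transmittance midpoint rule is exact on piecewise
  constant interiors and converges at second order on smooth fields.
- Voxelization is by voxel-center inclusion (cylinders have flat caps);
  adequate at the test voxel sizes, with volume error vanishing as the
  voxel shrinks.
- Overlapping primitives: densities sum, last-listed shape wins the dye
  index. Mixed-dye voxels are not supported (one index per voxel).
- Empty scenes, rays missing the bounds, zero-density specimens, and
  excitation outside every dye's band all render black rather than raising.
- Determinism: every random stream (pixel jitter, lens sampling, march
  jitter, phantom generation) descends from explicit integer seeds;
  identical config + seed reproduces identical output bytes.

## Known limitations

Single scattering only; no diffraction-limited PSF (resolution is set by
pixel pitch and defocus geometry, not by λ/NA); ideal noiseless detector;
the per-dye mean-emission-wavelength attenuation shortcut above; the
aperture/focus-distance pair is a phenomenological stand-in for a real lens
prescription; bundled spectra are synthetic approximations.
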