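"""Wavelength grids, spectral distributions, fluorophores and the
fluorescence-efficiency mathematics.

The spectral currency of the simulator is a :class:`SpectralDistribution`: a
vector of non-negative per-bin values on a shared :class:`WavelengthGrid`
(midpoint convention).  Fluorophores carry a peak-normalised excitation
spectrum ``f_ex`` (dimensionless efficiency in [0, 1]), an emission spectrum
``f_em`` normalised to unit integral (a probability density per nm), a quantum
yield ``phi`` and a molecular absorption cross section ``sigma_cm2``.

Two wavelength-redistribution models are provided:

* the historical ocean-water baseline — a binary absorption window
  (1 for 370 < λex < 690 nm) combined with a Gaussian emission line — kept as
  a comparison point;
* the spectrally-resolved fluorescence efficiency
  ``P_f(λ ← λex) = f_ex(λex) · f_em(λ) · φ`` used by the renderer, which
  plugs the measured excitation/emission profiles of real dyes into the
  inelastic source term.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WavelengthGrid",
    "SpectralDistribution",
    "Fluorophore",
    "EmissionFilter",
    "SpectrumFormatError",
    "gaussian_emission",
    "cerezo_absorption",
    "cerezo_redistribution",
    "fluorescence_efficiency",
    "spd_integrate",
    "read_spectrum_csv",
    "write_spectrum_csv",
]


class SpectrumFormatError(ValueError):
    """Raised when a spectrum CSV file is malformed."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength binning over [start_nm, stop_nm].

    Bin centers sit at ``start_nm + (i + 0.5) * step_nm``; the bin count
    ``(stop - start) / step`` must be an exact integer.
    """

    start_nm: float = 300.0
    stop_nm: float = 800.0
    step_nm: float = 5.0

    def __post_init__(self):
        if not (self.start_nm < self.stop_nm):
            raise ValueError("start_nm must be < stop_nm")
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        n = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"grid span {self.stop_nm - self.start_nm} nm is not an "
                f"integer multiple of step {self.step_nm} nm"
            )

    @property
    def n_bins(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm))

    @property
    def centers(self) -> np.ndarray:
        return self.start_nm + (np.arange(self.n_bins) + 0.5) * self.step_nm

    def bin_index(self, lambda_nm: float) -> int:
        """Index of the bin containing ``lambda_nm``; -1 if outside."""
        i = int(np.floor((lambda_nm - self.start_nm) / self.step_nm))
        return i if 0 <= i < self.n_bins else -1


@dataclass
class SpectralDistribution:
    """Per-bin values on a wavelength grid (photons, photons/nm or relative)."""

    grid: WavelengthGrid
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.values is None:
            self.values = np.zeros(self.grid.n_bins)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError(
                f"values length {self.values.shape} does not match grid bin "
                f"count {self.grid.n_bins}"
            )
        if np.any(self.values < 0):
            raise ValueError("spectral values must be non-negative")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectral values must be finite")

    def integrate(self) -> float:
        """Midpoint-rule integral, Σ value_i · Δλ."""
        return float(self.values.sum() * self.grid.step_nm)

    def value_at(self, lambda_nm):
        """Linear interpolation between bin centers; 0 outside the grid."""
        return np.interp(
            lambda_nm, self.grid.centers, self.values, left=0.0, right=0.0
        )

    def normalized_to_peak(self) -> "SpectralDistribution":
        peak = self.values.max()
        if peak <= 0:
            raise ValueError("cannot peak-normalize an all-zero spectrum")
        return SpectralDistribution(self.grid, self.values / peak)

    def normalized_to_unit_integral(self) -> "SpectralDistribution":
        area = self.integrate()
        if area <= 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return SpectralDistribution(self.grid, self.values / area)


def spd_integrate(spd: SpectralDistribution) -> float:
    """Integrate an SPD over wavelength (midpoint rule): Σ value_i · Δλ.

    Linear in the values; this is the inner wavelength integral of the film
    photon count.
    """
    return spd.integrate()


@dataclass
class Fluorophore:
    """A fluorescent dye: spectra, quantum yield and absorption cross section.

    ``f_ex`` is the relative excitation efficiency (peak-normalised to 1);
    ``f_em`` is the emission line shape normalised to unit integral over
    wavelength (per-nm probability density); ``phi`` is the quantum yield
    (emitted photons per absorbed photon); ``sigma_cm2`` the per-molecule
    absorption cross section.
    """

    name: str
    f_ex: SpectralDistribution
    f_em: SpectralDistribution
    phi: float
    sigma_cm2: float

    def __post_init__(self):
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError("quantum yield must lie in [0, 1]")
        if self.sigma_cm2 <= 0:
            raise ValueError("absorption cross section must be positive")
        if self.f_ex.values.max() > 1.0 + 1e-9:
            raise ValueError("f_ex must be peak-normalized to at most 1")
        if abs(self.f_em.integrate() - 1.0) > 1e-6:
            raise ValueError("f_em must integrate to 1 (per-nm density)")

    def excitation(self, lambda_ex_nm):
        """Relative excitation efficiency at λex (0 outside the band)."""
        return self.f_ex.value_at(lambda_ex_nm)

    def emission_density(self, lambda_nm):
        """Emission probability density (nm⁻¹) at λ (0 outside the band)."""
        return self.f_em.value_at(lambda_nm)


@dataclass
class EmissionFilter:
    """Spectral transmission of the filter plane in front of the camera."""

    transmission: SpectralDistribution

    def __post_init__(self):
        if np.any(self.transmission.values > 1.0 + 1e-12):
            raise ValueError("filter transmission must be <= 1 per bin")

    @classmethod
    def unity(cls, grid: WavelengthGrid) -> "EmissionFilter":
        return cls(SpectralDistribution(grid, np.ones(grid.n_bins)))

    @classmethod
    def notch(cls, grid: WavelengthGrid, lambda_nm: float) -> "EmissionFilter":
        """Block the bin containing λ and its two neighbours (laser notch)."""
        t = np.ones(grid.n_bins)
        i = grid.bin_index(lambda_nm)
        if i >= 0:
            t[max(i - 1, 0) : i + 2] = 0.0
        return cls(SpectralDistribution(grid, t))

    @classmethod
    def bandpass(
        cls, grid: WavelengthGrid, lo_nm: float, hi_nm: float
    ) -> "EmissionFilter":
        c = grid.centers
        t = ((c >= lo_nm) & (c <= hi_nm)).astype(float)
        return cls(SpectralDistribution(grid, t))


def gaussian_emission(lambda_nm, lambda0_nm: float, lambda_sigma_nm: float):
    """Gaussian emission line: normal density in wavelength (nm⁻¹).

    The simplified emission model of the ocean-water fluorescence baseline;
    integrates to 1 over the real line.
    """
    if lambda_sigma_nm <= 0:
        raise ValueError("lambda_sigma must be positive")
    lam = np.asarray(lambda_nm, dtype=float)
    z = (lam - lambda0_nm) / lambda_sigma_nm
    out = np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * lambda_sigma_nm)
    return out if out.ndim else float(out)


def cerezo_absorption(lambda_ex_nm):
    """Binary absorption window of the baseline model: 1 iff 370 < λex < 690.

    Boundary values are excluded (strict inequalities).
    """
    lam = np.asarray(lambda_ex_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    out = ((lam > 370.0) & (lam < 690.0)).astype(float)
    return out if out.ndim else float(out)


def cerezo_redistribution(
    lambda_ex_nm: float,
    lambda_nm: float,
    lambda0_nm: float,
    lambda_sigma_nm: float,
    phi: float,
):
    """Baseline wavelength-redistribution function g(λex)·h(λ)·φ·(λex/λ).

    Historical comparison model: binary absorption window times a Gaussian
    emission line, scaled by the quantum yield and the photon-energy ratio.
    """
    if lambda_ex_nm <= 0 or lambda_nm <= 0:
        raise ValueError("wavelengths must be positive")
    g = cerezo_absorption(lambda_ex_nm)
    h = gaussian_emission(lambda_nm, lambda0_nm, lambda_sigma_nm)
    return g * h * phi * (lambda_ex_nm / lambda_nm)


def fluorescence_efficiency(fluo: Fluorophore, lambda_ex_nm, lambda_nm):
    """Spectrally-resolved fluorescence efficiency f_ex(λex)·f_em(λ)·φ.

    Dimensionless per nm of emission bandwidth; zero wherever either spectrum
    is zero (wavelengths outside the tabulated support read as 0).
    """
    return (
        fluo.excitation(lambda_ex_nm)
        * fluo.emission_density(lambda_nm)
        * fluo.phi
    )


def read_spectrum_csv(path, grid: WavelengthGrid) -> SpectralDistribution:
    """Read a two-column spectrum CSV and resample onto ``grid``.

    Expected header ``wavelength_nm,value``; wavelengths strictly increasing,
    values non-negative.  Resampling is linear interpolation between tabulated
    points, clamped to 0 outside the tabulated support.
    """
    wl: list[float] = []
    vals: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != [
            "wavelength_nm",
            "value",
        ]:
            raise SpectrumFormatError(
                f"{path}: line 1: expected header 'wavelength_nm,value'"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise SpectrumFormatError(f"{path}: line {lineno}: need 2 columns")
            try:
                w = float(row[0])
                v = float(row[1])
            except ValueError as exc:
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: non-numeric value"
                ) from exc
            if wl and w <= wl[-1]:
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: wavelengths must be strictly increasing"
                )
            if v < 0:
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: negative spectral value"
                )
            wl.append(w)
            vals.append(v)
    if len(wl) < 2:
        raise SpectrumFormatError(f"{path}: need at least two data rows")
    resampled = np.interp(grid.centers, wl, vals, left=0.0, right=0.0)
    # clamp outside the tabulated support even if endpoint values are nonzero
    c = grid.centers
    resampled[(c < wl[0]) | (c > wl[-1])] = 0.0
    return SpectralDistribution(grid, resampled)


def write_spectrum_csv(spd: SpectralDistribution, path) -> None:
    """Write an SPD as a two-column CSV (bin centers, values)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavelength_nm", "value"])
        for w, v in zip(spd.grid.centers, spd.values):
            writer.writerow([f"{w:.6g}", f"{v:.10g}"])
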