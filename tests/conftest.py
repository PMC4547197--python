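"""Shared fixtures: wavelength grids, bundled dyes, and small test scenes."""

import numpy as np
import pytest

from lsfmsim import (
    FluorophoreTable,
    LightSheet,
    MarchSettings,
    Scene,
    WavelengthGrid,
    load_fluorophore,
    make_homogeneous_cube,
)
from lsfmsim.spectral import Fluorophore, SpectralDistribution


@pytest.fixture(scope="session")
def grid5():
    """Default 300-800 nm grid with 5 nm bins."""
    return WavelengthGrid(300.0, 800.0, 5.0)


@pytest.fixture(scope="session")
def gfp(grid5):
    return load_fluorophore("gfp", grid5)


@pytest.fixture(scope="session")
def rfp(grid5):
    return load_fluorophore("rfp", grid5)


@pytest.fixture(scope="session")
def cfp(grid5):
    return load_fluorophore("cfp", grid5)


def gaussian_line_dye(
    grid,
    name="line_dye",
    ex_peak_nm=488.0,
    ex_width_nm=20.0,
    em_peak_nm=530.0,
    em_width_nm=18.0,
    phi=0.8,
    sigma_cm2=3.0e-16,
):
    """Single-Gaussian-band dye with controllable peaks (test helper)."""
    c = grid.centers
    ex = np.exp(-0.5 * ((c - ex_peak_nm) / ex_width_nm) ** 2)
    em = np.exp(-0.5 * ((c - em_peak_nm) / em_width_nm) ** 2)
    ex[ex < 1e-6] = 0.0  # truncate tails as tabulated spectra do
    em[em < 1e-6] = 0.0
    return Fluorophore(
        name,
        SpectralDistribution(grid, ex).normalized_to_peak(),
        SpectralDistribution(grid, em).normalized_to_unit_integral(),
        phi,
        sigma_cm2,
    )


@pytest.fixture()
def line_dye(grid5):
    return gaussian_line_dye(grid5)


@pytest.fixture()
def cube_scene(grid5, line_dye):
    """2 µm homogeneous fluorescent cube, full-face sheet at 488 nm."""
    grid = make_homogeneous_cube(2.0, 1.0e18, 0, 0.1)
    sheet = LightSheet(
        thickness_um=2.0, height_um=2.0, lambda_ex_nm=488.0, photons=1.0e12
    )
    return Scene(
        grid,
        sheet,
        FluorophoreTable([line_dye]),
        MarchSettings.for_grid(grid),
        grid5,
    )
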