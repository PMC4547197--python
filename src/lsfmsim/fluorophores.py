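"""Bundled fluorophore definitions and loaders.

The packaged GFP/RFP/CFP-like spectra are *synthetic approximations* — sums
of one or two Gaussians with literature-plausible peak positions and widths —
not digitised database spectra.  They are adequate for exercising the
spectral pipeline (everything downstream is written against whatever spectra
are loaded) and can be replaced by user-supplied CSV tables at any time.

A fluorophore definition file is a small YAML document::

    name: my_dye
    phi: 0.6
    sigma_cm2: 3.0e-16
    excitation_csv: path/to/ex.csv
    emission_csv: path/to/em.csv

with the CSVs in the two-column ``wavelength_nm,value`` format.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml

from .spectral import Fluorophore, SpectralDistribution, WavelengthGrid, read_spectrum_csv

__all__ = ["BUNDLED", "load_fluorophore", "load_fluorophore_file", "bundled_names"]

# quantum yields / cross sections: plausible fixture values for the three
# classic fluorescent-protein classes (cm² per molecule)
BUNDLED = {
    "gfp": {"phi": 0.60, "sigma_cm2": 3.0e-16},
    "rfp": {"phi": 0.25, "sigma_cm2": 2.2e-16},
    "cfp": {"phi": 0.40, "sigma_cm2": 2.6e-16},
}


def bundled_names() -> list[str]:
    return sorted(BUNDLED)


def _data_path(fname: str) -> Path:
    return Path(importlib.resources.files("lsfmsim") / "data" / fname)


def _build(name: str, ex_path, em_path, phi: float, sigma_cm2: float,
           grid: WavelengthGrid) -> Fluorophore:
    f_ex = read_spectrum_csv(ex_path, grid).normalized_to_peak()
    f_em = read_spectrum_csv(em_path, grid).normalized_to_unit_integral()
    return Fluorophore(name=name, f_ex=f_ex, f_em=f_em, phi=phi, sigma_cm2=sigma_cm2)


def load_fluorophore(name: str, grid: WavelengthGrid | None = None) -> Fluorophore:
    """Load a bundled fluorophore ('gfp', 'rfp' or 'cfp') on ``grid``."""
    key = name.lower()
    if key not in BUNDLED:
        raise KeyError(f"unknown bundled fluorophore {name!r}; have {bundled_names()}")
    grid = grid or WavelengthGrid()
    props = BUNDLED[key]
    return _build(
        key,
        _data_path(f"{key}_excitation.csv"),
        _data_path(f"{key}_emission.csv"),
        props["phi"],
        props["sigma_cm2"],
        grid,
    )


def load_fluorophore_file(path, grid: WavelengthGrid | None = None) -> Fluorophore:
    """Load a fluorophore from a YAML definition file (see module docstring)."""
    grid = grid or WavelengthGrid()
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("name", "phi", "sigma_cm2", "excitation_csv", "emission_csv"):
        if key not in doc:
            raise ValueError(f"{path}: missing key {key!r}")
    base = path.parent
    return _build(
        str(doc["name"]),
        base / doc["excitation_csv"],
        base / doc["emission_csv"],
        float(doc["phi"]),
        float(doc["sigma_cm2"]),
        grid,
    )
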